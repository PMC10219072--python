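"""Structural descriptors of coarse ensembles.

Superposition RMSD (Kabsch), radius of gyration, per-site RMSF, inter-
selection distances, hydrogen-bond detection/occupancy, salt-bridge scans
and moving averages — the per-frame observables used to characterise
stability and compactness of the wild-type and phosphorylated complexes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Ensemble, Selection, SiteModel

__all__ = [
    "DescriptorSeries",
    "HBondCriterion",
    "ContactRecord",
    "kabsch",
    "superpose",
    "align_frames",
    "rmsd_series",
    "radius_of_gyration",
    "rg_series",
    "rmsf",
    "detect_hbond",
    "hbond_occupancy",
    "salt_bridge_scan",
    "distance_series",
    "moving_average",
]


@dataclass
class DescriptorSeries:
    name: str  # RMSD | RG | DISTANCE
    values: np.ndarray
    selection: str = "all"
    reference: str = "initial"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.name in ("RMSD", "RG") and np.any(self.values < -1e-12):
            raise ValueError(f"{self.name} series must be non-negative")


@dataclass
class HBondCriterion:
    """Geometric hydrogen-bond criterion.

    Present iff donor-acceptor distance <= d_max and the hydrogen-donor-
    acceptor angular deviation <= angle_max.
    """

    d_max: float = 3.5  # A
    angle_max: float = 30.0  # degrees

    def __post_init__(self):
        if self.d_max <= 0 or not 0 < self.angle_max < 180:
            raise ValueError("invalid H-bond criterion")


@dataclass
class ContactRecord:
    site_a: int
    site_b: int
    kind: str  # HBOND | SALT_BRIDGE
    per_frame: np.ndarray
    distance_series: np.ndarray
    occupancy: float = field(init=False)

    def __post_init__(self):
        self.per_frame = np.asarray(self.per_frame, dtype=bool)
        self.distance_series = np.asarray(self.distance_series, dtype=float)
        self.occupancy = float(self.per_frame.mean())


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rotation/translation of ``mobile`` onto ``reference``.

    Returns ``(rotation 3x3, translation, rmsd)`` minimising the RMSD over
    all proper rigid motions; the rotation determinant is +1 (reflections
    excluded by sign correction of the smallest singular vector).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 sites")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    a, b = mobile - mc, reference - rc
    if np.linalg.matrix_rank(b, tol=1e-9) < 2:
        raise ValueError("collinear sites: rotation is not unique")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    rotated = a @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((rotated - b) ** 2, axis=1))))
    translation = rc - rot @ mc
    return rot, translation, rmsd


def superpose(mobile: np.ndarray, reference: np.ndarray, indices=None):
    """Superpose ``mobile`` onto ``reference`` fitting on ``indices``.

    The fit uses the selected sites; the returned coordinates are the full
    mobile set moved by the fitted rigid motion. Returns ``(moved, rmsd)``
    with the RMSD measured over the fit set.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    idx = slice(None) if indices is None else np.asarray(indices)
    rot, trans, rmsd = kabsch(mobile[idx], reference[idx])
    return mobile @ rot.T + trans, rmsd


def _resolve(selection, model: SiteModel):
    if selection is None:
        return np.arange(model.n_sites)
    if isinstance(selection, Selection):
        if selection.indices is None:
            selection.resolve(model)
        return selection.indices
    if isinstance(selection, str):
        return model.select(selection).indices
    return np.asarray(selection, dtype=int)


def rmsd_series(
    ensemble: Ensemble, reference="initial", selection=None
) -> DescriptorSeries:
    """Per-frame superposed RMSD against a reference frame or structure.

    ``reference`` is "initial" (frame 0), a frame index, or an explicit
    (n_sites, 3) array; fitting and measuring use the same selection.
    """
    idx = _resolve(selection, ensemble.site_model)
    if isinstance(reference, str):
        if reference != "initial":
            raise ValueError(f"unknown reference {reference!r}")
        ref = ensemble.coords[0]
        refname = "initial"
    elif np.isscalar(reference):
        ref = ensemble.coords[int(reference)]
        refname = f"frame {int(reference)}"
    else:
        ref = np.asarray(reference, float)
        refname = "external"
    vals = np.empty(ensemble.n_frames)
    for t, frame in enumerate(ensemble.coords):
        _, _, vals[t] = kabsch(frame[idx], ref[idx])
    return DescriptorSeries("RMSD", vals, selection=str(selection), reference=refname)


def align_frames(ensemble: Ensemble, selection=None, n_iter: int = 2) -> Ensemble:
    """Superpose every frame onto the (iteratively refined) ensemble mean.

    Standard essential-dynamics alignment: frames are fitted onto the mean
    structure, the mean recomputed, and the fit repeated ``n_iter`` times.
    Removes rigid-body contamination from the fluctuation statistics.
    """
    idx = _resolve(selection, ensemble.site_model)
    coords = ensemble.coords.copy()
    ref = coords[0]
    for _ in range(n_iter):
        for t in range(coords.shape[0]):
            coords[t], _ = superpose(coords[t], ref, idx)
        ref = coords.mean(axis=0)
    out = Ensemble(coords, ensemble.site_model, times=ensemble.times, aligned=True)
    out.metadata = dict(ensemble.metadata)
    return out


# ---------------------------------------------------------------------------
# scalar descriptors
# ---------------------------------------------------------------------------

def radius_of_gyration(frame, selection=None, masses=None, model=None) -> float:
    """sqrt(sum m_i |r_i - r_cm|^2 / sum m_i) over the selected sites."""
    frame = np.asarray(frame, float)
    idx = _resolve(selection, model) if model is not None else (
        np.arange(frame.shape[0]) if selection is None else np.asarray(selection, int)
    )
    pts = frame[idx]
    m = np.ones(len(pts)) if masses is None else np.asarray(masses, float)[idx]
    total = m.sum()
    if total <= 0:
        raise ValueError("zero total mass")
    cm = (m[:, None] * pts).sum(axis=0) / total
    return float(np.sqrt((m * np.sum((pts - cm) ** 2, axis=1)).sum() / total))


def rg_series(ensemble: Ensemble, selection=None, mass_weighted=True) -> DescriptorSeries:
    idx = _resolve(selection, ensemble.site_model)
    masses = ensemble.site_model.masses if mass_weighted else None
    vals = np.array(
        [radius_of_gyration(f, idx, masses=masses) for f in ensemble.coords]
    )
    return DescriptorSeries("RG", vals, selection=str(selection))


def rmsf(ensemble: Ensemble, selection=None, align_first: bool = True) -> np.ndarray:
    """Per-site root-mean-square fluctuation about the time-average position.

    With ``align_first`` every frame is first superposed onto the ensemble
    mean (two refinement passes), so rigid tumbling contributes nothing.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    idx = _resolve(selection, ensemble.site_model)
    ens = align_frames(ensemble, idx) if align_first else ensemble
    x = ens.coords[:, idx, :]
    mean = x.mean(axis=0)
    return np.sqrt(np.mean(np.sum((x - mean) ** 2, axis=2), axis=0))


# ---------------------------------------------------------------------------
# hydrogen bonds and salt bridges
# ---------------------------------------------------------------------------

def detect_hbond(donor, hydrogen, acceptor, criterion: HBondCriterion | None = None) -> bool:
    """Apply the distance/angle criterion to one donor-H-acceptor triple."""
    criterion = criterion or HBondCriterion()
    donor = np.asarray(donor, float)
    hydrogen = np.asarray(hydrogen, float)
    acceptor = np.asarray(acceptor, float)
    dh = hydrogen - donor
    if np.linalg.norm(dh) < 1e-9:
        raise ValueError("donor and hydrogen coincide; angle undefined")
    da = acceptor - donor
    dist = np.linalg.norm(da)
    if dist > criterion.d_max:
        return False
    cosang = float(dh @ da / (np.linalg.norm(dh) * dist))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return bool(angle <= criterion.angle_max)


def hbond_occupancy(
    ensemble: Ensemble,
    donor_label: int = 1,
    hydrogen_label: int = 2,
    acceptor_label: int = 3,
    criterion: HBondCriterion | None = None,
    chain: str | None = None,
) -> ContactRecord:
    """Fraction of frames in which a donor-H-acceptor triple is bonded."""
    criterion = criterion or HBondCriterion()
    m = ensemble.site_model
    di = m.index_of(donor_label, chain)
    hi = m.index_of(hydrogen_label, chain)
    ai = m.index_of(acceptor_label, chain)
    flags = np.array(
        [
            detect_hbond(f[di], f[hi], f[ai], criterion)
            for f in ensemble.coords
        ]
    )
    dists = np.linalg.norm(ensemble.coords[:, ai] - ensemble.coords[:, di], axis=1)
    return ContactRecord(donor_label, acceptor_label, "HBOND", flags, dists)


def salt_bridge_scan(
    ensemble: Ensemble,
    basic_sites,
    acidic_sites,
    d_max: float = 4.0,
    occupancy_min: float = 0.5,
) -> list[ContactRecord]:
    """Score basic/acidic site pairs by their N-O proxy distance.

    Coarse sites stand in for the charged-group atoms; a pair is reported
    when its distance is <= ``d_max`` in at least ``occupancy_min`` of
    frames. The full distance series is kept on every reported record
    since physical bridge distances straddle any single cutoff.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    basic = list(basic_sites)
    acidic = list(acidic_sites)
    if not basic or not acidic:
        raise ValueError("empty site set")
    m = ensemble.site_model
    records = []
    for lb in basic:
        bi = m.index_of(lb)
        for la in acidic:
            ai = m.index_of(la)
            d = np.linalg.norm(ensemble.coords[:, bi] - ensemble.coords[:, ai], axis=1)
            present = d <= d_max
            if present.mean() >= occupancy_min:
                records.append(ContactRecord(lb, la, "SALT_BRIDGE", present, d))
    return records


# ---------------------------------------------------------------------------
# distances and smoothing
# ---------------------------------------------------------------------------

def distance_series(
    ensemble: Ensemble, selection_a, selection_b, mode: str = "centroid"
) -> DescriptorSeries:
    """Per-frame centroid-centroid or minimum distance between two site sets."""
    ia = _resolve(selection_a, ensemble.site_model)
    ib = _resolve(selection_b, ensemble.site_model)
    if mode == "centroid":
        ca = ensemble.coords[:, ia, :].mean(axis=1)
        cb = ensemble.coords[:, ib, :].mean(axis=1)
        vals = np.linalg.norm(ca - cb, axis=1)
    elif mode == "min":
        a = ensemble.coords[:, ia, None, :]
        b = ensemble.coords[:, None, ib, :]
        vals = np.sqrt(np.sum((a - b) ** 2, axis=3)).min(axis=(1, 2))
    else:
        raise ValueError("mode must be 'centroid' or 'min'")
    return DescriptorSeries("DISTANCE", vals, selection=f"{selection_a}|{selection_b}")


def moving_average(series, bin_size: int) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges.

    The window around index i spans ``bin_size`` points (half on each
    side, truncated at the array ends); the output has the input length.
    """
    x = np.asarray(series, dtype=float)
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if bin_size > x.size:
        raise ValueError("bin_size exceeds series length")
    half_lo = (bin_size - 1) // 2
    half_hi = bin_size // 2
    out = np.empty_like(x)
    for i in range(x.size):
        lo = max(0, i - half_lo)
        hi = min(x.size, i + half_hi + 1)
        out[i] = x[lo:hi].mean()
    return out
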