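"""Anisotropic network model (ANM) and perturbation response scanning (PRS).

The complex is modelled as a network of coarse sites joined by harmonic
springs within a distance cutoff (default 12 A). The 3N x 3N Hessian H of
the ANM potential encodes the network's collective dynamics; its pseudo-
inverse is the linear-response susceptibility. PRS probes allostery by
applying unit forces at each site in turn and measuring the displacement
response everywhere (Hooke's law, dR = H^+ F). Row statistics of the
response map rank sites as signal *effectors*, column statistics as
*sensors*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .model import SiteModel

__all__ = [
    "ANMModel",
    "PRSMap",
    "contact_pairs",
    "build_anm",
    "build_anm_from_contacts",
    "mode_restricted_inverse",
    "prs_scan",
    "effector_sensor_profiles",
    "prs_difference",
]

DEFAULT_CUTOFF = 12.0  # A
DEFAULT_N_MODES = 20
ZERO_MODE_RTOL = 1e-8  # eigenvalue < rtol * max eigenvalue counts as rigid-body


@dataclass
class ANMModel:
    hessian: np.ndarray
    coords: np.ndarray
    site_model: SiteModel | None
    cutoff: float
    gamma: float
    eigenvalues: np.ndarray = field(init=False)
    eigenvectors: np.ndarray = field(init=False)
    n_zero_modes: int = field(init=False)
    contacts: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        evals, evecs = np.linalg.eigh(self.hessian)
        evals[np.abs(evals) < ZERO_MODE_RTOL * max(evals.max(), 1e-30)] = 0.0
        self.eigenvalues = evals
        self.eigenvectors = evecs
        self.n_zero_modes = int(np.sum(evals == 0.0))

    @property
    def n_sites(self) -> int:
        return self.coords.shape[0]

    def covariance(self, kT: float = 1.0, n_modes: int | None = None) -> np.ndarray:
        """Fluctuation covariance kT * H^+ (optionally mode-restricted)."""
        if n_modes is None:
            n_modes = 3 * self.n_sites - self.n_zero_modes
        return kT * mode_restricted_inverse(self, n_modes)


def contact_pairs(coords: np.ndarray, cutoff: float = DEFAULT_CUTOFF) -> set[tuple[int, int]]:
    """All site pairs (i < j) within the cutoff distance."""
    d = squareform(pdist(coords))
    i, j = np.nonzero(np.triu(d <= cutoff, k=1))
    return set(zip(i.tolist(), j.tolist()))


def build_anm(
    site_model_or_coords,
    coords: np.ndarray | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    gamma: float = 1.0,
) -> ANMModel:
    """Build the ANM Hessian from coordinates and a distance cutoff.

    Off-diagonal 3x3 block for a contact pair (i, j) is -(gamma/d^2) d (x) d
    with d the inter-site vector; diagonal blocks are minus the sum of the
    row's off-diagonal blocks, so every row-block sums to zero (translation
    invariance). A contact graph that leaves the structure with more than
    the 6 rigid-body zero modes raises with the disconnected components.
    """
    site_model, coords = _unpack(site_model_or_coords, coords)
    pairs = contact_pairs(coords, cutoff)
    return build_anm_from_contacts(site_model, coords, pairs, gamma=gamma, cutoff=cutoff)


def build_anm_from_contacts(
    site_model: SiteModel | None,
    coords: np.ndarray,
    contacts,
    gamma: float = 1.0,
    spring_scales: dict | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> ANMModel:
    """ANM from an explicit contact set (optionally per-contact spring scales)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("an ANM needs at least 2 sites")
    contacts = sorted({(min(i, j), max(i, j)) for i, j in contacts})
    for i, j in contacts:
        if i == j or not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"invalid contact ({i}, {j}) for {n} sites")
    comps = _graph_components(n, contacts)
    if len(comps) > 1:
        raise ValueError(
            f"contact graph is disconnected ({len(comps)} components): "
            f"{[sorted(c)[:8] for c in comps]}"
        )
    hessian = assemble_hessian(coords, contacts, gamma, spring_scales)
    model = ANMModel(hessian, coords, site_model, cutoff, gamma, contacts=contacts)
    if model.n_zero_modes > 6:
        raise ValueError(
            f"structure is underconstrained: {model.n_zero_modes} zero modes "
            "from floppy (mechanism) regions despite a connected contact graph"
        )
    return model


def assemble_hessian(coords, contacts, gamma=1.0, spring_scales=None) -> np.ndarray:
    """Dense ANM Hessian for an explicit contact list."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    hessian = np.zeros((3 * n, 3 * n))
    for i, j in contacts:
        dvec = coords[j] - coords[i]
        d2 = float(dvec @ dvec)
        if d2 == 0.0:
            raise ValueError(f"coincident sites in contact ({i}, {j})")
        g = gamma
        if spring_scales:
            g = g * spring_scales.get((i, j), spring_scales.get((j, i), 1.0))
        block = -(g / d2) * np.outer(dvec, dvec)
        hessian[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] += block
        hessian[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] += block
        hessian[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        hessian[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return hessian


def count_zero_modes(coords, contacts) -> int:
    """Number of near-zero Hessian modes (sparse solve for large systems)."""
    h = assemble_hessian(coords, contacts)
    if h.shape[0] <= 240:
        ev = np.linalg.eigvalsh(h)
        return int(np.sum(np.abs(ev) < ZERO_MODE_RTOL * max(ev[-1], 1e-30)))
    from scipy.sparse import csc_matrix
    from scipy.sparse.linalg import eigsh

    hs = csc_matrix(h)
    lam_max = eigsh(hs, k=1, which="LA", return_eigenvectors=False)[0]
    try:
        low = eigsh(hs, k=12, sigma=-1e-6, which="LM", return_eigenvectors=False)
        return int(np.sum(np.abs(low) < ZERO_MODE_RTOL * lam_max))
    except Exception:
        ev = np.linalg.eigvalsh(h)
        return int(np.sum(np.abs(ev) < ZERO_MODE_RTOL * max(ev[-1], 1e-30)))


def _unpack(site_model_or_coords, coords):
    if isinstance(site_model_or_coords, SiteModel):
        sm = site_model_or_coords
        c = sm.reference_coords if coords is None else np.asarray(coords, float)
        return sm, c
    return None, np.asarray(site_model_or_coords, dtype=float)


def _graph_components(n, contacts):
    adj = [[] for _ in range(n)]
    for i, j in contacts:
        adj[i].append(j)
        adj[j].append(i)
    seen, comps = set(), []
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(w for w in adj[v] if w not in comp)
        seen |= comp
        comps.append(comp)
    return comps


def mode_restricted_inverse(anm: ANMModel, n_modes: int) -> np.ndarray:
    """Pseudo-inverse of H restricted to the n_modes slowest nonzero modes.

    Sum over k of u_k u_k^T / lambda_k, modes taken in ascending eigenvalue
    order after skipping the rigid-body null space. With all nonzero modes
    this is the Moore-Penrose pseudo-inverse.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    nz = np.flatnonzero(anm.eigenvalues > 0.0)
    if n_modes > nz.size:
        raise ValueError(f"requested {n_modes} modes but only {nz.size} nonzero modes")
    sel = nz[:n_modes]
    u = anm.eigenvectors[:, sel]
    return (u / anm.eigenvalues[sel]) @ u.T


@dataclass
class PRSMap:
    """Site-by-site perturbation response map.

    Row i holds the response of every site to unit forces at site i;
    entry (i, j) sums the squared displacement of site j over the three
    Cartesian unit forces applied at site i. Rows may be normalized by the
    self-response S_ii so the diagonal is 1.
    """

    matrix: np.ndarray
    n_modes_used: int
    normalized: bool
    site_model: SiteModel | None = None

    @property
    def effectiveness(self) -> np.ndarray:
        return self.matrix.mean(axis=1)

    @property
    def sensitivity(self) -> np.ndarray:
        return self.matrix.mean(axis=0)


def prs_scan(
    anm: ANMModel, n_modes: int = DEFAULT_N_MODES, normalize: bool = True
) -> PRSMap:
    """Scan unit-force perturbations over all sites through the ANM.

    S_ij = || 3x3 block (j, i) of the mode-restricted H^+ ||_F^2, which is
    the sum of squared responses of site j to the three canonical unit
    forces at site i. With ``normalize`` rows are divided by S_ii.
    """
    n = anm.n_sites
    hinv = mode_restricted_inverse(anm, n_modes)
    # blocks[j, i] = H^+[3j:3j+3, 3i:3i+3]; S_ij = sum of squares over block
    b = hinv.reshape(n, 3, n, 3)
    s = np.einsum("jaib,jaib->ij", b, b)
    if normalize:
        diag = np.diag(s).copy()
        if np.any(diag == 0.0):
            bad = int(np.flatnonzero(diag == 0.0)[0])
            raise ValueError(f"zero self-response at site index {bad}; cannot normalize")
        s = s / diag[:, None]
    return PRSMap(s, n_modes_used=n_modes, normalized=normalize, site_model=anm.site_model)


def effector_sensor_profiles(prs_map: PRSMap) -> tuple[np.ndarray, np.ndarray]:
    """(effectiveness per site, sensitivity per site) = row/column means."""
    m = prs_map.matrix
    if not np.all(np.isfinite(m)):
        raise ValueError("PRS map contains non-finite entries")
    return m.mean(axis=1), m.mean(axis=0)


def prs_difference(map_a: PRSMap, map_b: PRSMap):
    """Elementwise map_a - map_b plus per-site profile deltas ranked by size.

    Returns ``(diff_matrix, ranked)`` where ``ranked`` is a list of records
    ``{site_index, d_effectiveness, d_sensitivity, magnitude}`` sorted by
    descending magnitude = max(|d_eff|, |d_sens|).
    """
    if map_a.matrix.shape != map_b.matrix.shape:
        raise ValueError("PRS maps have different shapes")
    diff = map_a.matrix - map_b.matrix
    d_eff = map_a.effectiveness - map_b.effectiveness
    d_sens = map_a.sensitivity - map_b.sensitivity
    mag = np.maximum(np.abs(d_eff), np.abs(d_sens))
    order = np.argsort(-mag)
    ranked = [
        {
            "site_index": int(i),
            "d_effectiveness": float(d_eff[i]),
            "d_sensitivity": float(d_sens[i]),
            "magnitude": float(mag[i]),
        }
        for i in order
    ]
    return diff, ranked
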