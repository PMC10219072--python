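"""Synthetic conformational ensembles with known ground truth.

The analyses in this package were designed for microsecond MD ensembles of
the DNA polymerase beta / gapped-DNA complex, which are not publicly
deposited. This module generates coarse ensembles carrying the statistical
structure those analyses assume, with the generating parameters stored as
ground truth so every downstream stage can be tested for parameter
recovery:

* a 354-site reference (326 C-alpha pseudo-chain in four spatially
  clustered domains + 28 DNA phosphorus sites on a B-DNA-like double
  helix adjacent to the D/C interface), built so the lyase and N domains
  touch only through a narrow bridge between residues 44 and 335 — the
  hydrogen-bonded pair that locks the closed state;
* Gaussian ensembles with covariance kT * H^+ of an anisotropic network
  model (sampled exactly from the mode spectrum);
* two-basin closed/open mixtures with recorded basin labels;
* scripted hydrogen-bond traces with exact occupancy;
* a "phosphorylation" contact perturbation that breaks the 44-335 contact
  and adds a 44-149 contact, mimicking the loss of the S44-E335 hydrogen
  bond and the new S44-R149 salt bridge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enm import ANMModel, contact_pairs
from .model import (
    DEFAULT_DOMAIN_RANGES,
    Domain,
    Ensemble,
    Site,
    SiteModel,
    SiteRole,
    assign_domain,
)

__all__ = [
    "SyntheticSpec",
    "PerturbationSpec",
    "phospho_spec",
    "make_reference",
    "make_open_reference",
    "sample_anm_ensemble",
    "sample_two_state",
    "apply_perturbation",
    "script_hbond_trace",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic coarse complex."""

    n_protein_sites: int = 326
    n_dna_sites: int = 28
    first_label: int = 10  # polymerase numbering starts at residue 10
    domain_ranges: dict = field(default_factory=lambda: dict(DEFAULT_DOMAIN_RANGES))
    ca_bond_length: float = 3.8  # A, successive C-alpha pseudo-bond
    p_bond_length: float = 6.5  # A, successive backbone P along a strand
    kT: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_protein_sites < 1 or self.n_dna_sites < 0:
            raise ValueError("site counts must be positive")
        last = self.first_label + self.n_protein_sites - 1
        spans = sorted((lo, hi) for lo, hi in self.domain_ranges.values())
        prev_hi = None
        for lo, hi in spans:
            if lo > hi:
                raise ValueError(f"inverted domain range {lo}-{hi}")
            if prev_hi is not None and lo <= prev_hi:
                raise ValueError("domain ranges overlap")
            prev_hi = hi
        if spans and (spans[0][0] < self.first_label or spans[-1][1] > last):
            raise ValueError("domain ranges fall outside the protein labels")


@dataclass
class PerturbationSpec:
    """Contact-set edit standing in for a chemical perturbation."""

    removed_contacts: list[tuple[int, int]] = field(default_factory=list)
    added_contacts: list[tuple[int, int]] = field(default_factory=list)
    spring_scale: float = 1.0

    def __post_init__(self):
        if self.spring_scale <= 0:
            raise ValueError("spring_scale must be > 0")


def phospho_spec() -> PerturbationSpec:
    """Default phosphorylation mimic: break 44-335, form 44-149.

    Phosphorylation of S44 disrupts the S44-E335 hydrogen bond that locks
    the closed state and creates a new salt bridge to R149 at the D/C
    junction; as a contact edit that is one removal and one addition.
    """
    return PerturbationSpec(removed_contacts=[(44, 335)], added_contacts=[(44, 149)])


# ---------------------------------------------------------------------------
# reference architecture
# ---------------------------------------------------------------------------

# Domain centroids (A) of the synthetic architecture. The catalytic (C)
# subdomain sits centrally with D and N on opposite sides, as in the
# polymerase; the lyase blob sits above D, and the C-terminal tail of the
# N domain reaches across to the lyase bridge site.
# The lyase blob hangs clear of the other domains (surface gaps beyond the
# 12 A spring cutoff) so that its only mechanical attachments are the
# chain linker threading down to the D domain and the 44-335 bridge; the
# perturbation that removes the bridge therefore genuinely mobilises it.
_CENTROIDS = {
    Domain.LYASE: np.array([33.0, 32.0, 0.0]),
    Domain.D: np.array([25.0, 0.0, 0.0]),
    Domain.C: np.array([0.0, 0.0, 0.0]),
    Domain.N: np.array([-25.0, 0.0, 0.0]),
}
_BLOB_RADIUS = {
    Domain.LYASE: 10.0,
    Domain.D: 10.0,
    Domain.C: 13.0,
    Domain.N: 11.0,
}

_BRIDGE_44 = np.array([14.0, 24.0, 0.0])
# The bridge bond points along the lyase pendulum's in-plane swing
# direction (perpendicular to the hinge->44 radius), so it is the one
# spring that braces the swing; the tail tip it anchors to lies against
# the C-domain surface and is itself well braced.
_U_BRIDGE = np.array([-0.5547, -0.8321, 0.0])
# 335 approaches 44 radially from outside the lyase blob, 11 A away (just
# inside the 12 A spring cutoff); its chain predecessor sits a further bond
# outward and the bridge-flanking lyase residues a bond backward, so the only
# lyase/N contact inside the cutoff is the 44-335 pair itself.
_BRIDGE_335 = _BRIDGE_44 + 11.0 * _U_BRIDGE
_U_PERP = np.array([-0.8321, 0.5547, 0.0])
_Z = np.array([0.0, 0.0, 1.0])

# Pinned anchors (residue label -> exact target point) shaping the default chain.
_LYASE_EDGE = _CENTROIDS[Domain.LYASE] + 10.0 * np.array([-0.9217, -0.3880, 0.0])
_PINS = {
    10: np.array([36.0, 38.0, 2.0]),
    41: _LYASE_EDGE + np.array([0.0, 0.5, 0.0]),
    43: _BRIDGE_44 - 3.8 * (0.85 * _U_BRIDGE - 0.45 * _U_PERP - 0.28 * _Z),
    44: _BRIDGE_44,
    45: _BRIDGE_44 - 3.8 * (0.85 * _U_BRIDGE + 0.45 * _U_PERP + 0.28 * _Z),
    47: _LYASE_EDGE + np.array([0.5, -0.9, 1.2]),
    87: np.array([32.0, 12.0, 0.0]),
    90: np.array([30.0, 7.0, 0.0]),
    149: np.array([14.0, 0.0, 0.0]),
    151: np.array([12.0, -4.0, 0.0]),
    260: np.array([-14.0, 0.0, 0.0]),
    261: np.array([-17.0, 0.0, 0.0]),
    326: np.array([-14.0, 8.0, 6.0]),
    331: np.array([-3.0, 14.0, 3.0]),
    333: _BRIDGE_335 + 3.8 * (1.6 * _U_BRIDGE - 0.45 * _Z),
    334: _BRIDGE_335 + 3.8 * (0.75 * _U_BRIDGE + 0.55 * _Z),
    335: _BRIDGE_335,
}

_MIN_SEPARATION = 2.0  # A, self-avoidance radius
_EXACT_PINS = {43, 44, 45, 333, 334, 335}  # pins that define the lyase/N bridge
_MAX_RETRIES = 60


def make_reference(spec: SyntheticSpec | None = None) -> SiteModel:
    """Deterministic (seeded) synthetic reference complex.

    The protein is a self-avoiding pseudo-chain confined to four domain
    blobs and threaded through pinned anchors; DNA is a 2 x (n/2) double
    helix of P sites (radius 9 A, rise 3.4 A, twist 36 deg, giving the
    requested ~6.5 A P-P spacing) adjacent to the D/C interface. The same
    spec and seed always give identical coordinates.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    labels = list(range(spec.first_label, spec.first_label + spec.n_protein_sites))
    validate = bool(_pin_schedule(labels, spec))
    for _ in range(10):
        coords = _grow_chain(labels, spec, rng)
        sites = [
            Site(
                -1,
                lab,
                "PROT",
                SiteRole.CA,
                assign_domain(lab, spec.domain_ranges),
                coords[k],
            )
            for k, lab in enumerate(labels)
        ]
        sites += _dna_sites(spec)
        model = SiteModel(sites)
        if not validate or _elastically_rigid(model):
            return model
    raise RuntimeError(
        "could not grow a mechanism-free reference after bounded retries; "
        "infeasible geometry"
    )


def _elastically_rigid(model: SiteModel) -> bool:
    """True when the cutoff network (with and without the 44-335 bridge)
    has only the six rigid-body zero modes, i.e. no floppy mechanisms."""
    from .enm import count_zero_modes

    coords = model.reference_coords
    contacts = sorted(contact_pairs(coords))
    if count_zero_modes(coords, contacts) != 6:
        return False
    i44, i335 = model.index_of(44), model.index_of(335)
    bridge = (min(i44, i335), max(i44, i335))
    if bridge in contacts:
        reduced = [p for p in contacts if p != bridge]
        if count_zero_modes(coords, reduced) != 6:
            return False
    return True


def _pin_schedule(labels, spec):
    """Pins applicable to this spec (defaults only fit the full-size chain)."""
    if spec.n_protein_sites < 300 or spec.domain_ranges != DEFAULT_DOMAIN_RANGES:
        return {}
    return {lab: pt for lab, pt in _PINS.items() if lab in set(labels)}


def _centroid_for(label, spec):
    dom = assign_domain(label, spec.domain_ranges)
    if dom in _CENTROIDS:
        return _CENTROIDS[dom], _BLOB_RADIUS[dom]
    return None, None


def _grow_chain(labels, spec, rng) -> np.ndarray:
    n = len(labels)
    pins = _pin_schedule(labels, spec)
    pin_labels = sorted(pins)
    b = spec.ca_bond_length
    coords = np.zeros((n, 3))
    coords[0] = pins.get(labels[0], np.zeros(3))
    k = 1
    backtracks = 0
    while k < n:
        lab = labels[k]
        nxt = next((p for p in pin_labels if p >= lab), None)
        centroid, radius = _centroid_for(lab, spec)
        prev = coords[k - 1]
        ok = False
        for attempt in range(_MAX_RETRIES):
            if lab in pins:
                # pinned residues land on their anchor (the pseudo-bond into
                # a pin may deviate from the nominal length); pins that only
                # shape the fold tolerate jitter when the anchor is occupied,
                # the bridge pins defining the lyase/N interface stay exact
                if np.linalg.norm(pins[lab] - prev) > 2.0 * b:
                    break
                cand = pins[lab].copy()
                if attempt and lab not in _EXACT_PINS:
                    cand = cand + rng.normal(scale=0.3 * min(attempt, 5), size=3)
            else:
                direction = _step_direction(prev, lab, nxt, pins, centroid, radius, b, rng, attempt)
                cand = prev + b * direction
            back = max(0, k - 4)
            sep = _MIN_SEPARATION if attempt < _MAX_RETRIES // 2 else 0.75 * _MIN_SEPARATION
            if back:
                if np.min(np.linalg.norm(coords[:back] - cand, axis=1)) < sep:
                    continue
            if lab not in pins and any(
                p > lab and np.linalg.norm(pins[p] - cand) < 1.1 * _MIN_SEPARATION
                for p in _EXACT_PINS
                if p in pins
            ):
                continue  # keep upcoming exact-pin anchors unobstructed
            if pins and _violates_bridge_standoff(lab, cand, spec):
                continue
            coords[k] = cand
            ok = True
            break
        if ok:
            k += 1
            continue
        # dead end: back out a few residues and regrow along a fresh path
        backtracks += 1
        if backtracks > 1000:
            raise RuntimeError(
                f"could not place residue {lab} without clashes after repeated "
                f"backtracking; infeasible geometry"
            )
        k = max(1, k - 6)
    return coords


def _violates_bridge_standoff(lab, cand, spec):
    # only the 44-335 pair may bridge the lyase and N domains within the
    # spring cutoff; every other residue of either domain keeps clear
    dom = assign_domain(lab, spec.domain_ranges)
    standoff = 12.4
    if dom is Domain.LYASE and lab not in _EXACT_PINS:
        return np.linalg.norm(cand - _BRIDGE_335) < standoff
    if dom is Domain.N and lab not in _EXACT_PINS:
        return np.linalg.norm(cand - _BRIDGE_44) < standoff
    return False


def _step_direction(prev, lab, next_pin, pins, centroid, radius, bond, rng, attempt=0):
    # retries widen the proposal cone so a blocked direction is not re-proposed
    noise = rng.normal(size=3)
    noise /= np.linalg.norm(noise)
    noise = noise * (1.0 + 0.4 * attempt)
    if next_pin is not None:
        target = pins[next_pin]
        gap = target - prev
        dist = np.linalg.norm(gap)
        steps_left = max(next_pin - lab + 1, 1)
        urgency = dist / (bond * steps_left)
        if urgency > 0.75 or steps_left <= 3:
            # head for the pin before it becomes unreachable
            direction = gap / max(dist, 1e-12) * (1.0 + 3.0 * max(urgency, 0.5)) + 0.4 * noise
            return direction / np.linalg.norm(direction)
    pull = np.zeros(3)
    if centroid is not None:
        off = prev - centroid
        r = np.linalg.norm(off)
        if r > radius:
            pull = -off / r * (1.0 + (r - radius) / bond)
    direction = noise + pull
    return direction / np.linalg.norm(direction)


def _dna_sites(spec) -> list[Site]:
    if spec.n_dna_sites == 0:
        return []
    n = spec.n_dna_sites
    n1 = (n + 1) // 2
    # a tight 6-per-turn pseudo-helix: wider helices leave each strand an
    # almost linear single-spring chain with floppy transverse mechanisms
    # under the elastic-network cutoff
    rise, twist_deg = 3.4, 60.0
    chord = np.sqrt(max(spec.p_bond_length**2 - rise**2, 1e-9))
    radius = chord / (2.0 * np.sin(np.radians(twist_deg) / 2.0))
    axis_start = np.array([24.0, -16.0, 0.0])
    axis_dir = np.array([-1.0, 0.0, 0.0])
    e1, e2 = np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0])
    sites = []
    for i in range(n):
        strand2 = i >= n1
        j = (i - n1) if strand2 else i
        # strands offset by the ~154 deg groove asymmetry of B-DNA (a
        # 180 deg offset would superpose sites of a 10-per-turn helix)
        theta = np.radians(twist_deg) * j + (np.radians(154.0) if strand2 else 0.0)
        axial = (n1 - 1 - j) if strand2 else j  # antiparallel second strand
        pt = (
            axis_start
            + axis_dir * rise * axial
            + radius * (np.cos(theta) * e1 + np.sin(theta) * e2)
        )
        sites.append(Site(-1, i + 1, "DNA", SiteRole.P, Domain.DNA, pt))
    return sites


def make_open_reference(
    site_model: SiteModel, angle_deg: float = 18.0
) -> SiteModel:
    """Open-state reference: lyase domain rotated toward the C centroid.

    The closed-to-open transition is emulated as a rigid rotation of the
    lyase sites about a hinge at the lyase/D junction (the last lyase
    residue), about the axis perpendicular to the hinge->lyase-centroid
    and hinge->C-centroid directions, by ``angle_deg``. All other sites
    are unchanged.
    """
    from scipy.spatial.transform import Rotation

    lyase = site_model.domain_indices(Domain.LYASE)
    cdom = site_model.domain_indices(Domain.C)
    if lyase.size == 0 or cdom.size == 0:
        raise ValueError("model lacks lyase or C domain sites")
    coords = site_model.reference_coords
    hinge = coords[lyase[-1]]
    v1 = coords[lyase].mean(axis=0) - hinge
    v2 = coords[cdom].mean(axis=0) - hinge
    axis = np.cross(v1, v2)
    nrm = np.linalg.norm(axis)
    if nrm < 1e-9:
        raise ValueError("degenerate hinge geometry; cannot define rotation axis")
    rot = Rotation.from_rotvec(np.radians(angle_deg) * axis / nrm)
    new_sites = []
    lyset = set(lyase.tolist())
    for s in site_model.sites:
        c = s.reference_coords
        if s.site_id in lyset:
            c = hinge + rot.apply(c - hinge)
        new_sites.append(Site(-1, s.label, s.chain, s.role, s.domain, np.array(c), s.mass))
    return SiteModel(new_sites)


# ---------------------------------------------------------------------------
# ensemble samplers
# ---------------------------------------------------------------------------

def sample_anm_ensemble(
    anm: ANMModel, n_frames: int, kT: float = 1.0, seed: int = 0
) -> Ensemble:
    """Draw i.i.d. frames from the Gaussian with covariance kT * H^+.

    Fluctuations are synthesised in the nonzero mode basis
    (dx = sum_k sqrt(kT/lambda_k) z_k u_k with z_k standard normal) and
    added to the reference, so the sample covariance converges to the
    analytic ANM covariance and contains no rigid-body component.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    nz = np.flatnonzero(anm.eigenvalues > 0.0)
    if nz.size == 0:
        raise ValueError("ANM has no nonzero modes")
    rng = np.random.default_rng(seed)
    n = anm.n_sites
    ref = anm.coords.reshape(-1)
    if kT == 0.0:
        coords = np.tile(ref, (n_frames, 1))
    else:
        amp = np.sqrt(kT / anm.eigenvalues[nz])
        z = rng.standard_normal((n_frames, nz.size))
        coords = ref + (z * amp) @ anm.eigenvectors[:, nz].T
    ens = Ensemble(
        coords.reshape(n_frames, n, 3),
        anm.site_model or _anon_model(anm.coords),
        aligned=True,
    )
    ens.metadata["generator"] = {"kind": "anm_gaussian", "kT": kT, "seed": seed}
    return ens


def _anon_model(coords) -> SiteModel:
    return SiteModel(
        [
            Site(-1, i + 1, "X", SiteRole.CA, None, np.asarray(c, float))
            for i, c in enumerate(coords)
        ]
    )


def sample_two_state(
    reference_a: SiteModel | np.ndarray,
    reference_b: SiteModel | np.ndarray,
    weights: tuple[float, float],
    jitter: float,
    n_frames: int,
    seed: int = 0,
    site_model: SiteModel | None = None,
) -> Ensemble:
    """i.i.d. two-basin mixture with isotropic Gaussian jitter.

    Each frame belongs to basin A with probability ``weights[0]`` and is
    the corresponding reference plus N(0, jitter^2) noise on every
    coordinate. Basin labels are recorded in ``metadata['basin_labels']``.
    """
    ca = reference_a.reference_coords if isinstance(reference_a, SiteModel) else np.asarray(reference_a, float)
    cb = reference_b.reference_coords if isinstance(reference_b, SiteModel) else np.asarray(reference_b, float)
    if ca.shape != cb.shape:
        raise ValueError("basin references have mismatched site counts")
    w = np.asarray(weights, dtype=float)
    if w.size != 2 or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be two non-negatives summing to 1")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    model = site_model or (reference_a if isinstance(reference_a, SiteModel) else _anon_model(ca))
    rng = np.random.default_rng(seed)
    labels = rng.random(n_frames) >= w[0]  # False = basin A
    coords = np.where(labels[:, None, None], cb[None], ca[None]).astype(float)
    if jitter > 0:
        coords = coords + rng.normal(scale=jitter, size=coords.shape)
    ens = Ensemble(coords, model, aligned=True)
    ens.metadata["basin_labels"] = labels.astype(int)
    ens.metadata["generator"] = {
        "kind": "two_state",
        "weights": tuple(w.tolist()),
        "jitter": jitter,
        "seed": seed,
    }
    return ens


# ---------------------------------------------------------------------------
# contact perturbation
# ---------------------------------------------------------------------------

def apply_perturbation(
    contact_set, perturbation: PerturbationSpec, site_model: SiteModel
) -> set[tuple[int, int]]:
    """Apply a contact edit (label pairs) to an index-pair contact set."""
    contacts = {(min(i, j), max(i, j)) for i, j in contact_set}
    for la, lb in perturbation.removed_contacts:
        i, j = site_model.index_of(la), site_model.index_of(lb)
        pair = (min(i, j), max(i, j))
        if pair not in contacts:
            raise ValueError(f"cannot remove absent contact {la}-{lb}")
        contacts.discard(pair)
    for la, lb in perturbation.added_contacts:
        i, j = site_model.index_of(la), site_model.index_of(lb)
        contacts.add((min(i, j), max(i, j)))
    return contacts


def perturbed_anm(
    site_model: SiteModel,
    perturbation: PerturbationSpec,
    cutoff: float = 12.0,
    gamma: float = 1.0,
):
    """Convenience: cutoff contacts of the reference, edited, as an ANM."""
    from .enm import build_anm_from_contacts

    coords = site_model.reference_coords
    contacts = apply_perturbation(contact_pairs(coords, cutoff), perturbation, site_model)
    scales = None
    if perturbation.spring_scale != 1.0:
        touched = []
        for la, lb in perturbation.added_contacts:
            i, j = site_model.index_of(la), site_model.index_of(lb)
            touched.append((min(i, j), max(i, j)))
        scales = {p: perturbation.spring_scale for p in touched}
    return build_anm_from_contacts(
        site_model, coords, contacts, gamma=gamma, spring_scales=scales, cutoff=cutoff
    )


# ---------------------------------------------------------------------------
# scripted hydrogen-bond traces
# ---------------------------------------------------------------------------

#: donor, hydrogen, acceptor positions satisfying the 3.5 A / 30 deg criterion
DEFAULT_GEOMETRY_IN = np.array(
    [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [3.0, 0.3, 0.0]]
)
#: same triple pushed past the distance criterion
DEFAULT_GEOMETRY_OUT = np.array(
    [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [5.5, 0.3, 0.0]]
)


def script_hbond_trace(
    n_frames: int,
    occupancy: float,
    geometry_in: np.ndarray | None = None,
    geometry_out: np.ndarray | None = None,
    seed: int = 0,
) -> Ensemble:
    """Donor/hydrogen/acceptor trace with exact bonded-frame count.

    Exactly ``round(occupancy * n_frames)`` frames adopt ``geometry_in``
    (which must satisfy the hydrogen-bond criterion) and the rest
    ``geometry_out`` (which must violate it); the frame order is a seeded
    permutation. Ground truth is stored in ``metadata['bonded']``.
    """
    from .geometry import HBondCriterion, detect_hbond

    if not 0.0 <= occupancy <= 1.0:
        raise ValueError("occupancy must lie in [0, 1]")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    gi = DEFAULT_GEOMETRY_IN if geometry_in is None else np.asarray(geometry_in, float)
    go = DEFAULT_GEOMETRY_OUT if geometry_out is None else np.asarray(geometry_out, float)
    crit = HBondCriterion()
    if not detect_hbond(gi[0], gi[1], gi[2], crit):
        raise ValueError("geometry_in does not satisfy the H-bond criterion")
    if detect_hbond(go[0], go[1], go[2], crit):
        raise ValueError("geometry_out satisfies the H-bond criterion")
    n_bonded = int(round(occupancy * n_frames))
    bonded = np.zeros(n_frames, dtype=bool)
    bonded[:n_bonded] = True
    rng = np.random.default_rng(seed)
    rng.shuffle(bonded)
    coords = np.where(bonded[:, None, None], gi[None], go[None])
    model = SiteModel(
        [
            Site(-1, 1, "HB", SiteRole.CA, None, gi[0]),
            Site(-1, 2, "HB", SiteRole.CA, None, gi[1]),
            Site(-1, 3, "HB", SiteRole.CA, None, gi[2]),
        ]
    )
    ens = Ensemble(coords.astype(float), model, aligned=True)
    ens.metadata["bonded"] = bonded
    return ens
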