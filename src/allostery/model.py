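"""Coarse-site data model shared by every analysis stage.

The analyses operate on a coarse representation of a protein/DNA complex:
one site per protein residue (the C-alpha atom) and one site per nucleotide
(the backbone phosphorus). Sites carry a 1-based label matching the source
structure's residue numbering, a role (CA or P) and a domain assignment
(for DNA polymerase beta: lyase domain plus the D, C and N subdomains, and
DNA). Internal indexing is 0-based and stable: index ``i`` refers to the
same site in every matrix produced downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np


class SiteRole(enum.Enum):
    """Atom role a coarse site stands for."""

    CA = "CA"
    P = "P"


class Domain(enum.Enum):
    """Structural domain of DNA polymerase beta, plus DNA."""

    LYASE = "LYASE"
    D = "D"
    C = "C"
    N = "N"
    DNA = "DNA"


#: Protein residue ranges (1-based, inclusive) of the polymerase architecture:
#: lyase domain and the DNA-binding (D), catalytic (C) and nascent-pair (N)
#: subdomains.
DEFAULT_DOMAIN_RANGES: dict[Domain, tuple[int, int]] = {
    Domain.LYASE: (10, 87),
    Domain.D: (90, 150),
    Domain.C: (151, 260),
    Domain.N: (261, 335),
}


def assign_domain(
    label: int, ranges: dict[Domain, tuple[int, int]] | None = None
) -> Domain | None:
    """Domain of a protein residue label, or None for linker residues."""
    ranges = DEFAULT_DOMAIN_RANGES if ranges is None else ranges
    for dom, (lo, hi) in ranges.items():
        if lo <= label <= hi:
            return dom
    return None


@dataclass
class Site:
    site_id: int
    label: int
    chain: str
    role: SiteRole
    domain: Domain | None
    reference_coords: np.ndarray
    mass: float = 1.0


class SiteModel:
    """Ordered collection of coarse sites with a reference geometry.

    Sites are ordered protein-first then DNA; user-facing labels are 1-based
    residue/nucleotide numbers from the source structure, unique per chain.
    """

    def __init__(self, sites: list[Site]):
        if not sites:
            raise ValueError("SiteModel requires at least one site")
        seen: set[tuple[str, int]] = set()
        for s in sites:
            key = (s.chain, s.label)
            if key in seen:
                raise ValueError(f"duplicate site label {s.label} in chain {s.chain}")
            seen.add(key)
            if not np.all(np.isfinite(s.reference_coords)):
                raise ValueError(f"non-finite reference coordinates at site {s.label}")
        self.sites = sites
        for i, s in enumerate(sites):
            s.site_id = i

    # -- basic accessors ---------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def labels(self) -> list[int]:
        return [s.label for s in self.sites]

    @property
    def reference_coords(self) -> np.ndarray:
        return np.array([s.reference_coords for s in self.sites], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([s.mass for s in self.sites], dtype=float)

    @property
    def domains(self) -> list[Domain | None]:
        return [s.domain for s in self.sites]

    @property
    def roles(self) -> list[SiteRole]:
        return [s.role for s in self.sites]

    def domain_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.sites:
            key = s.domain.value if s.domain is not None else "LINKER"
            counts[key] = counts.get(key, 0) + 1
        return counts

    def index_of(self, label: int, chain: str | None = None) -> int:
        """0-based index of the site with the given 1-based label."""
        hits = [
            s.site_id
            for s in self.sites
            if s.label == label and (chain is None or s.chain == chain)
        ]
        if not hits:
            raise KeyError(f"no site with label {label}" + (f" in chain {chain}" if chain else ""))
        if len(hits) > 1:
            # bare residue numbers refer to the protein; DNA sites need an
            # explicit chain
            prot = [
                s.site_id
                for s in self.sites
                if s.label == label and s.chain == "PROT"
            ]
            if len(prot) == 1:
                return prot[0]
            raise KeyError(
                f"label {label} is ambiguous across chains; pass chain explicitly"
            )
        return hits[0]

    def domain_indices(self, domain: Domain) -> np.ndarray:
        return np.array([s.site_id for s in self.sites if s.domain is domain], dtype=int)

    def select(self, expression: str) -> "Selection":
        return Selection(expression).resolve(self)


class Selection:
    """Site selection by domain names, roles and label ranges.

    The expression is a union of whitespace- or comma-separated terms:

    - a domain name: ``LYASE``, ``D``, ``C``, ``N``, ``DNA``
    - a role: ``CA``, ``P``
    - a label or inclusive range on the protein chain: ``44``, ``10-87``
    - ``all``

    Resolution preserves site order and drops duplicates.
    """

    def __init__(self, expression: str):
        self.expression = expression
        self.indices: np.ndarray | None = None

    def resolve(self, model: SiteModel) -> "Selection":
        terms = [t for t in self.expression.replace(",", " ").split() if t]
        if not terms:
            raise ValueError("empty selection expression")
        mask = np.zeros(model.n_sites, dtype=bool)
        domain_names = {d.value for d in Domain}
        role_names = {r.value for r in SiteRole}
        for term in terms:
            t = term.upper()
            if t == "ALL":
                mask[:] = True
            elif t in domain_names:
                dom = Domain(t)
                mask |= np.array([s.domain is dom for s in model.sites])
            elif t in role_names:
                role = SiteRole(t)
                mask |= np.array([s.role is role for s in model.sites])
            else:
                lo, hi = _parse_label_range(term)
                mask |= np.array(
                    [
                        s.role is SiteRole.CA and lo <= s.label <= hi
                        for s in model.sites
                    ]
                )
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"selection {self.expression!r} matches no sites")
        self.indices = idx
        return self


def _parse_label_range(term: str) -> tuple[int, int]:
    try:
        if "-" in term:
            lo_s, hi_s = term.split("-", 1)
            lo, hi = int(lo_s), int(hi_s)
        else:
            lo = hi = int(term)
    except ValueError as exc:
        raise ValueError(f"cannot parse selection term {term!r}") from exc
    if hi < lo:
        raise ValueError(f"inverted label range {term!r}")
    return lo, hi


@dataclass
class Ensemble:
    """Conformational ensemble: frames x sites x 3 coordinates in Angstrom."""

    coords: np.ndarray
    site_model: SiteModel
    times: np.ndarray | None = None
    aligned: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_sites, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("an ensemble needs at least one frame")
        if self.coords.shape[1] != self.site_model.n_sites:
            raise ValueError(
                f"frame site count {self.coords.shape[1]} does not match "
                f"site model ({self.site_model.n_sites})"
            )
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.coords.shape[0],):
                raise ValueError("times must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_sites(self) -> int:
        return self.coords.shape[1]

    def subset(self, indices: np.ndarray) -> np.ndarray:
        """Coordinate view restricted to the given site indices."""
        return self.coords[:, indices, :]
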