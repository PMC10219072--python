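"""Essential dynamics: covariance, cross-correlation, PCA, free-energy maps.

The Cartesian fluctuation covariance Gamma = <dx dx^T> of the aligned
ensemble is the central object. Its per-site 3x3 blocks yield the dynamic
cross-correlation map (DCCM); its eigendecomposition Gamma = U Lambda U^T
yields the principal components (essential modes), whose projections
define free-energy landscapes F = -kT ln(rho / rho_max) over a pair of
reaction coordinates. Cosine content diagnoses whether a projection is
distinguishable from random diffusion; porcupine vectors export a mode's
per-site direction and amplitude for visualisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import align_frames
from .model import Ensemble

__all__ = [
    "CovarianceModel",
    "CorrelationMap",
    "FreeEnergySurface",
    "PCProjection",
    "covariance",
    "covariance_from_matrix",
    "dccm",
    "dccm_from_covariance",
    "map_difference",
    "pca",
    "project",
    "cosine_content",
    "free_energy_landscape",
    "detect_basins",
    "porcupine_vectors",
]


@dataclass
class CovarianceModel:
    """Mean structure plus 3N x 3N fluctuation covariance and eigensystem."""

    mean_coords: np.ndarray
    gamma: np.ndarray
    n_frames_used: int
    eigenvalues: np.ndarray = field(init=False)
    eigenvectors: np.ndarray = field(init=False)

    def __post_init__(self):
        self.gamma = 0.5 * (self.gamma + self.gamma.T)  # enforce symmetry
        evals, evecs = np.linalg.eigh(self.gamma)
        order = np.argsort(evals)[::-1]  # descending
        self.eigenvalues = np.clip(evals[order], 0.0, None)
        self.eigenvectors = evecs[:, order]

    @property
    def n_sites(self) -> int:
        return self.mean_coords.shape[0]

    def block(self, i: int, j: int) -> np.ndarray:
        return self.gamma[3 * i : 3 * i + 3, 3 * j : 3 * j + 3]

    @property
    def variance_fractions(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return self.eigenvalues / tot if tot > 0 else self.eigenvalues


@dataclass
class CorrelationMap:
    matrix: np.ndarray
    kind: str  # DCCM | LMI

    def __post_init__(self):
        m = np.asarray(self.matrix, float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("correlation map must be square")
        self.matrix = m


@dataclass
class FreeEnergySurface:
    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ma.MaskedArray  # kT units, minimum 0, empty bins masked
    kT: float = 1.0

    @property
    def mask(self) -> np.ndarray:
        return np.ma.getmaskarray(self.free_energy)


@dataclass
class PCProjection:
    component_index: int
    values: np.ndarray
    variance_fraction: float
    cosine_content: float | None = None


# ---------------------------------------------------------------------------
# covariance and correlation
# ---------------------------------------------------------------------------

def covariance(ensemble: Ensemble, selection=None, align: bool = True) -> CovarianceModel:
    """Cartesian fluctuation covariance of an ensemble (ML estimator).

    With ``align`` every frame is superposed onto the iteratively refined
    ensemble mean (two passes) before the covariance is accumulated, the
    standard essential-dynamics fit that removes rigid-body motion.
    """
    if ensemble.n_frames < 2:
        raise ValueError("covariance needs at least 2 frames")
    from .geometry import _resolve

    idx = _resolve(selection, ensemble.site_model)
    ens = align_frames(ensemble, idx) if align else ensemble
    x = ens.coords[:, idx, :].reshape(ens.n_frames, -1)
    mean = x.mean(axis=0)
    d = x - mean
    gamma = d.T @ d / ens.n_frames
    return CovarianceModel(mean.reshape(-1, 3), gamma, ens.n_frames)


def covariance_from_matrix(gamma: np.ndarray, mean_coords: np.ndarray) -> CovarianceModel:
    """Wrap an analytic covariance (e.g. kT * H^+ of an ANM)."""
    return CovarianceModel(np.asarray(mean_coords, float), np.asarray(gamma, float), 0)


def dccm_from_covariance(gamma: np.ndarray) -> np.ndarray:
    """DCCM from a 3N x 3N covariance: C_ij = tr G_ij / sqrt(tr G_ii tr G_jj)."""
    gamma = np.asarray(gamma, float)
    n = gamma.shape[0] // 3
    blocks = gamma.reshape(n, 3, n, 3)
    inner = np.einsum("iaja->ij", blocks)  # trace of each 3x3 block
    diag = np.diag(inner).copy()
    if np.any(diag <= 0):
        bad = int(np.flatnonzero(diag <= 0)[0])
        raise ValueError(f"zero fluctuation at site index {bad}")
    c = inner / np.sqrt(np.outer(diag, diag))
    np.fill_diagonal(c, 1.0)
    return c


def dccm(cov: CovarianceModel) -> CorrelationMap:
    """Dynamic cross-correlation map of per-site fluctuation vectors."""
    return CorrelationMap(dccm_from_covariance(cov.gamma), "DCCM")


def map_difference(map_a, map_b) -> np.ndarray:
    """Elementwise difference of two correlation maps (A - B)."""
    a = map_a.matrix if isinstance(map_a, CorrelationMap) else np.asarray(map_a, float)
    b = map_b.matrix if isinstance(map_b, CorrelationMap) else np.asarray(map_b, float)
    if a.shape != b.shape:
        raise ValueError("correlation maps have different shapes")
    return a - b


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(cov: CovarianceModel, n_components: int = 20):
    """Leading essential modes of the covariance, by descending eigenvalue.

    Returns a list of dicts with the eigenvalue, variance fraction,
    cumulative fraction and eigenvector of each requested mode.
    """
    dim = cov.gamma.shape[0]
    if not 1 <= n_components <= dim:
        raise ValueError(f"n_components must lie in [1, {dim}]")
    fracs = cov.variance_fractions
    cum = np.cumsum(fracs)
    return [
        {
            "component": k,
            "eigenvalue": float(cov.eigenvalues[k]),
            "variance_fraction": float(fracs[k]),
            "cumulative_fraction": float(cum[k]),
            "eigenvector": cov.eigenvectors[:, k],
        }
        for k in range(n_components)
    ]


def project(ensemble: Ensemble, cov: CovarianceModel, component: int) -> PCProjection:
    """Per-frame projection of mean-free coordinates onto one eigenvector.

    The ensemble must be aligned consistently with the covariance fit; the
    variance of the projection then equals the mode eigenvalue.
    """
    dim = cov.gamma.shape[0]
    if not 0 <= component < dim:
        raise ValueError(f"component {component} out of range")
    x = ensemble.coords.reshape(ensemble.n_frames, -1)
    if x.shape[1] != dim:
        raise ValueError("ensemble and covariance dimensions differ")
    d = x - cov.mean_coords.reshape(-1)
    vals = d @ cov.eigenvectors[:, component]
    return PCProjection(component, vals, float(cov.variance_fractions[component]))


def cosine_content(projection, k: int = 1) -> float:
    """Cosine content c_k of a projection time series (uniform spacing).

    c_k = (2/T) (integral of cos(k pi t / T) p(t) dt)^2 / integral p^2 dt,
    evaluated by discrete quadrature; 1 means the projection is a pure
    half-cosine (random-diffusion-like), small values mean genuine
    conformational sampling.
    """
    p = projection.values if isinstance(projection, PCProjection) else np.asarray(projection, float)
    n = p.size
    if n < 2:
        raise ValueError("cosine content needs at least 2 frames")
    denom = float(p @ p)
    if denom == 0.0:
        raise ValueError("zero-variance projection")
    t = np.arange(n) / (n - 1)
    c = np.cos(k * np.pi * t)
    return float(2.0 * (c @ p) ** 2 / (n * denom))


# ---------------------------------------------------------------------------
# free-energy landscapes
# ---------------------------------------------------------------------------

def free_energy_landscape(
    x_series, y_series, n_bins: int = 50, kT: float = 1.0, range=None
) -> FreeEnergySurface:
    """2-D free-energy surface F = -kT ln(count / max_count).

    Bins with no samples are masked; the minimum over populated bins is
    exactly 0 by construction. ``range`` optionally fixes the bin span
    ((xmin, xmax), (ymin, ymax)) instead of the data extent.
    """
    x = np.asarray(x_series, float)
    y = np.asarray(y_series, float)
    if x.shape != y.shape:
        raise ValueError("reaction-coordinate series have different lengths")
    if np.isscalar(n_bins):
        if n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        bins = (int(n_bins), int(n_bins))
    else:
        bins = tuple(int(b) for b in n_bins)
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=bins, range=range)
    empty = counts == 0
    with np.errstate(divide="ignore"):
        f = -kT * np.log(counts / counts.max())
    surface = np.ma.masked_array(np.where(empty, 0.0, f), mask=empty)
    return FreeEnergySurface(x_edges, y_edges, surface, kT)


def detect_basins(surface: FreeEnergySurface, depth_threshold: float = np.inf):
    """Locate free-energy basins on a surface.

    Local minima (8-connected, strictly no lower unmasked neighbour) with
    F below ``depth_threshold`` seed basins; every other unmasked bin is
    assigned by steepest descent. Returns a list of basins sorted by
    increasing minimum free energy (ties broken by x- then y-bin index),
    each ``{label, bin, x, y, free_energy, n_bins}``, plus a degenerate
    flag when the surface is flat.
    """
    f = surface.free_energy
    mask = surface.mask
    if mask.all():
        raise ValueError("surface has no populated bins")
    nx, ny = f.shape
    filled = np.where(mask, np.inf, np.asarray(f))

    def neighbours(i, j):
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                a, b = i + di, j + dj
                if 0 <= a < nx and 0 <= b < ny:
                    yield a, b

    # steepest-descent target of every populated bin
    descend = {}
    minima = []
    for i in range(nx):
        for j in range(ny):
            if mask[i, j]:
                continue
            best, best_val = (i, j), filled[i, j]
            for a, b in neighbours(i, j):
                if filled[a, b] < best_val or (
                    filled[a, b] == best_val and (a, b) < best
                ):
                    best, best_val = (a, b), filled[a, b]
            descend[(i, j)] = best
            if best == (i, j):
                minima.append((i, j))
    minima = [m for m in minima if filled[m] <= depth_threshold]
    if not minima:  # flat or above-threshold surface: one degenerate basin
        lowest = min(descend, key=lambda ij: (filled[ij], ij))
        minima = [lowest]
    assignment = {}

    def root(cell):
        path = []
        while descend[cell] != cell and cell not in assignment:
            path.append(cell)
            cell = descend[cell]
        target = assignment.get(cell, cell)
        for p in path:
            assignment[p] = target
        return target

    counts = {m: 0 for m in minima}
    for cell in descend:
        r = root(cell)
        if r in counts:
            counts[r] += 1
    order = sorted(minima, key=lambda ij: (filled[ij], ij))
    xc = 0.5 * (surface.x_edges[:-1] + surface.x_edges[1:])
    yc = 0.5 * (surface.y_edges[:-1] + surface.y_edges[1:])
    basins = [
        {
            "label": k + 1,
            "bin": m,
            "x": float(xc[m[0]]),
            "y": float(yc[m[1]]),
            "free_energy": float(filled[m]),
            "n_bins": counts[m],
            "degenerate": len(minima) == 1 and np.allclose(filled[~mask], filled[minima[0]]),
        }
        for k, m in enumerate(order)
    ]
    return basins


# ---------------------------------------------------------------------------
# porcupine vectors
# ---------------------------------------------------------------------------

def porcupine_vectors(
    cov: CovarianceModel, component: int = 0, scale: float = 1.0, min_length: float = 0.0
):
    """Per-site arrows depicting one essential mode on the mean structure.

    Each arrow is the site's 3-vector segment of the eigenvector times
    ``scale``, anchored at the mean coordinates; arrows shorter than
    ``min_length`` are suppressed.
    """
    dim = cov.gamma.shape[0]
    if not 0 <= component < dim:
        raise ValueError(f"component {component} out of range")
    vec = cov.eigenvectors[:, component].reshape(-1, 3) * scale
    lengths = np.linalg.norm(vec, axis=1)
    arrows = []
    for i, (anchor, v, ln) in enumerate(zip(cov.mean_coords, vec, lengths)):
        if ln >= min_length and ln > 0.0:
            arrows.append(
                {"site_index": i, "anchor": anchor.copy(), "vector": v.copy(), "length": float(ln)}
            )
    return arrows
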