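"""LMI correlation, weighted residue networks and betweenness centrality.

Linear mutual information (LMI) between the 3-D fluctuation vectors of two
sites, I = 1/2 [ln det C_ii + ln det C_jj - ln det C_(ij)], is mapped to
the generalized correlation r = sqrt(1 - exp(-2I/3)) in [0, 1], which
captures couplings a Pearson-based DCCM misses (e.g. orthogonal but
coupled motions). Edges between contacting sites are weighted
w = -ln r so stronger coupling means a shorter path; betweenness
centrality BC(i) — the fraction of all-pairs shortest paths crossing a
node — then ranks sites on the information pathway, and the normalized
BC difference between a perturbed and a reference system flags sites that
gain or lose importance (|dBC| > 0.1 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .model import SiteModel

__all__ = [
    "LMIResult",
    "ResidueNetwork",
    "lmi_matrix",
    "lmi_from_covariance",
    "build_network",
    "betweenness",
    "bc_difference",
]

DEFAULT_EDGE_CUTOFF = 10.0  # A, mean-structure contact distance for edges
DEFAULT_EDGE_PERSISTENCE = 0.75  # fraction of frames a contact must persist
DEFAULT_FLAG_THRESHOLD = 0.1  # |dBC| above this is reported


@dataclass
class LMIResult:
    mutual_information: np.ndarray  # nats, symmetric, >= 0 off-diagonal
    generalized_correlation: np.ndarray  # in [0, 1], diagonal 1


@dataclass
class ResidueNetwork:
    graph: nx.Graph
    site_model: SiteModel | None = None
    bc: dict | None = None
    normalized: bool = True
    connected: bool = field(init=False)

    def __post_init__(self):
        self.connected = (
            nx.is_connected(self.graph) if self.graph.number_of_nodes() else False
        )

    @property
    def nodes(self):
        return list(self.graph.nodes)


# ---------------------------------------------------------------------------
# linear mutual information
# ---------------------------------------------------------------------------

def lmi_from_covariance(gamma: np.ndarray) -> LMIResult:
    """LMI and generalized correlation from a 3N x 3N fluctuation covariance.

    Uses the 3x3 marginal blocks C_ii and 6x6 joint blocks C_(ij); a
    singular marginal block is an error naming the site.
    """
    gamma = np.asarray(gamma, float)
    n = gamma.shape[0] // 3
    logdet_marg = np.empty(n)
    for i in range(n):
        cii = gamma[3 * i : 3 * i + 3, 3 * i : 3 * i + 3]
        sign, logdet = np.linalg.slogdet(cii)
        if sign <= 0:
            raise ValueError(f"singular marginal covariance block at site index {i}")
        logdet_marg[i] = logdet
    mi = np.zeros((n, n))
    for i in range(n):
        bi = slice(3 * i, 3 * i + 3)
        for j in range(i + 1, n):
            bj = slice(3 * j, 3 * j + 3)
            joint = np.empty((6, 6))
            joint[:3, :3] = gamma[bi, bi]
            joint[3:, 3:] = gamma[bj, bj]
            joint[:3, 3:] = gamma[bi, bj]
            joint[3:, :3] = gamma[bj, bi]
            sign, logdet_joint = np.linalg.slogdet(joint)
            if sign <= 0:  # numerically deterministic dependence
                val = np.inf
            else:
                val = 0.5 * (logdet_marg[i] + logdet_marg[j] - logdet_joint)
            mi[i, j] = mi[j, i] = max(val, 0.0)
    r = np.sqrt(1.0 - np.exp(-2.0 * mi / 3.0))
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(mi, np.inf)
    return LMIResult(mi, r)


def lmi_matrix(cov) -> LMIResult:
    """LMI of a CovarianceModel (see :func:`lmi_from_covariance`)."""
    return lmi_from_covariance(cov.gamma)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def build_network(
    correlation: np.ndarray,
    contacts=None,
    site_model: SiteModel | None = None,
    weight_rule: str = "-ln r",
) -> ResidueNetwork:
    """Weighted residue network from a correlation matrix.

    Edges are restricted to ``contacts`` (iterable of index pairs; pass
    None for the fully dense network) and weighted ``-ln r`` so strong
    coupling means short paths. Edges with r = 0 are dropped with a
    warning; r must not exceed 1. A disconnected graph is allowed and
    flagged on the returned network.
    """
    c = np.asarray(correlation, float)
    n = c.shape[0]
    if contacts is None:
        contacts = [(i, j) for i in range(n) for j in range(i + 1, n)]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    dropped = 0
    for i, j in contacts:
        if i == j:
            continue
        r = float(c[i, j])
        if weight_rule == "-ln r":
            r = abs(r)
        elif weight_rule == "-ln |c|":
            r = abs(r)
        else:
            raise ValueError(f"unknown weight rule {weight_rule!r}")
        if r > 1.0 + 1e-9:
            raise ValueError(f"correlation {r} > 1 on edge ({i}, {j})")
        if r <= 0.0:
            dropped += 1
            continue
        g.add_edge(int(i), int(j), weight=max(-np.log(min(r, 1.0)), 0.0))
    if dropped:
        warnings.warn(f"dropped {dropped} edges with zero correlation", stacklevel=2)
    return ResidueNetwork(g, site_model=site_model)


def persistent_contacts(ensemble, cutoff=DEFAULT_EDGE_CUTOFF, persistence=DEFAULT_EDGE_PERSISTENCE):
    """Index pairs within ``cutoff`` in at least ``persistence`` of frames."""
    coords = ensemble.coords
    n = coords.shape[1]
    frac = np.zeros((n, n))
    for frame in coords:
        d = np.linalg.norm(frame[:, None, :] - frame[None, :, :], axis=2)
        frac += d <= cutoff
    frac /= coords.shape[0]
    i, j = np.nonzero(np.triu(frac >= persistence, k=1))
    return list(zip(i.tolist(), j.tolist()))


# ---------------------------------------------------------------------------
# betweenness centrality
# ---------------------------------------------------------------------------

def betweenness(network: ResidueNetwork, normalized: bool = True) -> np.ndarray:
    """Weighted shortest-path betweenness centrality per node.

    Degenerate shortest paths are counted fractionally (Brandes);
    endpoints are excluded; normalization divides by (n-1)(n-2)/2.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    bc = nx.betweenness_centrality(g, normalized=normalized, weight="weight")
    network.bc = bc
    network.normalized = normalized
    return np.array([bc[v] for v in sorted(g.nodes)])


def bc_difference(
    network_a: ResidueNetwork,
    network_b: ResidueNetwork,
    flag_threshold: float = DEFAULT_FLAG_THRESHOLD,
):
    """Per-node normalized BC difference (A - B) with flagged sites.

    Returns ``(delta, flags)``: ``delta`` is the per-node array of
    BC_a - BC_b on normalized values, and ``flags`` lists records
    ``{site_index, label, domain, delta}`` for |delta| > threshold,
    sorted by descending |delta|. Node sets must match.
    """
    ga, gb = network_a.graph, network_b.graph
    if set(ga.nodes) != set(gb.nodes):
        raise ValueError("networks have different node sets")
    bca = betweenness(network_a, normalized=True)
    bcb = betweenness(network_b, normalized=True)
    delta = bca - bcb
    model = network_a.site_model or network_b.site_model
    flags = []
    for i in np.argsort(-np.abs(delta)):
        if abs(delta[i]) <= flag_threshold:
            break
        rec = {"site_index": int(i), "delta": float(delta[i])}
        if model is not None:
            site = model.sites[int(i)]
            rec["label"] = site.label
            rec["domain"] = site.domain.value if site.domain else "LINKER"
        flags.append(rec)
    return delta, flags
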