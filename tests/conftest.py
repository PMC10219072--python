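"""Shared fixtures: small site models, random structures, tiny ensembles."""

import numpy as np
import pytest

from allostery.model import Ensemble, Site, SiteModel, SiteRole


def make_sites(coords, labels=None, chain="PROT", role=SiteRole.CA, domain=None):
    coords = np.asarray(coords, dtype=float)
    labels = labels or list(range(1, len(coords) + 1))
    return SiteModel(
        [Site(-1, lab, chain, role, domain, c) for lab, c in zip(labels, coords)]
    )


@pytest.fixture
def square_model():
    """Four equal-mass sites on the unit square corners (z = 0)."""
    return make_sites([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_connected_coords(n, rng, cutoff=12.0, box=None, min_sep=3.0):
    """Random point cloud whose cutoff contact graph is elastically rigid.

    Density defaults to roughly one site per 150 A^3 (protein-like), which
    keeps the spring network well conditioned.
    """
    from allostery.enm import contact_pairs, count_zero_modes

    if box is None:
        box = (n * 150.0) ** (1.0 / 3.0)
    while True:
        pts = []
        while len(pts) < n:
            cand = rng.uniform(0, box, size=3)
            if not pts or np.min(np.linalg.norm(np.asarray(pts) - cand, axis=1)) >= min_sep:
                pts.append(cand)
        coords = np.asarray(pts)
        if count_zero_modes(coords, sorted(contact_pairs(coords, cutoff))) == 6:
            return coords


def static_ensemble(model, n_frames=5):
    coords = np.tile(model.reference_coords, (n_frames, 1, 1))
    return Ensemble(coords, model)
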