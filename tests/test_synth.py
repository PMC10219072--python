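"""Synthetic ensemble generators and their ground-truth guarantees."""

import numpy as np
import pytest

from allostery import synth
from allostery.enm import build_anm, contact_pairs
from allostery.model import Domain
from allostery.synth import (
    PerturbationSpec,
    SyntheticSpec,
    apply_perturbation,
    make_open_reference,
    make_reference,
    phospho_spec,
    sample_anm_ensemble,
    sample_two_state,
    script_hbond_trace,
)
from conftest import random_connected_coords


@pytest.fixture(scope="module")
def default_ref():
    return make_reference(SyntheticSpec(seed=1))


class TestMakeReference:
    def test_default_site_and_domain_counts(self, default_ref):
        assert default_ref.n_sites == 354
        counts = default_ref.domain_counts()
        assert counts["LYASE"] == 78
        assert counts["D"] == 61
        assert counts["C"] == 110
        assert counts["N"] == 75
        assert counts["DNA"] == 28

    def test_same_seed_identical_coordinates(self):
        a = make_reference(SyntheticSpec(seed=3))
        b = make_reference(SyntheticSpec(seed=3))
        np.testing.assert_array_equal(a.reference_coords, b.reference_coords)

    def test_different_seeds_differ(self):
        a = make_reference(SyntheticSpec(seed=3))
        b = make_reference(SyntheticSpec(seed=4))
        assert not np.allclose(a.reference_coords, b.reference_coords)

    def test_small_chain_without_dna(self):
        spec = SyntheticSpec(n_protein_sites=3, n_dna_sites=0, first_label=1,
                             domain_ranges={})
        model = make_reference(spec)
        assert model.n_sites == 3
        bonds = np.linalg.norm(np.diff(model.reference_coords, axis=0), axis=1)
        np.testing.assert_allclose(bonds, 3.8, atol=1e-9)

    def test_bridge_is_only_lyase_N_contact(self, default_ref):
        """The 44-335 pair is the single lyase/N contact inside the spring
        cutoff — the designed closed-state lock of the architecture."""
        pairs = contact_pairs(default_ref.reference_coords, 12.0)
        doms = default_ref.domains
        bridge = [
            tuple(sorted((default_ref.labels[i], default_ref.labels[j])))
            for i, j in pairs
            if {doms[i], doms[j]} == {Domain.LYASE, Domain.N}
        ]
        assert bridge == [(44, 335)]

    def test_network_is_elastically_rigid(self, default_ref):
        anm = build_anm(default_ref)
        assert anm.n_zero_modes == 6

    def test_dna_strand_spacing(self, default_ref):
        coords = default_ref.reference_coords[326:]
        strand1 = coords[:14]
        bonds = np.linalg.norm(np.diff(strand1, axis=0), axis=1)
        np.testing.assert_allclose(bonds, 6.5, atol=0.01)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(n_protein_sites=0)
        with pytest.raises(ValueError, match="overlap"):
            SyntheticSpec(domain_ranges={Domain.LYASE: (10, 90), Domain.D: (88, 150),
                                         Domain.C: (151, 260), Domain.N: (261, 335)})


class TestOpenReference:
    def test_only_lyase_moves(self, default_ref):
        open_ref = make_open_reference(default_ref, angle_deg=15.0)
        a = default_ref.reference_coords
        b = open_ref.reference_coords
        ly = default_ref.domain_indices(Domain.LYASE)
        others = np.setdiff1d(np.arange(354), ly)
        np.testing.assert_array_equal(a[others], b[others])
        assert np.linalg.norm(a[ly] - b[ly], axis=1).max() > 1.0

    def test_rotation_is_rigid(self, default_ref):
        open_ref = make_open_reference(default_ref, angle_deg=20.0)
        ly = default_ref.domain_indices(Domain.LYASE)
        from scipy.spatial.distance import pdist

        d0 = pdist(default_ref.reference_coords[ly])
        d1 = pdist(open_ref.reference_coords[ly])
        np.testing.assert_allclose(d0, d1, atol=1e-8)

    def test_lyase_moves_toward_catalytic_centroid(self, default_ref):
        open_ref = make_open_reference(default_ref, angle_deg=18.0)
        ly = default_ref.domain_indices(Domain.LYASE)
        cy = default_ref.domain_indices(Domain.C)
        c_cent = default_ref.reference_coords[cy].mean(axis=0)
        d0 = np.linalg.norm(default_ref.reference_coords[ly].mean(axis=0) - c_cent)
        d1 = np.linalg.norm(open_ref.reference_coords[ly].mean(axis=0) - c_cent)
        assert d1 < d0


class TestAnmSampling:
    def test_kT_zero_reproduces_reference(self, rng):
        coords = random_connected_coords(10, rng)
        anm = build_anm(coords)
        ens = sample_anm_ensemble(anm, 5, kT=0.0, seed=1)
        for frame in ens.coords:
            np.testing.assert_array_equal(frame, coords)

    def test_same_seed_bit_identical(self, rng):
        coords = random_connected_coords(10, rng)
        anm = build_anm(coords)
        a = sample_anm_ensemble(anm, 20, kT=1.0, seed=9)
        b = sample_anm_ensemble(anm, 20, kT=1.0, seed=9)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_sample_covariance_converges_to_analytic(self, rng):
        coords = random_connected_coords(12, rng)
        anm = build_anm(coords)
        target = anm.covariance(kT=1.0)
        ens = sample_anm_ensemble(anm, 30_000, kT=1.0, seed=2)
        x = ens.coords.reshape(ens.n_frames, -1)
        d = x - x.mean(axis=0)
        sample = d.T @ d / ens.n_frames
        rel = np.linalg.norm(sample - target) / np.linalg.norm(target)
        assert rel < 0.05

    def test_frame_count_validated(self, rng):
        anm = build_anm(random_connected_coords(8, rng))
        with pytest.raises(ValueError):
            sample_anm_ensemble(anm, 0)


class TestTwoState:
    def test_occupancy_within_binomial_error(self, rng):
        ref_a = rng.normal(size=(5, 3))
        ref_b = ref_a + 5.0
        n = 100_000
        ens = sample_two_state(ref_a, ref_b, (0.8, 0.2), jitter=0.0, n_frames=n, seed=4)
        frac_a = 1.0 - ens.metadata["basin_labels"].mean()
        # 5 sigma binomial band around 0.8
        assert abs(frac_a - 0.8) < 5 * np.sqrt(0.8 * 0.2 / n)

    def test_degenerate_weights_all_one_basin(self, rng):
        ref_a = rng.normal(size=(4, 3))
        ens = sample_two_state(ref_a, ref_a + 1.0, (1.0, 0.0), 0.0, 50, seed=1)
        assert ens.metadata["basin_labels"].sum() == 0

    def test_zero_jitter_frames_exactly_at_references(self, rng):
        ref_a = rng.normal(size=(4, 3))
        ref_b = ref_a + 2.0
        ens = sample_two_state(ref_a, ref_b, (0.5, 0.5), 0.0, 200, seed=2)
        labels = ens.metadata["basin_labels"]
        np.testing.assert_array_equal(ens.coords[labels == 0],
                                      np.tile(ref_a, (int((labels == 0).sum()), 1, 1)))
        np.testing.assert_array_equal(ens.coords[labels == 1],
                                      np.tile(ref_b, (int((labels == 1).sum()), 1, 1)))

    def test_pc1_aligns_with_interbasin_vector(self, rng):
        from allostery.essential import covariance

        ref_a = rng.normal(size=(10, 3)) * 4
        disp = rng.normal(size=(10, 3))
        disp /= np.linalg.norm(disp)
        ref_b = ref_a + 6.0 * disp
        ens = sample_two_state(ref_a, ref_b, (0.5, 0.5), jitter=0.05,
                               n_frames=5000, seed=6)
        cov = covariance(ens, align=False)
        pc1 = cov.eigenvectors[:, 0]
        cos = abs(pc1 @ (6.0 * disp).ravel()) / 6.0
        assert cos > 0.99

    def test_mismatched_references_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_two_state(np.zeros((3, 3)), np.zeros((4, 3)), (0.5, 0.5), 0.1, 10)
        with pytest.raises(ValueError, match="weights"):
            sample_two_state(np.zeros((3, 3)), np.zeros((3, 3)), (0.5, 0.4), 0.1, 10)


class TestPerturbation:
    def test_default_phospho_edit(self, default_ref):
        contacts = contact_pairs(default_ref.reference_coords, 12.0)
        edited = apply_perturbation(contacts, phospho_spec(), default_ref)
        i44 = default_ref.index_of(44)
        i335 = default_ref.index_of(335)
        i149 = default_ref.index_of(149)
        assert (min(i44, i335), max(i44, i335)) not in edited
        assert (min(i44, i149), max(i44, i149)) in edited

    def test_empty_spec_is_identity(self, default_ref):
        contacts = contact_pairs(default_ref.reference_coords, 12.0)
        edited = apply_perturbation(contacts, PerturbationSpec(), default_ref)
        assert edited == {(min(i, j), max(i, j)) for i, j in contacts}

    def test_add_then_remove_roundtrip(self, default_ref):
        contacts = contact_pairs(default_ref.reference_coords, 12.0)
        start = {(min(i, j), max(i, j)) for i, j in contacts}
        added = apply_perturbation(start, PerturbationSpec(added_contacts=[(20, 200)]),
                                   default_ref)
        back = apply_perturbation(added, PerturbationSpec(removed_contacts=[(20, 200)]),
                                  default_ref)
        assert back == start

    def test_removing_absent_contact_rejected(self, default_ref):
        contacts = contact_pairs(default_ref.reference_coords, 12.0)
        with pytest.raises(ValueError, match="absent"):
            apply_perturbation(contacts, PerturbationSpec(removed_contacts=[(10, 260)]),
                               default_ref)

    def test_spring_scale_validated(self):
        with pytest.raises(ValueError):
            PerturbationSpec(spring_scale=0.0)


class TestHbondTrace:
    def test_exact_bonded_count(self):
        ens = script_hbond_trace(100, 0.4, seed=1)
        assert ens.metadata["bonded"].sum() == 40

    def test_rounding_of_occupancy(self):
        ens = script_hbond_trace(10, 0.25, seed=1)
        assert ens.metadata["bonded"].sum() == round(0.25 * 10)

    def test_seed_permutes_order_only(self):
        a = script_hbond_trace(50, 0.5, seed=1)
        b = script_hbond_trace(50, 0.5, seed=2)
        assert a.metadata["bonded"].sum() == b.metadata["bonded"].sum()
        assert not np.array_equal(a.metadata["bonded"], b.metadata["bonded"])

    def test_invalid_geometries_rejected(self):
        good = synth.DEFAULT_GEOMETRY_IN
        bad = synth.DEFAULT_GEOMETRY_OUT
        with pytest.raises(ValueError, match="geometry_in"):
            script_hbond_trace(10, 0.5, geometry_in=bad)
        with pytest.raises(ValueError, match="geometry_out"):
            script_hbond_trace(10, 0.5, geometry_out=good)

    def test_occupancy_bounds(self):
        with pytest.raises(ValueError):
            script_hbond_trace(10, 1.5)
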