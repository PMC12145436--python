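"""Spin permutations and eigenmode surrogates."""

import numpy as np
import pytest

from brainkrig import (
    SurfaceMap,
    SynthesisSpec,
    binned_variogram,
    eigenstrap,
    spin_ensemble,
    spin_null,
    spin_rotate,
    surrogate_pvalue,
    synth_map,
    synth_networks,
)
from brainkrig.nulls import (
    _eigengroups,
    _surrogate_values,
    random_rotation,
)


class TestRotations:
    def test_haar_mean_direction_vanishes(self, rng):
        v = np.array([1.0, 0.0, 0.0])
        images = np.array([random_rotation(rng) @ v for _ in range(1000)])
        assert np.linalg.norm(images.mean(axis=0)) < 0.1

    def test_proper_orthogonal(self, rng):
        for _ in range(20):
            r = random_rotation(rng)
            assert np.allclose(r @ r.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(r) == pytest.approx(1.0)


class TestSpinRotate:
    def test_identity_leaves_labels_unchanged(self, ico3):
        labels = synth_networks(ico3, 4, seed=0)
        assert np.array_equal(spin_rotate(ico3, labels, np.eye(3)), labels)

    def test_rotation_then_inverse_roundtrips(self, ico3, rng):
        labels = synth_networks(ico3, 4, seed=0)
        r = random_rotation(rng)
        there = spin_rotate(ico3, labels, r)
        back = spin_rotate(ico3, there, r.T)
        # nearest-neighbor reassignment is not exactly bijective on an
        # irregular mesh; demand near-total agreement
        assert np.mean(back == labels) > 0.95

    def test_label_counts_approximately_preserved(self, ico4, rng):
        labels = synth_networks(ico4, 4, seed=1)
        base = np.bincount(labels, minlength=5)[1:]
        for _ in range(100):
            rotated = spin_rotate(ico4, labels, random_rotation(rng))
            counts = np.bincount(rotated, minlength=5)[1:]
            assert np.all(np.abs(counts - base) <= 0.02 * labels.size)

    def test_improper_rotation_rejected(self, ico3):
        labels = np.zeros(ico3.n_vertices, dtype=int)
        flip = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="proper"):
            spin_rotate(ico3, labels, flip)


class TestSpinNull:
    CFG = {"n_levels": 1, "base_subdivision": 1, "alpha": (1.0,),
           "lam": 0.1}

    def test_ensemble_reproducible_from_seed(self, ico2):
        labels = synth_networks(ico2, 3, seed=2)
        a = spin_ensemble(ico2, labels, 5, seed=9)
        b = spin_ensemble(ico2, labels, 5, seed=9)
        assert np.array_equal(a.rotated_labels, b.rotated_labels)

    def test_pvalues_and_corrections(self, ico3, basis3):
        smap = synth_map(
            ico3,
            SynthesisSpec(spectrum_decay=3.0, n_modes=60, seed=4),
            basis=basis3,
        )
        labels = synth_networks(ico3, 3, seed=5)
        table, nulls = spin_null(smap, labels, n=100, seed=0,
                                 lattice_config=self.CFG, min_size=20)
        assert len(table) == 3
        assert ((table["p"] > 0) & (table["p"] <= 1)).all()
        assert (table["p_bonferroni"] >= table["p"] - 1e-15).all()
        assert (table["p_fdr"] >= table["p"] - 1e-15).all()
        assert all(len(nulls[k]) == 100 for k in nulls)

    def test_requires_enough_rotations(self, smooth_map3):
        labels = synth_networks(smooth_map3.mesh, 3, seed=0)
        with pytest.raises(ValueError):
            spin_null(smooth_map3, labels, n=10)


class TestSurrogatePvalue:
    def test_extreme_observation(self):
        nulls = np.linspace(0, 1, 200)
        assert surrogate_pvalue(2.0, nulls) == pytest.approx(1 / 201)

    def test_median_observation_near_half(self):
        nulls = np.linspace(0, 1, 201)
        assert surrogate_pvalue(0.5, nulls) == pytest.approx(0.5, abs=0.01)

    def test_matches_counting_oracle(self, rng):
        nulls = rng.standard_normal(150)
        obs = 0.3
        expected = (1 + np.sum(nulls >= obs)) / 151
        assert surrogate_pvalue(obs, nulls) == expected

    def test_observation_below_all_nulls(self):
        assert surrogate_pvalue(-5.0, np.zeros(100)) == 1.0

    def test_too_few_nulls_rejected(self):
        with pytest.raises(ValueError):
            surrogate_pvalue(0.0, np.zeros(10))


class TestEigengroups:
    def test_degenerate_spectrum_grouped_by_eigenvalue(self):
        vals = np.array([0.0, 2.0, 2.0, 2.0, 6.0, 6.0, 6.0, 6.0, 6.0])
        groups = _eigengroups(vals)
        assert groups == [[0], [1, 2, 3], [4, 5, 6, 7, 8]]

    def test_nondegenerate_spectrum_falls_back_to_harmonic_blocks(self):
        vals = np.arange(13, dtype=float) * 1.7
        groups = _eigengroups(vals)
        assert groups[0] == [0]
        assert [len(g) for g in groups[1:]] == [3, 5, 4]


class TestEigenstrap:
    def test_identity_rotations_recover_map(self, ico3, basis3):
        smap = synth_map(
            ico3,
            SynthesisSpec(spectrum_decay=3.0, n_modes=100, noise_sd=0.0,
                          seed=6),
            basis=basis3,
        )
        groups = _eigengroups(basis3.eigenvalues)
        rotations = [None] * len(groups)
        rec = _surrogate_values(smap.values, basis3, rotations, groups,
                                ico3.valid_mask)
        # the map lives in the basis span, so projection is lossless
        assert np.allclose(rec, smap.values, atol=1e-8)

    def test_resample_preserves_value_multiset_exactly(self, ico3, basis3,
                                                       smooth_map3):
        ens = eigenstrap(smooth_map3, basis3, n=5, seed=1, resample=True)
        orig = np.sort(smooth_map3.values[ico3.valid_mask])
        for s in range(5):
            surr = np.sort(ens.surrogate_maps[s][ico3.valid_mask])
            assert np.array_equal(surr, orig)

    def test_deterministic_given_seed(self, basis3, smooth_map3):
        a = eigenstrap(smooth_map3, basis3, n=3, seed=7)
        b = eigenstrap(smooth_map3, basis3, n=3, seed=7)
        assert np.array_equal(a.surrogate_maps, b.surrogate_maps)

    def test_surrogates_decorrelate_content(self, ico3, basis3):
        # a broad spectrum spreads variance over many eigengroups, so the
        # within-group rotations can actually randomize the content
        smap = synth_map(
            ico3,
            SynthesisSpec(spectrum_decay=0.5, n_modes=100, noise_sd=0.05,
                          seed=21),
            basis=basis3,
        )
        ens = eigenstrap(smap, basis3, n=20, seed=2)
        valid = ico3.valid_mask
        rs = [
            abs(np.corrcoef(smap.values[valid],
                            ens.surrogate_maps[s][valid])[0, 1])
            for s in range(20)
        ]
        assert np.mean(rs) < 0.2

    def test_variogram_preserved(self, ico3, basis3):
        # bins start at the basis resolution limit (~pi/9 for 100 modes);
        # below it the truncated projection cannot carry the map's content
        smap = synth_map(
            ico3,
            SynthesisSpec(spectrum_decay=2.0, n_modes=100, noise_sd=0.05,
                          seed=0),
            basis=basis3,
        )
        edges = np.array([0.35, 0.6, 0.9, 1.3, 1.8])
        orig = binned_variogram(ico3, smap.values, edges, seed=0)
        ens = eigenstrap(smap, basis3, n=20, seed=3)
        surr = np.mean(
            [
                binned_variogram(ico3, ens.surrogate_maps[s], edges, seed=0)[
                    "semivariance"
                ]
                for s in range(20)
            ],
            axis=0,
        )
        rel = np.abs(surr - orig["semivariance"]) / orig["semivariance"]
        assert np.all(rel < 0.15)

    def test_basis_mesh_mismatch_rejected(self, ico2, basis3):
        vals = np.zeros(ico2.n_vertices)
        smap = SurfaceMap(vals + np.arange(ico2.n_vertices), ico2)
        with pytest.raises(ValueError, match="match"):
            eigenstrap(smap, basis3, n=2)
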