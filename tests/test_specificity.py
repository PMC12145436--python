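"""Conjunction masks, true-vs-alternative pairwise tests, and per-network
prediction."""

import numpy as np
import pytest

from brainkrig import (
    SurfaceMap,
    SynthesisSpec,
    conjunction_mask,
    krige_from_mask,
    network_prediction,
    pairwise_specificity,
    pairwise_specificity_matrix,
    synth_networks,
    synth_task_family,
    threshold_mask,
)
from brainkrig.pipeline import VertexMask

CFG2 = {"n_levels": 2, "base_subdivision": 1, "alpha": (1.0, 0.25)}


class TestConjunctionMask:
    def test_identical_masks_reproduce_themselves(self, smooth_map3):
        a = threshold_mask(smooth_map3, 0.25)
        conj = conjunction_mask(a, a)
        assert np.array_equal(conj.member_flags, a.member_flags)

    def test_disjoint_masks_error_with_sizes(self):
        a = VertexMask(np.array([True, False, False, False]), "low", 0.25)
        b = VertexMask(np.array([False, True, False, False]), "low", 0.25)
        with pytest.raises(ValueError, match="1"):
            conjunction_mask(a, b)

    def test_intersection_count_matches_set_oracle(self, ico3, basis3):
        spec = SynthesisSpec(spectrum_decay=3.0, n_modes=80, seed=3)
        m1, m2 = synth_task_family(ico3, 2, 0.6, spec, basis=basis3)
        a = threshold_mask(m1, 0.25)
        b = threshold_mask(m2, 0.25)
        conj = conjunction_mask(a, b)
        oracle = set(np.flatnonzero(a.member_flags)) & set(
            np.flatnonzero(b.member_flags)
        )
        assert conj.n_members == len(oracle)

    def test_mixed_tails_rejected(self, smooth_map3):
        a = threshold_mask(smooth_map3, 0.25, "low")
        b = threshold_mask(smooth_map3, 0.25, "high")
        with pytest.raises(ValueError, match="tail"):
            conjunction_mask(a, b)


class TestPairwiseSpecificity:
    def test_identical_maps_tie_exactly(self, smooth_map3):
        dup = SurfaceMap(smooth_map3.values.copy(), smooth_map3.mesh,
                         name="dup")
        rep = pairwise_specificity(smooth_map3, dup, lattice_config=CFG2,
                                   min_conjunction=10)
        assert all(w == "tie" for w in rep.winner.values())
        for r in rep.winner:
            assert rep.rho_true[r] == rep.rho_alt[r]

    def test_true_task_wins_on_correlated_pair(self, ico3, basis3):
        spec = SynthesisSpec(spectrum_decay=3.5, n_modes=80, seed=5)
        m1, m2 = synth_task_family(ico3, 2, 0.6, spec, basis=basis3)
        rep = pairwise_specificity(m1, m2, lattice_config=CFG2,
                                   min_conjunction=10)
        assert rep.winner["all"] == "true"

    def test_reports_are_order_dependent(self, ico3, basis3):
        spec = SynthesisSpec(spectrum_decay=3.5, n_modes=80, seed=6)
        m1, m2 = synth_task_family(ico3, 2, 0.6, spec, basis=basis3)
        ab = pairwise_specificity(m1, m2, lattice_config=CFG2,
                                  min_conjunction=10)
        ba = pairwise_specificity(m2, m1, lattice_config=CFG2,
                                  min_conjunction=10)
        assert ab.task_pair == ("task0", "task1")
        assert ba.task_pair == ("task1", "task0")
        # different target sets -> different out-of-mask counts in general
        assert ab.rho_true["all"] != ba.rho_true["all"]

    def test_too_small_conjunction_rejected(self, ico3, basis3):
        spec = SynthesisSpec(spectrum_decay=3.5, n_modes=80, seed=8)
        m1, m2 = synth_task_family(ico3, 2, 0.6, spec, basis=basis3)
        with pytest.raises(ValueError, match="conjunction"):
            pairwise_specificity(m1, m2, lattice_config=CFG2,
                                 min_conjunction=10_000)

    def test_matrix_covers_all_ordered_pairs(self, ico3, basis3):
        spec = SynthesisSpec(spectrum_decay=3.5, n_modes=80, seed=9)
        maps = synth_task_family(ico3, 3, 0.6, spec, basis=basis3)
        table = pairwise_specificity_matrix(maps, lattice_config=CFG2,
                                            min_conjunction=10)
        # 3 maps -> 6 ordered pairs x 3 restrictions
        assert len(table) == 18
        pairs = set(zip(table["task_true"], table["task_alt"]))
        assert len(pairs) == 6
        assert all(a != b for a, b in pairs)


class TestNetworkPrediction:
    def test_two_way_split_reproduces_masked_prediction(self, smooth_map3):
        mask = threshold_mask(smooth_map3, 0.25)
        cfg = dict(CFG2, lam=0.1)
        res = krige_from_mask(smooth_map3, mask, cfg)
        labels = np.where(mask.member_flags, 1, 2)
        table = network_prediction(smooth_map3, labels, cfg).set_index(
            "network"
        )
        rho_pipeline = res.metrics.set_index("restriction").loc[
            "none", "spearman_rho"
        ]
        assert table.loc[1, "spearman_rho"] == pytest.approx(rho_pipeline,
                                                             abs=1e-12)

    def test_seven_networks_by_tasks_matrix(self, ico3, basis3):
        spec = SynthesisSpec(spectrum_decay=3.0, n_modes=80, seed=12)
        maps = synth_task_family(ico3, 3, 0.5, spec, basis=basis3)
        labels = synth_networks(ico3, n_networks=7, seed=1)
        table = network_prediction(maps, labels, dict(CFG2, lam=0.1),
                                   min_size=20)
        assert len(table) == 21  # 7 networks x 3 tasks
        assert table["spearman_rho"].notna().all()

    def test_small_network_flagged_skipped(self, smooth_map3):
        labels = np.full(smooth_map3.mesh.n_vertices, 1)
        labels[:5] = 2
        table = network_prediction(smooth_map3, labels, dict(CFG2, lam=0.1))
        assert bool(table.set_index("network").loc[2, "skipped"])

    def test_distributed_beats_compact(self, ico3, basis3):
        """Many small patches covering the sphere predict the complement
        better than one compact blob of equal total area."""
        wins = 0
        n_seeds = 8
        cfg = dict(CFG2, lam=0.1)
        for seed in range(n_seeds):
            spec = SynthesisSpec(spectrum_decay=3.0, n_modes=80,
                                 noise_sd=0.05, seed=100 + seed)
            from brainkrig import synth_map

            smap = synth_map(ico3, spec, basis=basis3)
            distributed = synth_networks(ico3, 2, patches_per_network=8,
                                         seed=seed)
            compact = synth_networks(ico3, 2, patches_per_network=1,
                                     seed=seed)
            td = network_prediction(smap, distributed, cfg).set_index(
                "network")
            tc = network_prediction(smap, compact, cfg).set_index("network")
            wins += (
                td.loc[1, "spearman_rho"] > tc.loc[1, "spearman_rho"]
            )
        assert wins >= int(0.75 * n_seeds)
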