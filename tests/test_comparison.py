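import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ordnet import comparison, simulate
from ordnet.datatypes import PairedPanel, ValidationError
from ordnet.metrics import global_strength

from conftest import random_network


class TestNctStatistics:
    def test_identical_networks_zero(self, rng):
        net = random_network(rng, 6)
        m, s, diffs = comparison.nct_statistics(net, net)
        assert m == 0.0 and s == 0.0
        assert (diffs == 0.0).all()

    def test_one_edge_case(self):
        from tests_helpers import make_single_edge_networks

        net1, net2 = make_single_edge_networks(0.30, 0.10)
        m, s, _ = comparison.nct_statistics(net1, net2)
        assert m == pytest.approx(0.20)
        assert s == pytest.approx(0.20)

    def test_structure_zero_implies_strength_zero(self, rng):
        net1 = random_network(rng, 5)
        m, s, _ = comparison.nct_statistics(net1, net1)
        assert m == 0.0
        assert s == 0.0

    def test_s_is_absolute_global_strength_difference(self, rng):
        net1, net2 = random_network(rng, 6), random_network(rng, 6)
        _, s, _ = comparison.nct_statistics(net1, net2)
        assert s == abs(global_strength(net1) - global_strength(net2))

    def test_m_is_max_edge_difference(self, rng):
        net1, net2 = random_network(rng, 6), random_network(rng, 6)
        m, _, diffs = comparison.nct_statistics(net1, net2)
        assert m == diffs[np.triu_indices(6, k=1)].max()

    def test_label_mismatch_raises(self, rng):
        net1 = random_network(rng, 4, labels=list("abcd"))
        net2 = random_network(rng, 4, labels=list("abce"))
        with pytest.raises(ValidationError):
            comparison.nct_statistics(net1, net2)


class TestPermutePaired:
    @pytest.fixture
    def pair(self):
        pair, _ = simulate.make_paired_panel(simulate.default_config(n_subjects=612, seed=1))
        return pair

    def test_deterministic_for_fixed_seed(self, pair):
        a = comparison.permute_paired(pair, seed=4)
        b = comparison.permute_paired(pair, seed=4)
        np.testing.assert_array_equal(a.baseline.scores, b.baseline.scores)

    def test_about_half_of_subjects_swapped(self, pair):
        swapped_fracs = []
        for seed in range(10):
            perm = comparison.permute_paired(pair, seed=seed)
            swapped = (perm.baseline.scores != pair.baseline.scores).any(axis=1)
            swapped_fracs.append(swapped.mean())
        assert abs(np.mean(swapped_fracs) - 0.5) < 0.05

    def test_complementary_masks_restore_original(self, pair):
        mask = np.random.default_rng(0).random(pair.n_subjects) < 0.5
        once = comparison.swap_waves(pair, mask)
        twice = comparison.swap_waves(once, mask)
        np.testing.assert_array_equal(twice.baseline.scores, pair.baseline.scores)
        np.testing.assert_array_equal(twice.followup.scores, pair.followup.scores)

    def test_swap_preserves_subject_alignment(self, pair):
        perm = comparison.permute_paired(pair, seed=9)
        np.testing.assert_array_equal(perm.baseline.subject_ids, pair.baseline.subject_ids)


class TestHolm:
    def test_hand_worked_example(self):
        out = comparison.holm_adjust([0.01, 0.04, 0.03])
        np.testing.assert_allclose(out, [0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert comparison.holm_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_capped(self):
        np.testing.assert_array_equal(comparison.holm_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_raises(self):
        with pytest.raises(ValidationError):
            comparison.holm_adjust([0.5, 1.5])

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_dominates_raw_and_bounded_by_bonferroni(self, pvals):
        raw = np.asarray(pvals)
        adj = comparison.holm_adjust(raw)
        bonf = np.minimum(raw * len(raw), 1.0)
        assert (adj >= raw - 1e-15).all()
        assert (adj <= bonf + 1e-12).all()
        assert (adj <= 1.0).all()

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=8))
    def test_preserves_order(self, pvals):
        raw = np.asarray(pvals)
        adj = comparison.holm_adjust(raw)
        order = np.argsort(raw, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestNctDependent:
    def test_identical_waves_give_unit_pvalues(self, fast_settings):
        pair, _ = simulate.make_paired_panel(simulate.default_config(n_subjects=200, seed=5))
        degenerate = PairedPanel(
            pair.baseline,
            type(pair.baseline)(
                pair.baseline.subject_ids, "followup",
                pair.baseline.scores, pair.baseline.item_labels,
            ),
        )
        res = comparison.nct_dependent(degenerate, fast_settings, B=100, seed=0)
        assert res.M == 0.0 and res.S == 0.0
        assert res.p_M == 1.0 and res.p_S == 1.0

    def test_result_identities_and_ranges(self, fast_settings):
        pair, _ = simulate.make_paired_panel(
            simulate.default_config(n_subjects=300, seed=2, strength_scale_followup=0.8)
        )
        res = comparison.nct_dependent(pair, fast_settings, B=120, seed=1)
        iu = np.triu_indices(12, k=1)
        assert res.M == res.edge_diffs[iu].max()
        assert res.S == abs(res.g1 - res.g2)
        b_ok = len(res.perm_S)
        for p in (res.p_M, res.p_S, *res.edge_p_raw):
            assert 1.0 / (b_ok + 1) <= p <= 1.0
        assert (res.edge_p_holm >= res.edge_p_raw - 1e-15).all()

    def test_deterministic_for_fixed_seed(self, fast_settings):
        pair, _ = simulate.make_paired_panel(simulate.default_config(n_subjects=200, seed=3))
        a = comparison.nct_dependent(pair, fast_settings, B=100, seed=7)
        b = comparison.nct_dependent(pair, fast_settings, B=100, seed=7)
        assert a.p_S == b.p_S and a.p_M == b.p_M
        np.testing.assert_array_equal(a.perm_S, b.perm_S)

    def test_power_against_scaled_followup(self, fast_settings):
        """Shrunken follow-up network is detected by the strength test.

        Pinned from the first validated run (20 replications): 20/20
        rejections at scale 0.8, n=612, B=200.
        """
        rejections = 0
        n_reps = 20
        for rep in range(n_reps):
            config = simulate.default_config(
                n_subjects=612, seed=1000 + rep, between_weight=0.0,
                strength_scale_followup=0.8,
            )
            pair, _ = simulate.make_paired_panel(config)
            res = comparison.nct_dependent(pair, fast_settings, B=200, seed=rep)
            rejections += res.p_S < 0.05
        assert rejections / n_reps >= 0.5

    def test_edge_policy_none_suppresses_reporting(self, fast_settings):
        pair, _ = simulate.make_paired_panel(simulate.default_config(n_subjects=200, seed=4))
        res = comparison.nct_dependent(
            pair, fast_settings, B=100, seed=2, edge_tests="none"
        )
        assert res.edges_reported is False
        assert len(res.edge_p_holm) == 66


def test_nct_independent_runs(fast_settings):
    pair, _ = simulate.make_paired_panel(simulate.default_config(n_subjects=250, seed=6))
    res = comparison.nct_independent(
        pair.baseline, pair.followup, fast_settings, B=100, seed=0
    )
    assert 0.0 < res.p_S <= 1.0
    assert res.S == abs(res.g1 - res.g2)


def test_nct_result_serialization(tmp_path, fast_settings):
    pair, _ = simulate.make_paired_panel(simulate.default_config(n_subjects=200, seed=8))
    res = comparison.nct_dependent(pair, fast_settings, B=100, seed=3)
    paths = res.write(tmp_path / "nct")
    assert all(p.exists() for p in paths)
    table = res.edge_table()
    assert list(table.columns) == ["item_a", "item_b", "abs_diff", "p_raw", "p_holm"]
    assert len(table) == 66
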