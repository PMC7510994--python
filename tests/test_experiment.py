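"""Protocol orchestration and statistics: settling, the injure/recover
pipeline bookkeeping, ANOVA + Tukey-Kramer, and Bonferroni t-tests."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import spikelesion as sl


def tiny_protocol(**overrides) -> sl.ProtocolConfig:
    """Seconds-scale protocol on a 60-neuron network for bookkeeping tests."""
    cfg = sl.desk_scale(n=60, n_replicates=2)
    net = replace(cfg.network, mean_degree=20.0)
    base = replace(
        cfg, network=net,
        settle_window_min=0.02, settle_max_min=0.10,
        measure_window_min=0.02, recovery_max_min=0.04,
        injury_fractions=(0.2,), injury_modes=("random",),
    )
    return replace(base, **overrides)


class TestSettle:
    def test_vacuous_criterion_stops_after_two_blocks(self):
        cfg = tiny_protocol(settle_tol=float("inf"))
        topo = sl.build_network(cfg.network, seed=1)
        state = sl.init_state(topo, cfg.sim)
        res = sl.settle(topo, state, cfg, np.random.default_rng(2))
        assert res.converged
        assert len(res.history) == 2
        assert res.elapsed_min == pytest.approx(2 * cfg.settle_window_min)

    def test_frozen_weights_with_stationary_drive_converge(self):
        # without plasticity the measured statistics are stationary, so the
        # 1 % criterion is met quickly
        cfg = tiny_protocol(settle_max_min=0.4, settle_tol=0.5)
        topo = sl.build_network(cfg.network, seed=3)
        state = sl.init_state(topo, cfg.sim)
        res = sl.settle(topo, state, cfg, np.random.default_rng(4), plasticity_on=False)
        assert res.converged

    def test_cap_warns_and_proceeds(self):
        cfg = tiny_protocol(settle_tol=0.0)  # unattainable
        topo = sl.build_network(cfg.network, seed=5)
        state = sl.init_state(topo, cfg.sim)
        with pytest.warns(RuntimeWarning):
            res = sl.settle(topo, state, cfg, np.random.default_rng(6))
        assert not res.converged


class TestRunProtocol:
    def test_row_count_combinatorics_and_reproducibility(self):
        cfg = tiny_protocol()
        t1 = sl.run_protocol(cfg, seed=11)
        t2 = sl.run_protocol(cfg, seed=11)
        # replicates x (baseline + |grid| x {post-injury, post-plasticity})
        assert len(t1) == cfg.n_replicates * (1 + len(cfg.injury_fractions) * 2)
        pd.testing.assert_frame_equal(t1, t2)
        assert set(t1["phase"]) == {"baseline", "post-injury", "post-plasticity"}

    def test_empty_grid_gives_baseline_only(self):
        cfg = tiny_protocol(injury_fractions=())
        t = sl.run_protocol(cfg, seed=12)
        assert set(t["phase"]) == {"baseline"}
        assert len(t) == cfg.n_replicates

    def test_replicates_differ_and_se_positive(self):
        cfg = tiny_protocol(injury_fractions=())
        t = sl.run_protocol(cfg, seed=13)
        assert t["firing_rate_hz"].nunique() > 1
        gm = sl.group_means(t)
        assert (gm["firing_rate_hz_se"] > 0).all()


class TestAnovaTukey:
    def test_identical_groups_not_significant(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        F, p, pairs = sl.anova_tukey(g)
        assert F == pytest.approx(0.0, abs=1e-12)
        assert not pairs["significant"].any()

    def test_two_groups_equal_pooled_t_test(self):
        rng = np.random.default_rng(21)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 9)
        F, p, _ = sl.anova_tukey({"a": a, "b": b})
        t, pt = sps.ttest_ind(a, b, equal_var=True)
        assert F == pytest.approx(t**2, rel=1e-10)
        assert p == pytest.approx(pt, rel=1e-10)

    def test_textbook_fixture_matches_hand_computed_f(self):
        # brute-force sums of squares for a fixed 3-group sample
        g = {"g1": np.array([6.0, 8.0, 4.0, 5.0, 3.0, 4.0]),
             "g2": np.array([8.0, 12.0, 9.0, 11.0, 6.0, 8.0]),
             "g3": np.array([13.0, 9.0, 11.0, 8.0, 7.0, 12.0])}
        allv = np.concatenate(list(g.values()))
        grand = allv.mean()
        ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in g.values())
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in g.values())
        f_hand = (ss_between / 2) / (ss_within / (len(allv) - 3))
        F, p, pairs = sl.anova_tukey(g)
        assert F == pytest.approx(f_hand, rel=1e-12)
        assert len(pairs) == 3

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            sl.anova_tukey({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        with pytest.raises(ValueError):
            sl.anova_tukey({"a": [1.0, 2.0]})


class TestTtestBonferroni:
    def test_single_pair_reduces_to_plain_t(self):
        rng = np.random.default_rng(22)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        out = sl.ttest_bonferroni([(a, b)])
        t, p = sps.ttest_ind(a, b, equal_var=False)
        assert out.loc[0, "t"] == pytest.approx(t)
        assert out.loc[0, "p_adj"] == pytest.approx(p)

    def test_identical_samples_not_significant(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        out = sl.ttest_bonferroni([(a, a.copy())])
        assert not out["significant"].any()

    def test_known_means_match_closed_form(self):
        a = np.array([10.0, 12.0, 11.0, 13.0])
        b = np.array([8.0, 9.0, 7.0, 10.0])
        out = sl.ttest_bonferroni([(a, b), (a, a.copy())])
        t_hand = (a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / 4 + b.var(ddof=1) / 4)
        assert out.loc[0, "t"] == pytest.approx(t_hand, rel=1e-12)
        # Bonferroni doubling with two pairs
        assert out.loc[0, "p_adj"] == pytest.approx(min(out.loc[0, "p"] * 2, 1.0))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sl.ttest_bonferroni([])


class TestEISweep:
    def test_self_normalization_at_baseline_composition(self):
        cfg = tiny_protocol(injury_fractions=(), n_replicates=2)
        t = sl.ei_sweep(cfg, seed=31, frac_exc_grid=(0.80,))
        assert np.allclose(t["firing_rate_hz_norm"].groupby(t["frac_exc"]).mean(), 1.0)
        assert set(t["frac_exc"]) == {0.80}
        assert "index_rate_r" in t.columns
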