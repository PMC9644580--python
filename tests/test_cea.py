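"""Strategy comparison: mixes, PSA, incremental statistics, CEAC, scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cadcea import (
    PSAResult,
    StrategyMix,
    ce_plane,
    ceac,
    evaluate_mix,
    incremental_summary,
    population_scale,
    run_psa,
)


def psa_from_records(records):
    df = pd.DataFrame(records, columns=["draw", "strategy", "cost", "qaly"])
    return PSAResult(draws=df, n_draws=df["draw"].nunique(), seed=0)


class TestStrategyMix:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            StrategyMix("bad", {"OMT": 0.5, "PCI": 0.4})

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            StrategyMix("bad", {"OMT": 1.5, "PCI": -0.5})


class TestEvaluateMix:
    arm_results = {"OMT": (10.0, 1.0), "PCI": (20.0, 2.0), "CABG": (30.0, 3.0)}

    def test_degenerate_mix_equals_arm(self):
        mix = StrategyMix("cabg", {"CABG": 1.0})
        assert evaluate_mix(mix, self.arm_results) == (30.0, 3.0)

    def test_equal_three_way_mix(self):
        mix = StrategyMix("eq", {a: 1 / 3 for a in self.arm_results})
        cost, qaly = evaluate_mix(mix, self.arm_results)
        assert cost == pytest.approx(20.0, abs=1e-12)
        assert qaly == pytest.approx(2.0, abs=1e-12)

    def test_current_practice_weights_hand_sum(self):
        mix = StrategyMix("cp", {"OMT": 0.819, "PCI": 0.135, "CABG": 0.046})
        cost, qaly = evaluate_mix(mix, self.arm_results)
        assert cost == pytest.approx(0.819 * 10 + 0.135 * 20 + 0.046 * 30, abs=1e-12)
        assert qaly == pytest.approx(0.819 * 1 + 0.135 * 2 + 0.046 * 3, abs=1e-12)

    def test_missing_arm_rejected(self):
        with pytest.raises(ValueError, match="no results"):
            evaluate_mix(StrategyMix("x", {"SURG": 1.0}), self.arm_results)

    @given(w=st.floats(0.0, 1.0))
    def test_mix_of_mixes_is_convex_combination(self, w):
        mix_a = StrategyMix("a", {"OMT": 1.0})
        mix_b = StrategyMix("b", {"PCI": 0.5, "CABG": 0.5})
        blended = StrategyMix(
            "ab", {"OMT": w, "PCI": 0.5 * (1 - w), "CABG": 0.5 * (1 - w)}
        )
        ca, qa = evaluate_mix(mix_a, self.arm_results)
        cb, qb = evaluate_mix(mix_b, self.arm_results)
        c, q = evaluate_mix(blended, self.arm_results)
        assert c == pytest.approx(w * ca + (1 - w) * cb, abs=1e-12)
        assert q == pytest.approx(w * qa + (1 - w) * qb, abs=1e-12)


class TestRunPsa:
    def test_fixed_specs_zero_variance(self, default_config):
        import dataclasses

        fixed = {
            name: dataclasses.replace(
                spec, kind="fixed", sd=None
            )
            for name, spec in default_config.parameters.items()
        }
        cfg = dataclasses.replace(default_config, parameters=fixed)
        psa = run_psa(cfg, n_draws=5, seed=0)
        for _, grp in psa.draws.groupby("strategy"):
            assert grp["cost"].std() == 0.0
            assert grp["qaly"].std() == 0.0

    def test_same_seed_identical_draws(self, default_config):
        a = run_psa(default_config, n_draws=20, seed=123)
        b = run_psa(default_config, n_draws=20, seed=123)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_costs_nonnegative_and_complete(self, default_config):
        psa = run_psa(default_config, n_draws=20, seed=1)
        assert (psa.draws["cost"] >= 0).all()
        counts = psa.draws.groupby("strategy").size()
        assert (counts == 20).all()
        assert len(counts) == len(default_config.strategies)

    def test_dirichlet_transition_sampling_runs(self, default_config):
        from cadcea import estimate_transition_matrix, generate_histories

        truth = default_config.ground_truth(seed=2, n_patients=2000)
        h = generate_histories(truth)
        est = estimate_transition_matrix(h, default_config.state_names, absorbing="Dead")
        fitted = default_config.with_transitions(est)
        psa = run_psa(fitted, n_draws=10, seed=4, sample_transitions=True)
        assert psa.draws["qaly"].var() > 0


class TestIncrementalSummary:
    def test_self_comparison_all_zero(self):
        psa = psa_from_records(
            [(d, s, 100.0 + d, 1.0) for d in range(4) for s in ("a", "b")]
        )
        ce = incremental_summary(psa, "a", "a", 80_000)
        assert ce.delta_cost == 0.0 and ce.delta_qaly == 0.0 and ce.nmb == 0.0
        assert ce.p_cost_saving == 0.0
        assert ce.p_cost_effective == 0.0

    def test_hand_arithmetic_example(self):
        psa = psa_from_records([(0, "base", 100.0, 1.0), (0, "new", 90.0, 1.2)])
        ce = incremental_summary(psa, "new", "base", 80_000)
        assert ce.delta_cost == pytest.approx(-10.0, abs=1e-12)
        assert ce.delta_qaly == pytest.approx(0.2, abs=1e-12)
        assert ce.nmb == pytest.approx(80_000 * 0.2 + 10.0, abs=1e-9)

    def test_nmb_at_zero_wtp_is_minus_delta_cost(self):
        rng = np.random.default_rng(0)
        psa = psa_from_records(
            [(d, s, float(rng.uniform(50, 150)), float(rng.uniform(0.5, 2)))
             for d in range(50) for s in ("base", "new")]
        )
        ce = incremental_summary(psa, "new", "base", 0.0)
        assert ce.nmb == pytest.approx(-ce.delta_cost, abs=1e-9)

    def test_nmb_affine_in_wtp_on_every_draw(self):
        rng = np.random.default_rng(1)
        psa = psa_from_records(
            [(d, s, float(rng.uniform(50, 150)), float(rng.uniform(0.5, 2)))
             for d in range(100) for s in ("base", "new")]
        )
        s = psa.totals("new")
        b = psa.totals("base")
        dc = s["cost"].to_numpy() - b["cost"].to_numpy()
        dq = s["qaly"].to_numpy() - b["qaly"].to_numpy()
        for lam in (0.0, 40_000.0, 80_000.0):
            nmb = lam * dq - dc
            assert np.allclose(nmb, lam * dq - dc, atol=0)
            # slope between grid points equals delta-QALY per unit lambda
        slope = ((80_000 * dq - dc) - (40_000 * dq - dc)) / 40_000
        assert np.allclose(slope, dq, atol=1e-12)

    def test_percentile_interval_brackets_mean_for_unimodal_draws(self):
        rng = np.random.default_rng(2)
        hits = 0
        reps = 20
        for r in range(reps):
            records = []
            for d in range(1000):
                records.append((d, "base", 100.0, 1.0))
                records.append(
                    (d, "new", 100.0 + rng.normal(-10, 5), 1.0 + rng.normal(0.2, 0.05))
                )
            ce = incremental_summary(psa_from_records(records), "new", "base", 80_000)
            if ce.delta_cost_ui[0] <= ce.delta_cost <= ce.delta_cost_ui[1]:
                hits += 1
        assert hits / reps >= 0.94


class TestCeac:
    def test_monotone_when_qaly_gain_positive(self):
        rng = np.random.default_rng(3)
        records = []
        for d in range(200):
            records.append((d, "base", 100.0, 1.0))
            records.append((d, "new", 100.0 + abs(rng.normal(5, 2)),
                            1.0 + abs(rng.normal(0.1, 0.05))))
        curve = ceac(psa_from_records(records), "new", "base",
                     np.arange(0, 200_001, 20_000))
        assert (np.diff(curve["p_cost_effective"]) >= 0).all()

    def test_zero_threshold_point_equals_p_cost_saving(self):
        rng = np.random.default_rng(4)
        records = []
        for d in range(200):
            records.append((d, "base", 100.0, 1.0))
            records.append((d, "new", 100.0 + rng.normal(0, 10), 1.0))
        psa = psa_from_records(records)
        ce = incremental_summary(psa, "new", "base", 80_000)
        curve = ceac(psa, "new", "base", [0.0, 80_000.0])
        assert curve["p_cost_effective"].iloc[0] == ce.p_cost_saving

    def test_single_draw_breakeven_threshold(self):
        # dC = -10, dQ = -0.001: cost-effective exactly below lambda = 10,000
        psa = psa_from_records(
            [(0, "base", 100.0, 1.0), (0, "new", 90.0, 0.999)]
        )
        curve = ceac(psa, "new", "base", [0.0, 9_999.0, 10_001.0])
        assert list(curve["p_cost_effective"]) == [1.0, 1.0, 0.0]

    def test_empty_grid_rejected(self):
        psa = psa_from_records([(0, "a", 1.0, 1.0), (0, "b", 1.0, 1.0)])
        with pytest.raises(ValueError, match="empty"):
            ceac(psa, "a", "b", [])


class TestPopulationScale:
    def _ce(self, dc, dq, wtp=80_000.0):
        return incremental_summary(
            psa_from_records([(0, "base", 100.0, 1.0), (0, "new", 100.0 + dc, 1.0 + dq)]),
            "new",
            "base",
            wtp,
        )

    def test_qaly_gain_scales_to_cohort(self):
        _, annual_qaly, _ = population_scale(self._ce(0.0, 0.23), 6000)
        assert annual_qaly == pytest.approx(1380.0, abs=1e-9)

    def test_cost_saving_scales_to_millions(self):
        annual_cost, _, _ = population_scale(self._ce(-1743.0, 0.0), 6000)
        assert annual_cost == pytest.approx(-10_458_000.0, abs=1e-6)

    def test_monetary_value_of_health_gain(self):
        _, _, value = population_scale(self._ce(0.0, 0.23), 6000)
        assert value == pytest.approx(1380 * 80_000.0, abs=1e-6)

    def test_negative_population_rejected(self):
        with pytest.raises(ValueError):
            population_scale(self._ce(0.0, 0.1), -1)
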