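"""Probabilistic sensitivity analysis and policy comparison.

Cost and utility parameters are sampled 1000 times from their gamma/beta
laws; every policy (current practice, three 100% policies, and the
recommended 86% OMT / 14% CABG mix) is evaluated under the same draw.
Incremental results against current practice are summarised as mean
changes with 95% percentile intervals, net monetary benefit at the SGD
$80,000/QALY threshold, and an acceptability curve.
"""

from cadcea import (
    ceac,
    incremental_summary,
    load_default_config,
    population_scale,
    run_psa,
)

cfg = load_default_config()
psa = run_psa(cfg, n_draws=1000, seed=1)

ce = incremental_summary(psa, "recommended", "current_practice", cfg.engine.wtp_threshold)
print(f"Recommended Policy vs current practice ({psa.n_draws} draws):")
print(f"  change to costs : ${ce.delta_cost:,.0f} "
      f"(95% UI {ce.delta_cost_ui[0]:,.0f} to {ce.delta_cost_ui[1]:,.0f})")
print(f"  change to QALYs : {ce.delta_qaly:.3f} "
      f"(95% UI {ce.delta_qaly_ui[0]:.3f} to {ce.delta_qaly_ui[1]:.3f})")
print(f"  NMB at $80,000  : ${ce.nmb:,.0f}")
print(f"  P(saves costs) = {ce.p_cost_saving:.1%}, "
      f"P(gains QALYs) = {ce.p_qaly_gain:.1%}, "
      f"P(cost-effective) = {ce.p_cost_effective:.1%}")

annual_cost, annual_qaly, annual_value = population_scale(ce, 6000)
print(f"\nScaled to 6,000 patients/year: cost change ${annual_cost:,.0f}, "
      f"QALY gain {annual_qaly:,.0f} (worth ${annual_value:,.0f})")

curve = ceac(psa, "recommended", "current_practice", range(0, 160_001, 40_000))
print("\nAcceptability curve (P cost-effective by threshold):")
print(curve.to_string(index=False))
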