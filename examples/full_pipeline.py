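"""Simulate a labeled-incubation experiment and analyze it end to end.

Generates a synthetic four-layer measurement table at the study conditions
(planted per-layer rates, +2000 per mil label, 24 h, triplicates, 0.1 per
mil CRDS noise), runs the full rate + significance analysis plus the field
chemistry block, and prints the report summary.
"""

import pandas as pd

import matlith as ml

layers, design = ml.default_lhc_params(seed=11)
table = ml.simulate_incubation(layers, design)
print(f"simulated {len(table)} measurements "
      f"({table.groupby(['layer', 'fraction', 'treatment']).ngroups} replicate groups)")

chemistry = pd.DataFrame(
    {
        "station": ["upstream", "downstream", "porewater_1cm", "porewater_5cm"],
        "temperature_c": [52.4, 38.1, 38.8, 48.4],
        "ph": [8.34, 8.29, 8.10, 8.30],
        "tco2_mm": [11.91, 11.88, 11.52, 11.59],
        "calcium_mm": [0.55, 0.55, 0.55, 0.55],
    }
)

report = ml.run_full_analysis(table, chemistry, ml.AnalysisConfig(seed=11))

cols = ["layer", "mode", "rate_pct_per_day", "p_bootstrap", "p_machine", "below_detection"]
print(report.rates[cols].round(4).to_string(index=False))
print()
print(report.chemistry[["station", "co3_mm", "omega_calcite"]].round(3).to_string(index=False))
print()
print("projection:", {k: round(v, 10) for k, v in report.projection.items()})

# Fixation rates near the planted 0.17/0.17/0.011/0.07 %/day come out
# significant (low bootstrap p); planted-zero comparisons hover near their
# baselines with high p, i.e. the pipeline distinguishes signal from noise
# at the instrument's 0.1 per mil level.
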