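# matlith

Isotope-tracer rate analysis for microbial mat carbonate precipitation and
lithification timescales.

Microbial mats are candidate precursors of microbialites — lithified,
layered carbonate structures with a fossil record reaching into the
Archean — yet most modern mats never lithify. `matlith` implements the
quantitative core of a labeled-bicarbonate incubation study on a hot-spring
mat: it turns δ¹³C measurements from ¹³C-labeled incubations into rates of
carbon fixation and biogenic/abiogenic carbonate precipitation, tests
whether triplicate differences are real, characterizes the carbonate
chemistry of the surrounding waters, and extrapolates measured
precipitation rates to the timescale on which a mat could become a
microbialite.

## The model

**Label mass balance.** Samples are incubated with HCO₃⁻ labeled at
δ¹³C = +2000 ‰. In the fractional-abundance coordinate
F = ¹³C/(¹²C + ¹³C), isotope mixing is linear, so if a fraction *x* of a
pool is newly formed from the label (no fractionation),
F_after = (1 − x) F_init + x F_label. Inverting:

```
percent new carbon = (1 − (F_sample − F_label) / (F_baseline − F_label)) × 100
```

with (sample, baseline) = (living, poisoned control) for gross fixation and
biogenic precipitation, and (poisoned control, negative control) for
abiogenic precipitation. Dividing by the incubation time (24 h) gives
% new carbon/day.

**Significance.** For each comparison of two triplicate means
(Δ_avg = mean_a − mean_b), the six values are pooled and resampled with
replacement into two new triplicates 1000 times; the one-sided p-value is
the fraction of resampled differences ≥ the observed one (ties count). An
exact oracle enumerates all 6⁶ = 46,656 resamples. Independently, CRDS
machine noise (σ = 0.1 ‰ per measurement) propagates to 0.1/√3 ≈ 0.058 ‰
for a triplicate mean and √(0.058² + 0.058²) ≈ 0.082 ‰ for Δ_avg; a normal
tail gives the probability that machine noise alone explains Δ_avg.

**Saturation state.** Pore and stream waters are speciated from (T, pH,
TCO₂) by carbonic-acid mass action, and Ω = [Ca²⁺][CO₃²⁻]/Ksp′ computed
with documented freshwater constants (an ionic-strength correction and a
CO2SYS-style stoichiometric seawater set are available).

**Lithification projection.** Percent rates become mass fluxes
(flux = carbonate mass × rate/100); 100/rate days bounds the time for a
carbonate-free mat to lithify; a two-pool compound-growth trajectory shows
that a mat whose organic production rate exceeds its carbonate
precipitation rate never reaches 100 wt% carbonate.

A forward-model generator (`simulate_incubation`) produces synthetic
measurement tables with planted true rates and realistic noise, so the
entire pipeline is testable by parameter recovery.

## Worked example

```
$ python examples/full_pipeline.py
simulated 72 measurements (24 replicate groups)
layer           mode  rate_pct_per_day  p_bootstrap  p_machine  below_detection
    A gross-fixation            0.1682        0.010     0.0000            False
    A       biogenic            0.0053        0.052     0.2024            False
    A      abiogenic            0.0101        0.019     0.0154            False
    B gross-fixation            0.1734        0.003     0.0000            False
    ...
projection: {'carbonate_mass_g': 0.00182, 'daily_mass_rate_g_per_day': 2.184e-07,
             'years_full_lithification': 23.0, 'years_to_target_wtpct': 2.0}
```

The simulation planted 0.17 % new organic carbon/day in layer A; the
analysis recovers 0.168 %/day with bootstrap p = 0.010 — a real signal at
the instrument's noise level. The projection block says an average mat
sample (0.002 g, 91 wt% carbonate) holds 0.0018 g of carbonate, gains
about 2.2 × 10⁻⁷ g/day, would need a minimum of 23 years to lithify from
zero carbonate, and about 2 more years to go from 91 to 100 wt%.

Each script in `examples/` is a self-contained narrative: the mass balance
(`label_mass_balance.py`), the bootstrap and machine-noise screens
(`bootstrap_significance.py`), water chemistry (`saturation_state.py`),
projections (`lithification_timescales.py`), and the full pipeline above.

A thin CLI wraps the same functions: `matlith simulate`, `matlith analyze`,
`matlith omega`, `matlith project`.

## Layout

- `src/matlith/isotopes.py` — δ¹³C/ratio/fractional-abundance conversions, mass balance
- `src/matlith/stats.py` — bootstrap test, exact enumeration oracle, machine-noise screen
- `src/matlith/carbonate.py` — speciation, equilibrium constants, Ω
- `src/matlith/projection.py` — mass fluxes and lithification timescales
- `src/matlith/simulate.py` — forward-model synthetic data generator
- `src/matlith/pipeline.py` — CSV I/O, config, orchestration, reports
- `docs/methods.md` — model assumptions, parameter choices, limitations
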