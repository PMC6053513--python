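# Methods

This note records the models `matlith` implements, the parameter choices
that matter, and the limits of what its tests demonstrate.

## Isotope mass balance

All mixing arithmetic is done in fractional abundance
F = ¹³C/(¹²C + ¹³C), the coordinate in which two-endmember mixing is
exactly linear. Conversions use δ = (R/R_VPDB − 1) × 1000 with
R_VPDB = 0.0112372 (configurable; any consistent reference cancels out of
the mass balance to first order). A flag allows evaluating the mass
balance on ¹³C/¹²C ratios instead; at tracer enrichments of a few thousand
per mil the two conventions differ by < 0.1 % new carbon, far below the
noise-implied detection limit.

Assumptions, matching the experimental design being analyzed:

- new carbon acquires the label's δ¹³C with no isotopic fractionation
  (a good approximation only because the +2000 ‰ spike dwarfs the ~20–30 ‰
  scale of biological fractionation);
- the label's fractional abundance is that of a δ¹³C = +2000 ‰ pool.
  Whether "+2000 ‰" describes the spike itself or the final amended water
  is ambiguous in the source experiment; `label_delta` is therefore an
  explicit parameter, and because the label term appears in both numerator
  and denominator the computed rates are insensitive to modest revisions
  of it;
- negative percent-new values (sample lighter than baseline) are reported
  with a `below_detection` flag, never clamped, so significance tests see
  the full sampling distribution.

The three rate comparisons are: organic living vs poisoned (gross
fixation), inorganic living vs poisoned (biogenic precipitation), and
inorganic poisoned vs negative control (abiogenic precipitation). Rates
are percent new carbon divided by incubation duration in days (24 h
default).

## Bootstrap significance test

The test pools the 4–6 values of the two replicate groups and draws, with
replacement, two new groups of the original sizes; the p-value is the
fraction of `n_resamples` (default 1000) resampled mean-differences that
meet or exceed the observed one. Choices:

- **One-sided by default** (enrichment is the alternative of interest);
  a two-sided option exists.
- **Ties count as exceedances.** This is conservative and forced by the
  degenerate all-equal pool, where every resampled difference is 0 and
  p must be 1. A tolerance of 1e-12 (relative) guards float round-off in
  the comparison.
- **Plain count/N estimator** to match the 1000-resample convention the
  analysis reproduces; an (count+1)/(N+1) estimator is available by flag.
- **Resampled group sizes mirror the originals** (3+3, or 2+3 when one
  group has two replicates).
- Every run is seeded; per-comparison seeds in the pipeline are spawned
  from the run seed via `numpy.random.SeedSequence`, so reports are
  bit-reproducible.

`exact_null_p` enumerates all k^k equally likely with-replacement
resamples (46,656 for k = 6; refused above k = 8) by enumerating the two
group-mean distributions separately and combining them on the outer grid.
It is the oracle the Monte-Carlo test is verified against. Calibration:
under a true null the test's one-sided size at α = 0.05 is slightly
anti-conservative (~0.06–0.08) — an inherent property of pooled
resampling at n = 3 — which `null_calibration` measures empirically.

The machine-noise screen propagates a per-measurement CRDS σ of 0.1 ‰ to
σ/√n per group mean and in quadrature to the difference (0.0577 and
0.0816 ‰ for triplicates). The published presentation of this chain rounds
intermediate values (0.058, 0.082, 2σ = 0.164 ‰); the library computes the
exact chain, and the acceptance checks reproduce the printed figures by
rounding at the same points. The screen probability is the two-sided
normal tail at the observed difference (one-sided available). A difference
below 1σ has a one-sided tail of ~16 % / two-sided ~32 %; a "14 %"
characterization sometimes quoted for this regime matches neither tail
exactly and is not reproduced here.

## Carbonate chemistry

Speciation solves the closed-form mass-action partition of TCO₂ among
CO₂(aq), HCO₃⁻ and CO₃²⁻ at the measured pH (treated as hydrogen-ion
activity). Constant sets:

- **freshwater** (default): Harned & Davis (1943) K₁, Harned & Scholes
  (1941) K₂, Plummer & Busenberg (1982) calcite Ksp — thermodynamic,
  zero-ionic-strength fits appropriate for dilute spring water. An
  optional Davies correction (user-supplied ionic strength, valid to
  I ≈ 0.5 M) converts to apparent constants and activity-corrects Ω.
- **seawater**: Lueker et al. (2000) K₁/K₂ with Mucci (1983)
  stoichiometric Ksp on a salinity grid — the convention of CO2SYS-style
  calculators, which absorbs ion pairing into the constants.

Concentrations are treated as mol/L ≈ mol/kg-solution, and the NBS/total
pH-scale distinction is ignored; both approximations are far below the
constant-set uncertainty at these dilutions.

**Known limitation — absolute Ω.** For the four field stations analyzed
in the tests (T = 38–52 °C, pH 8.1–8.3, TCO₂ ≈ 11.5–11.9 mM,
Ca = 0.55 mM), freshwater constants give Ω ≈ 17–47, i.e. strong
supersaturation, where the original field study reported Ω = 3.2–4.6 from
a speciation program whose constant options and calcium inputs were not
recorded. No documented uniform constant set reproduces all four reported
values to within 20 %: the reported upstream/1-cm-porewater ratio (1.43)
is incompatible under mass action with those stations' 0.24 pH-unit
difference (which implies a ratio ≥ 2.2 for any K set). The *ranking* of
the four stations, by contrast, is robust across every constant set
examined and is the quantity the package's tests assert. Users needing
absolute Ω should regard the constant set (and ionic strength) as a
declared modelling choice, which `SaturationState.constants_used` records.

## Lithification projections

"% new carbonate per day" is used in two deliberately distinct senses,
each matching one of the headline constructions:

- the **full-lithification bound** treats the rate as a constant flux of
  rate % of the *final* inventory per day → days = 100/rate, years
  rounded **up** (it is a minimum): 0.012 %/day → 23 years;
- the **target-weight-percent projection** and the **trajectory** treat it
  as rate % of the *current* pool per day. The projection accrues the
  constant-total-mass deficit total × (target − current) at the sample's
  present flux, quoted in whole years rounded **down** ("N more years"):
  0.002 g at 91 wt% and 0.012 %/day → 0.0018 g carbonate, 2.18 × 10⁻⁷
  g/day, 2 years to 100 wt%.

Because the target projection's flux is proportional to the *current*
carbonate pool, it diverges (infinite time) for a mat starting at 0 wt% —
the bound and the projection agree only in regimes where the current and
final inventories are comparable; they are intentionally not a single
formula.

The dilution trajectory grows each pool by compound interest,
m(t+Δ) = m(t)(1 + rΔ/100), converging to m₀e^(rt/100) as Δ → 0 (within
1 % for rt ≤ 50 at the default step). The carbonate weight fraction tends
to 1 iff the carbonate rate exceeds the organic rate; equal rates hold
composition constant; a faster organic rate drives the fraction toward 0
("never lithifies"). Years use 365 days.

## Synthetic data generator

`simulate_incubation` emulates the replicate structure of the source
experiment: per layer × fraction (organic, inorganic) × treatment
(negative, poisoned, living), `n_replicates` δ¹³C values. Planted
composition follows the treatments' logic: negatives keep the initial
δ¹³C; poisoned organics take up nothing; poisoned inorganics mix the
abiogenic fraction; living pools mix their biologically driven fraction
*into the poisoned composition* (sequential mixing), which makes the
generator the exact algebraic inverse of the analysis — noise-free tables
are recovered to machine precision, the anchor of the pipeline tests.

Default study conditions (`default_lhc_params`): label +2000 ‰, 24 h,
triplicates, machine σ = 0.1 ‰. Per-layer fixation rates 0.17, 0.17,
0.011, 0.07 %/day (layers A–D) and the layers' organic/carbonate weight
percents are the reported values; layer D's weight percents are set within
the reported range so the four-layer carbonate mean is 91 wt%. The
biogenic/abiogenic precipitation split per layer is a modelling choice
constrained to the reported qualitative pattern (A abiogenic-only,
B biogenic-only, C and D both) with the four-layer mean total equal to the
reported 0.012 %/day. Initial δ¹³C defaults are −25 ‰ (organic biomass)
and +1 ‰ (carbonate precipitated from DIC near −2 ‰); the mass balance
depends only weakly on them.

What the generator does **not** model: between-replicate biological
variance (default 0, exposed as `biological_sigma` — real triplicate
scatter exceeds pure machine noise), diel light/dark rate modulation
(rates are single effective daily values), isotopic fractionation, and
any community or mineralogical mechanism. Passing parameter-recovery
tests therefore demonstrates the *inferential* pipeline is correct and
unbiased under its own assumptions, not that those assumptions hold in
any particular mat.

## Problem sizes and numerics

The test suite and acceptance script run at desk scale by design:
bootstrap-vs-enumeration checks use 20 random pools × 10⁵ resamples, null
calibration 2000 simulated pairs × 1000 resamples, noisy parameter
recovery 500 seeds — sizes at which every Monte-Carlo band in the checks
(3 binomial SDs; 2 standard errors) is already narrow. Degenerate inputs
are handled explicitly: zero label contrast raises, δ < −1000 ‰ raises,
empty replicate groups raise, a zero precipitation rate yields an
infinite-time flag rather than an exception.
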