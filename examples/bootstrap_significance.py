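"""Is a triplicate delta13C difference real, instrument noise, or chance?

Compares a living and a poisoned triplicate three ways: the pooled
bootstrap (1000 resamples, as the analysis prescribes), the exact
enumeration of all 6^6 resamples, and the analytic probability that CRDS
machine noise alone (sigma = 0.1 per mil per measurement) produced the
observed difference of means.
"""

import matlith as ml

living = ml.TriplicateSet([-20.1, -20.6, -20.9], treatment="living")
poisoned = ml.TriplicateSet([-25.2, -24.9, -25.1], treatment="poisoned")

observed = ml.delta_avg(living, poisoned)
boot = ml.bootstrap_p(living, poisoned, n_resamples=1000, seed=0)
exact = ml.exact_null_p(living, poisoned)

mv = ml.propagate_machine_sigma(sigma_single=0.1)
p_machine = ml.machine_variability_prob(observed, mv.sigma_diff)

print(f"observed difference of means  = {observed:+.3f} per mil")
print(f"bootstrap p (1000 resamples)  = {boot.p_value:.4f}")
print(f"exact enumeration p (6^6)     = {exact:.4f}")
print(f"sigma of a triplicate mean    = {mv.sigma_mean:.3f} per mil")
print(f"sigma of the difference       = {mv.sigma_diff:.3f} per mil")
print(f"P(machine noise alone)        = {p_machine:.2e}")

# A ~4.7 per mil separation is far beyond both nulls: the bootstrap p sits
# at its floor (the 1/64 chance of perfectly re-segregating the pool) and
# machine noise at 0.082 per mil cannot explain it.
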