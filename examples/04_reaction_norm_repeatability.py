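"""Fit the candidate reaction-norm models and estimate repeatability.

Simulates a metric table with known among-individual variance
(true latent repeatability 0.6), fits all six candidate Gaussian mixed
models by Gibbs sampling, selects by DIC with the within-2-most-complex
rule, and reports r = s2_among / (s2_among + s2_within) with its 95%
credible interval and variance partition.
"""

from proxnet import (MODELS, McmcSettings, compute_dic, dic_table,
                     fit_mixed_model, repeatability, select_model,
                     simulate_observation_table)

obs, r_true = simulate_observation_table(
    n_individuals=12, sigma2_id=1.5, sigma2_resid=1.0,
    beta=(0.2, -0.4), seed=3)
print(f"simulated 12 individuals x 6 measures, latent r_true = {r_true:.2f}")

dics = {}
fits = {}
for label, spec in MODELS.items():
    fit = fit_mixed_model(obs, spec, mcmc=McmcSettings.desk(seed=10))
    fits[label] = fit
    dics[label] = compute_dic(fit)

print("\nDIC table (conditional likelihood):")
print(dic_table(dics).round(2).to_string(index=False))

best = select_model(dics)
est = repeatability(fits[best])
print(f"\nselected model: {best} (most complex within 2 DIC of the minimum)")
print(f"repeatability r = {est.r:.3f} "
      f"(95% CrI {est.ci_low:.3f}-{est.ci_high:.3f})")
print(f"variance partition (design-averaged diagonal): "
      f"{ {k: round(v, 3) for k, v in est.partition.items()} }")

est_m2 = repeatability(fits["M2"])
print(f"\nintercept-only (M2) r = {est_m2.r:.3f} "
      f"(95% CrI {est_m2.ci_low:.3f}-{est_m2.ci_high:.3f}) — this is the "
      f"quantity the latent r_true = {r_true:.2f} refers to.")
print("A CrI excluding 0 indicates stable individual differences across the "
      "density gradient.  Models with random slopes fold individual density "
      "responses into s2_among (marginalized over the design), so their r "
      "can sit above the intercept-only value.")
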