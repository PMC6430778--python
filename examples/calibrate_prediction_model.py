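"""Recover a population-specific prediction equation from (DMS, CA) pairs.

Draws 74 noisy score/age pairs from the bundled male reference model
CA = 1/(0.083 + 0.351 * 0.969**DMS), then fits the logistic growth curve
with a free upper asymptote and prints the recovered coefficients and fit
quality — the workflow used to derive a new equation for a local cohort.
"""

from dentalage import DEFAULT_MODELS, fit_logistic_growth, generate_calibration_pairs

truth = DEFAULT_MODELS["M"]
dms, ca = generate_calibration_pairs(truth, n=74, noise_sd=0.3, seed=42)
result = fit_logistic_growth(dms, ca, sex="M", asymptote="free")

m = result.model
print(f"true model:   CA = 1/({truth.a:.3f} + {truth.b:.3f} * {truth.c:.3f}**DMS)")
print(f"fitted model: CA = 1/({m.a:.3f} + {m.b:.3f} * {m.c:.3f}**DMS)")
print(f"R^2 = {result.r_squared:.3f}, Spearman rho = {result.spearman_rho:.3f}, n = {result.n}")
print(
    "The decay base c governs how fast age rises with maturity score; "
    "R^2 is computed on the age scale."
)
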