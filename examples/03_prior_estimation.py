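"""Estimate class priors from PU score distributions.

Draws a score mixture with known contamination (30% of the unlabeled
sample are true positives; 10% of the labeled positives are mislabeled),
then recovers alpha and beta and calibrates scores into posteriors.
"""

import arginylome as ag

ALPHA_TRUE, BETA_TRUE = 0.30, 0.10
pos, unl, _ = ag.generate_score_mixture(
    n_pos=5000, n_unl=5000, alpha_true=ALPHA_TRUE, separation=4.0,
    beta_true=BETA_TRUE, seed=5,
)

est = ag.estimate_alpha(pos, unl)
print(f"alpha (true {ALPHA_TRUE}): {est.alpha:.2f}   unstable: {est.unstable}")

est_b = ag.estimate_beta(pos, unl, est.alpha)
print(f"beta  (true {BETA_TRUE}): {est_b.beta:.2f}")

posteriors = ag.posterior_transform(unl, est.alpha, est.densities)
print(f"mean posterior over the unlabeled sample: {posteriors.mean():.3f}")
print("\nalpha is the fraction of true positives hidden among the unlabeled;")
print("beta the fraction of mislabeled positives. The mean posterior is the")
print("fraction-of-positives estimate and should match alpha on this sample.")
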