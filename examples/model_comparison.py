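"""Compare the numerosity model against every visual-feature model.

Runs the full pipeline on a small synthetic population: stimuli for the
five regimes, thirteen feature tracks each, simulated numerosity-tuned
voxels, grid fits in configuration-specific and constrained scopes, and
paired signed-rank tests of variance explained.
"""

import numpref as npf

result = npf.run_pipeline(seed=7, n_voxels=40, cycles=10, noise_sd=0.5)

medians = (
    result.comparison.site_values.groupby(["scope", "model"]).overall_r2.median()
)
print("median R^2 per model (constrained scope):")
for model, med in medians["constrained"].sort_values(ascending=False).items():
    marker = " <-- reference" if model == "numerosity" else ""
    print(f"  {model:28s} {med:.3f}{marker}")

worst = result.comparison.tests.p.max()
print(f"\nlargest Wilcoxon p across all feature models and scopes: {worst:.2e}")
print(
    "\nOn voxels that are numerosity-tuned by construction, every feature\n"
    "model explains less variance than the numerosity model, and the paired\n"
    "test rejects equality for each — the direction the real recordings show."
)
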