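"""Simulate a prokaryote-style panel and run the full species-level analysis.

Builds 30 proteomes whose amino-acid composition drifts with an optimal
growth temperature evolved by Brownian motion on a Yule tree (imposed slope
0.05 pp ERK per degC), then reports the naive correlations, the life-style
group tests, and the phylogenetically corrected contrast correlation.
"""

from thermobias import pipeline, synthetic

cfg = synthetic.GeneratorConfig(n_species=30, n_proteins=60, seed=8)
panel = synthetic.simulate_panel(cfg)
report = pipeline.run_prokaryote_analysis(
    panel.proteomes, panel.traits, tree=panel.tree, n_permutations=999, per_aa=False
)

pearson = report["pearson_erk_vs_temperature"]
spearman = report["spearman_erk_vs_temperature"]
contrasts = report["contrasts"]
print(f"naive Pearson R = {pearson.statistic:.2f} (p = {pearson.pvalue:.2g})")
print(f"naive Spearman rho = {spearman.statistic:.2f} (p = {spearman.pvalue:.2g})")
for name, test in report["group_tests"].items():
    print(f"group test {name}: p = {test.pvalue:.3g}")
print(
    f"contrast R = {contrasts['r_contrasts']:.2f}, "
    f"randomization p = {contrasts['p_randomization']:.4g} "
    f"({contrasts['n_permutations']} permutations)"
)
print(
    "\nA positive naive R shows the cross-species ERK-temperature trend; the"
    "\ncontrast R shows it survives correction for shared ancestry, as it"
    "\nmust here - the generator imposed a real composition-temperature slope."
)
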