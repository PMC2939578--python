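"""Endotherm-versus-ectotherm group tests on the published vertebrate table.

Loads the bundled 11-species table (typical operating temperature and
concatenated co-ortholog ERK per species) and runs the rank-sum test on
genomic averages: 5 endotherms (mammals + chicken) against 6 ectotherms
(reptile, amphibians, fish).
"""

from thermobias import datasets, stats

table = datasets.vertebrate_panel()
endo = table[table.group == "endotherm"]
ecto = table[table.group == "ectotherm"]

print(table[["species", "group", "temperature", "erk"]].to_string(index=False))
for col in ("erk", "temperature"):
    res = stats.wilcoxon_ranksum(endo[col], ecto[col], method="normal_approx")
    print(f"\nWilcoxon on {col}: U = {res.statistic:.0f}, p = {res.pvalue:.2g}")
print(
    "\nBoth columns separate the two groups completely, so both tests give"
    "\nsmall p-values: endotherm proteomes run warmer AND carry higher ERK."
)
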