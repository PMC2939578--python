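"""GC-neutral codon matching: separating amino-acid bias from GC bias.

Two constructed ortholog sets make the logic visible.  In the first, every
E-versus-D difference is carried by codons that also differ in G+C count
(GAG vs GAT), so the apparent ERK gap is 'explained by GC': restricting to
GC-matched codon columns removes it entirely.  In the second, the same
amino-acid differences ride on GC-matched codons (GAA vs GAT), so the gap
survives the filter - evidence the bias lives at the protein level.
"""

from thermobias import synthetic
from thermobias.pipeline import matched_erk_comparison

for label, gc_changing in (("GC-driven gap", True), ("protein-level gap", False)):
    genes = synthetic.simulate_gc_confounded_orthologs(
        n_genes=200, gc_changing=gc_changing, seed=1
    )
    rep = matched_erk_comparison(genes, "gc_neutral")
    msg = f"{label}: mean ERK_A - ERK_B on GC-neutral codons = {rep['mean_gap']:+.2f} pp"
    if "wilcoxon" in rep:
        msg += f" (rank-sum p = {rep['wilcoxon'].pvalue:.2g})"
    print(msg)
print(
    "\nA gap that vanishes on GC-matched codons was a nucleotide-composition"
    "\nartifact; one that persists cannot be explained by GC content."
)
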