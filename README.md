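# thermobias

Tools for studying temperature-related bias in protein amino-acid
composition — across prokaryotes living at different optimal growth
temperatures (OGT) and between endothermic ("warm-blooded") and ectothermic
("cold-blooded") vertebrates — with proper control for phylogenetic
relatedness and for nucleotide-composition confounding.

It is a library for molecular-evolution researchers who want to compute
composition statistics from proteome FASTA files, run phylogenetically
independent contrasts with a permutation null, build reciprocal-best-hit
(RBH) ortholog panels from BLAST-style tabular output, and perform
codon-matched (GC-neutral / purine-neutral) controls — without genome-scale
infrastructure.

## The statistics at the core

For a protein (or a concatenated proteome), with each capital letter
denoting the fraction of that amino acid among all standard residues:

- **ERK** = E + R + K − D − N − Q − T − S − H − A, in percentage points.
  The enriched set stabilizes protein surfaces electrostatically at high
  temperature; the depleted set destabilizes them.  Higher ERK proxies
  greater thermostability.
- **CvP-bias** = D + E + R + K − N − Q − T − S (charged minus
  polar-uncharged); a correlated alternative differing from ERK only in the
  treatment of D, H and A.

Species-level values pool residue counts over the whole proteome
(length-weighted, not an average of per-protein scores).

Cross-species correlations of such statistics with temperature are
pseudo-replicated by shared ancestry, so association is assessed on
**Felsenstein's independent contrasts**: at each internal node of a
bifurcating tree with child values x₁, x₂ on (variance-extended) branches
v₁, v₂, the standardized contrast is (x₁ − x₂)/√(v₁+v₂).  Two traits'
contrasts are correlated through the origin,
R = Σxᵢyᵢ / √(Σxᵢ²·Σyᵢ²), and significance comes from a seeded permutation
test: shuffle the pairing N times (default N = 9999), count exceedances k,
and report p = (k+1)/(N+1).

To exclude nucleotide-level explanations, ortholog protein alignments are
back-mapped to their codons and the analysis restricted to aligned codon
pairs with equal G+C count (GC-neutral) or equal A+G count (purine-neutral);
an ERK difference that survives the restriction cannot be an artifact of
the matched nucleotide property.

## Worked example

`examples/vertebrate_group_test.py` runs the rank-sum test on the bundled
11-vertebrate species table (typical operating temperature and
concatenated co-ortholog ERK per species):

```
Wilcoxon on erk: U = 30, p = 0.0075
Wilcoxon on temperature: U = 30, p = 0.008
```

Both columns separate the 5 endotherms from the 6 ectotherms completely;
the p-values quantify how unlikely that separation is under exchangeable
group labels — endotherm proteomes run warmer and carry higher ERK.

`examples/prokaryote_panel.py` simulates a 30-species panel with an imposed
composition–temperature slope (0.05 pp ERK per °C) and runs the full
species-level analysis:

```
naive Pearson R = 0.77 (p = 8.5e-07)
naive Spearman rho = 0.73 (p = 3.8e-06)
group test mesophile_vs_thermophile: p = 0.00343
contrast R = 0.58, randomization p = 0.001 (999 permutations)
```

The naive R shows the cross-species trend; the contrast R shows it survives
correction for shared ancestry, as it must when the generator imposed a
real slope.  `examples/independent_contrasts.py` and
`examples/codon_matched_erk.py` walk through the contrast recursion and the
GC-neutral control in the same style.

A thin CLI mirrors the library (`thermobias compose | rbh | cogroups | pic
| randtest | wilcoxon | codon-match | simulate | run-prokaryote |
run-vertebrate | run-segments`); every run writes a manifest with input
checksums and seeds next to its output.

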