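# Methods

## Composition statistics

ERK and CvP-bias are linear functionals of the amino-acid frequency vector,
reported in percentage points (fractions × 100) so species-level values sit
on the familiar proteome scale (around −16 for vertebrates).  Frequencies
are computed over the 20 standard letters only; the ambiguity codes X, B,
Z, U and stop (*) are excluded from both numerator and denominator, so an
assembly artifact cannot dilute the statistic.  A sequence with no
countable residue is an error rather than a zero — a silent zero would bias
pooled values.  Species-level statistics pool residue counts across all
proteins (equivalently, a length-weighted mean of per-protein values);
pooling, not averaging, is what makes the concatenated value independent of
how the proteome happens to be split into records.

Codon-class usage (%AT-rich, %GC-rich) is computed over sense codons.  The
class of a codon is not uniquely defined in the literature, so the scheme
is explicit and recorded in the output: the default classifies by the
encoded amino acid (FYMINK = AT-rich, GARP = GC-rich — the standard
composition dichotomy, which also lands species values in the low-20s
percent range typical of vertebrate gene sets), and an alternative
classifies by the codon's own bases (all A/T vs all G/C).  Only the
standard nuclear genetic code is supported.

## Independent contrasts

Felsenstein's recursion is implemented directly: postorder over a
bifurcating tree, contrast (x₁ − x₂)/√(v₁+v₂) at each internal node, node
value set to the branch-weighted mean and the parent branch extended by
v₁v₂/(v₁+v₂).  Child order follows the newick text, which fixes the
(arbitrary) contrast signs reproducibly.  The implementation is
cross-checked in the test suite against hand-worked small trees and against
`ape::pic` in R as an independent oracle.

Zero-length branches make the standardization blow up; the default policy
replaces each zero branch with half the minimum positive branch length (a
fixed replacement value is also available).  Polytomies are an error by
default; an explicit `resolve_polytomies` arbitrarily bifurcates them into
zero-length branches and then applies the same adjustment.

Association between two contrast sets uses the through-origin correlation
R = Σxy/√(Σx²Σy²) — contrasts have no natural sign, so an intercept term
would be meaningless; R is invariant to pairwise sign flips, and a
`positivize` helper provides the conventional x ≥ 0 orientation for
diagnostics.  Parametric p-values use the t distribution with
n_contrasts − 1 degrees of freedom (one parameter, the slope through the
origin, is estimated).

The randomization test shuffles the pairing between the two contrast
vectors N times (default 9999) with a seeded generator and reports
p = (k+1)/(N+1), the observed data counting as one more randomization, so
p is bounded below by 1/(N+1).  The default alternative counts
R_rand ≥ R_obs — a one-sided test of positive association whose null
distribution is uniform; choosing the tail after seeing the sign of R_obs
(available as `alternative="observed"`) halves the effective p under the
null and is provided only for comparability.  A sign-flip null is available
behind a flag; the permutation null is the default because it randomizes
exactly the association while preserving both marginal contrast
distributions.

## Orthology

RBH uses a deterministic tie-break ladder — bit score, then e-value, then
lexicographically smallest subject id — so results are identical across
platforms and input orderings.  Hit tables are reduced to the best HSP per
(query, subject) by the same ladder before RBH; bit score is the criterion
because it is database-size independent.  The life-style filter retains a
protein iff it has at least one ortholog in a different temperature group;
the co-ortholog construction emits a group only for reference proteins with
an RBH partner in every other species of the panel.

The built-in aligner is global Needleman–Wunsch (BLOSUM62; BLAST-style
affine gaps, default open 11 / extend 1, i.e. a gap of length k costs
11 + k) via Biopython's PairwiseAligner, intended for desk-scale segment
pairs; externally produced alignments are accepted as files wherever
alignments are consumed.  E-values are always read from input, never
computed.

## Codon-matched controls

Protein alignments are back-mapped onto codons after verifying that each
ungapped protein equals the translation of its CDS (terminal stop
ignored); a mismatch is an error, not a warning, because a frame error
would silently corrupt every downstream count.  Gap columns are skipped;
columns with ambiguous bases are dropped and counted for auditability.
"Same GC content" is read per aligned codon pair as equal integer G+C
count (0–3) — the coarsest faithful matching — and purine matching
analogously on A+G.  Matched ERK re-translates only the retained codons.
Downstream testing treats per-gene ERK pairs as the unit (rank-sum across
genes); pooled-codon testing is possible by concatenating pair lists, which
the filter commutes with.

## Synthetic data

The generators produce every input the pipeline consumes, with the
dependence structure the analysis assumes:

- **Tree**: pure-birth (Yule) with unit birth rate; ultrametric; after the
  n-th lineage appears the process runs one more exponential waiting time.
- **Temperature**: Brownian motion along branches, default root 50 °C and
  rate σ² = 100 °C² per unit branch (tip spreads of a few tens of °C on a
  50-leaf unit-rate tree), optionally clamped to 0–103 °C — the range over
  which composition–stability relations are approximately linear.  Clamping
  breaks exact BM, so calibration runs leave it off.
- **Proteomes**: residues i.i.d. from a baseline frequency vector (uniform
  0.05 by default, baseline ERK −20 pp) tilted so the expected ERK is
  baseline + β(T − T_root), with mass moved proportionally from the
  depleted to the enriched letters; β defaults to 0.05 pp/°C.  The tilt is
  exact in expectation, which is what makes slope-recovery tests
  well-posed.  i.i.d. sampling is adequate because ERK is order-invariant.
- **CDS**: synonymous codons chosen with third-position G/C probability
  gc3 (falling back when an amino acid has no choice); translation
  round-trips exactly.
- **Ortholog families**: one ancestor per family, sites replaced along
  each branch with probability 1 − exp(−rate·length), replacements drawn
  from the descendant's tilted composition; hit tables score 2 bits per
  identical ungapped position, so ortholog scores fall with divergence
  while background pairs sit near the random-identity floor.
- **Confounded panel**: two clades joined by long stem branches (default
  200 vs inner branches of 1); one clade carries a +20 °C offset and an
  independent +0.01 drift of one residue's frequency, both acquired on the
  stem.  A naive correlation sees two coincident clusters; the contrasts
  divide the single informative difference by the long stem and recover
  nothing — there is no causal slope anywhere (β = 0).  The long stem is
  essential: a clade shift across a short branch would produce one giant
  standardized contrast and the correction would not attenuate it.
- **GC-confounded orthologs**: E↔D substitutions carried either by
  GC-changing codons (GAG vs GAT; the GC-neutral filter removes every
  informative column, collapsing the matched ERK gap to exactly zero) or by
  GC-matched codons (GAA vs GAT; the gap survives filtering).

What the generators do **not** emulate: site-rate heterogeneity, indels,
realistic per-species codon-usage tables, selection on structure, or gene
gain/loss.  Passing tests therefore demonstrate that the statistical
machinery behaves correctly under its own model assumptions — not that
those assumptions hold for real genomes.

## Test and run sizes

Test panels use 10–50 species with 30–150 proteins of 80–300 residues —
sizes at which the imposed effects are several times the composition
sampling noise (per-species ERK noise scales as ~100·√(0.46/n_residues)
pp), chosen so detection tests measure correctness rather than power.
Monte-Carlo calibrations use 200-leaf trees for contrast variance (pooled
over five replicate trees in the acceptance script, ~1000 contrasts), 300
replicates at N = 199 permutations for null-p uniformity, and 10 seeds for
the confounding scenario.  The exact-vs-normal rank-sum comparison is
exhaustive over all C(16,8) tie-free arrangements at n₁ = n₂ = 8; the
enumerated worst-case disagreement there is 0.011 (mean ≈ 0.006), which is
the bound the tests assert — the normal approximation is simply not closer
than that at such sample sizes, and it degrades quickly below them.

## Known limitations

- The rank-sum normal approximation is unreliable below ~6 observations
  per group; `auto` prefers the exact method for small tie-free samples.
- Contrast p-values from the t distribution assume Brownian evolution;
  the randomization p is the safer default at small n.
- The built-in aligner is O(mn) and meant for segments, not proteomes.
- RBH is one-to-one by construction; lineage-specific duplicates
  (in-paralogs) are not clustered.
- Species-level codon-class percentages weight genes by codon count;
  per-gene weighting would differ when gene lengths vary systematically.
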