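"""End-to-end analyses: prokaryote panel, vertebrate panel, segment pairs.

Each function takes in-memory objects produced by :mod:`seqio` /
:mod:`synthetic`, runs the composition, orthology, contrast and test
machinery, and returns a plain-dict report whose leaves are floats,
DataFrames and small dicts — directly serializable for the CLI's TSV/JSON
output.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import codon_controls, composition, orthology, phylo, seqio, stats

logger = logging.getLogger(__name__)


def species_bias_table(
    proteomes: Mapping[str, Sequence[seqio.ProteinRecord]]
) -> pd.DataFrame:
    """Concatenated-proteome ERK and CvP per species."""
    rows = []
    for sp in sorted(proteomes):
        freqs = composition.proteome_frequencies(proteomes[sp])
        rows.append(
            {
                "species": sp,
                "n_proteins": len(proteomes[sp]),
                "n_residues": freqs.length,
                "erk": composition.erk_score(freqs),
                "cvp": composition.cvp_score(freqs),
            }
        )
    return pd.DataFrame(rows)


def _contrast_analysis(tree, species_values, temperatures, n_permutations, seed):
    ct = phylo.independent_contrasts(tree, temperatures, "temperature")
    ce = phylo.independent_contrasts(tree, species_values, "bias")
    rand = phylo.randomization_pvalue(ct, ce, n_permutations=n_permutations, seed=seed)
    return {
        "r_contrasts": rand.r_observed,
        "p_randomization": rand.pvalue,
        "p_t": phylo.contrast_correlation_pvalue(rand.r_observed, len(ct)),
        "n_contrasts": len(ct),
        "n_permutations": rand.n_permutations,
        "seed": rand.seed,
    }


def run_prokaryote_analysis(
    proteomes: Mapping[str, Sequence[seqio.ProteinRecord]],
    traits: pd.DataFrame,
    tree: phylo.Phylogeny | None = None,
    n_permutations: int = 9999,
    seed: int = 0,
    per_aa: bool = True,
) -> dict:
    """Species-level bias vs optimal growth temperature.

    Reports per-species ERK/CvP, naive Pearson and Spearman correlations
    with OGT, pairwise Wilcoxon tests between OGT life-style groups, the
    per-amino-acid naive/comparative profile, and the contrast correlation
    with its randomization p (when a tree is given).
    """
    traits = seqio.assign_ogt_groups(traits)
    panel = set(proteomes)
    tabled = set(traits["species"])
    if panel != tabled:
        raise ValueError(
            f"species mismatch between proteomes and traits: {sorted(panel ^ tabled)}"
        )
    bias = species_bias_table(proteomes)
    bias = bias.merge(traits, on="species")
    report: dict = {"species_table": bias}
    report["pearson_erk_vs_temperature"] = stats.pearson(
        bias["erk"], bias["temperature"]
    )
    report["spearman_erk_vs_temperature"] = stats.spearman(
        bias["erk"], bias["temperature"]
    )
    group_tests = {}
    by_group = {g: df["erk"].to_numpy() for g, df in bias.groupby("group")}
    for g1, g2 in combinations(sorted(by_group), 2):
        if len(by_group[g1]) and len(by_group[g2]):
            group_tests[f"{g1}_vs_{g2}"] = stats.wilcoxon_ranksum(
                by_group[g1], by_group[g2], method="normal_approx"
            )
    if len(by_group) < 2:
        logger.info("all species share one life-style group; group tests skipped")
    report["group_tests"] = group_tests
    if per_aa:
        report["per_aa_profile"] = phylo.per_aa_temperature_profile(
            proteomes, traits, tree=tree
        )
    if tree is not None:
        temps = dict(zip(traits["species"], traits["temperature"]))
        erks = dict(zip(bias["species"], bias["erk"]))
        report["contrasts"] = _contrast_analysis(
            tree, erks, temps, n_permutations, seed
        )
    return report


def run_vertebrate_analysis(
    proteomes: Mapping[str, Sequence[seqio.ProteinRecord]],
    traits: pd.DataFrame,
    tree: phylo.Phylogeny | None = None,
    reference: str | None = None,
    hit_tables: Mapping[tuple[str, str], pd.DataFrame] | None = None,
    cds: Mapping[str, Sequence[seqio.CdsRecord]] | None = None,
    codon_scheme: str = "fymink_garp",
    n_permutations: int = 9999,
    seed: int = 0,
) -> dict:
    """Endotherm-versus-ectotherm bias analysis.

    Reports per-species concatenated ERK/CvP, the endo-vs-ecto Wilcoxon on
    genomic averages, contrast correlation with randomization p (tree
    given), codon-class usage (CDS given), co-ortholog group count and
    per-species one-sided tests against reference orthologs (hit tables
    given).
    """
    groups = dict(zip(traits["species"], traits["group"]))
    if any(pd.isna(g) for g in groups.values()):
        raise ValueError("every species needs an endotherm/ectotherm group label")
    bias = species_bias_table(proteomes).merge(traits, on="species")
    report: dict = {"species_table": bias}
    endo = bias.loc[bias["group"] == seqio.ENDOTHERM, "erk"].to_numpy()
    ecto = bias.loc[bias["group"] == seqio.ECTOTHERM, "erk"].to_numpy()
    if len(endo) == 0 or len(ecto) == 0:
        raise ValueError("group test needs both endotherm and ectotherm species")
    report["wilcoxon_erk_genomic_averages"] = stats.wilcoxon_ranksum(
        endo, ecto, method="normal_approx"
    )
    report["wilcoxon_temperature"] = stats.wilcoxon_ranksum(
        bias.loc[bias["group"] == seqio.ENDOTHERM, "temperature"].to_numpy(),
        bias.loc[bias["group"] == seqio.ECTOTHERM, "temperature"].to_numpy(),
        method="normal_approx",
    )
    if tree is not None:
        temps = dict(zip(traits["species"], traits["temperature"]))
        erks = dict(zip(bias["species"], bias["erk"]))
        report["contrasts"] = _contrast_analysis(tree, erks, temps, n_permutations, seed)
    if cds is not None:
        rows = []
        for sp in sorted(cds):
            usages = [
                composition.codon_class_fractions(rec, scheme=codon_scheme)
                for rec in cds[sp]
            ]
            weights = np.array([u.n_codons for u in usages], dtype=float)
            rows.append(
                {
                    "species": sp,
                    "pct_at_rich": float(
                        np.average([u.pct_at_rich for u in usages], weights=weights)
                    ),
                    "pct_gc_rich": float(
                        np.average([u.pct_gc_rich for u in usages], weights=weights)
                    ),
                }
            )
        report["codon_class_table"] = pd.DataFrame(rows)
    if hit_tables is not None:
        if reference is None:
            raise ValueError("hit tables supplied but no reference species named")
        if reference not in proteomes:
            raise ValueError(f"reference species {reference!r} not in the panel")
        pairs = []
        per_species_tests = {}
        ref_profiles = {
            p.id: p.erk
            for p in (composition.composition_profile(r) for r in proteomes[reference])
        }
        for sp in sorted(proteomes):
            if sp == reference:
                continue
            rbh = orthology.reciprocal_best_hits(
                hit_tables[(reference, sp)],
                hit_tables[(sp, reference)],
                species_a=reference,
                species_b=sp,
            )
            pairs.extend(rbh)
            sp_erk = {
                p.id: p.erk
                for p in (composition.composition_profile(r) for r in proteomes[sp])
            }
            own = [sp_erk[p.protein_b] for p in rbh]
            ref = [ref_profiles[p.protein_a] for p in rbh]
            if own and ref:
                per_species_tests[sp] = stats.wilcoxon_ranksum(
                    own, ref, method="normal_approx", sides="greater"
                )
        groups_found = orthology.co_ortholog_groups(
            pairs, reference, species_panel=proteomes
        )
        report["co_ortholog_groups"] = len(groups_found)
        report["per_species_vs_reference"] = per_species_tests
    return report


def run_segment_comparison(
    pairs_by_label: Mapping[str, Sequence[tuple[str, str]]],
) -> pd.DataFrame:
    """Per-label rank-sum test of segment ERK between two aligned sides.

    Each pair is a (query segment, subject segment) alignment; gaps are
    stripped before computing ERK.  One row per label with the per-side
    mean ERK and the two-sided Wilcoxon p across segment pairs.
    """
    rows = []
    for label in sorted(pairs_by_label):
        pairs = pairs_by_label[label]
        if not pairs:
            raise ValueError(f"comparison {label!r} has no aligned pairs")
        erk_q, erk_s = [], []
        for q, s in pairs:
            erk_q.append(
                composition.erk_score(
                    composition.amino_acid_frequencies(q.replace("-", ""))
                )
            )
            erk_s.append(
                composition.erk_score(
                    composition.amino_acid_frequencies(s.replace("-", ""))
                )
            )
        test = stats.wilcoxon_ranksum(erk_q, erk_s, method="normal_approx")
        rows.append(
            {
                "label": label,
                "n_segments": len(pairs),
                "mean_erk_query": float(np.mean(erk_q)),
                "mean_erk_subject": float(np.mean(erk_s)),
                "pvalue": test.pvalue,
            }
        )
    return pd.DataFrame(rows)


def matched_erk_comparison(
    gene_tuples: Sequence[tuple[str, str, str, str, str]],
    mode: codon_controls.Mode,
) -> dict:
    """Codon-matched ERK over a set of ortholog pairs.

    ``gene_tuples`` are (gene_id, aligned_a, aligned_b, cds_a, cds_b).
    Back-maps each protein alignment to codons, applies the matched-codon
    filter, and tests the per-gene ERK values of side A against side B
    (rank-sum across genes, the default unit of testing).
    """
    cpas = [
        codon_controls.backmap_codons(a, b, ca, cb, gene_id=g)
        for g, a, b, ca, cb in gene_tuples
    ]
    table = codon_controls.matched_erk_table(cpas, mode)
    report = {"table": table, "mode": mode, "n_genes": len(table)}
    if len(table) >= 2 and (table["erk_a"] != table["erk_b"]).any():
        report["wilcoxon"] = stats.wilcoxon_ranksum(
            table["erk_a"].to_numpy(), table["erk_b"].to_numpy(), method="normal_approx"
        )
    report["mean_gap"] = float((table["erk_a"] - table["erk_b"]).mean())
    return report
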