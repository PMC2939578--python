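"""Codon-matched controls for nucleotide-composition confounding.

Genome-wide GC content (and purine loading) predicts amino-acid composition,
so an amino-acid bias between two species could be a side effect of
nucleotide bias rather than selection on the protein.  The control:
back-map a protein alignment of an ortholog pair onto its coding sequences,
keep only aligned codon columns where both species have the same G+C count
(GC-neutral) or the same A+G count (purine-neutral), and recompute ERK on
the amino acids encoded by the surviving codons.  A composition difference
that persists on matched codons cannot be explained by the matched
nucleotide property.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from .composition import (
    CODON_TO_AA,
    amino_acid_frequencies,
    erk_score,
    split_codons,
)

Mode = Literal["gc_neutral", "purine_neutral"]


def gc_count(codon: str) -> int:
    """Number of G or C bases in a codon (0-3)."""
    return sum(1 for b in codon if b in "GC")


def purine_count(codon: str) -> int:
    """Number of purine (A or G) bases in a codon (0-3)."""
    return sum(1 for b in codon if b in "AG")


@dataclass(frozen=True)
class CodonPairAlignment:
    """Aligned, gap-free sense-codon columns of one ortholog pair."""

    gene_id: str
    pairs: tuple[tuple[str, str], ...]
    n_columns: int
    n_dropped_ambiguous: int


def _translate(cds: str) -> str:
    codons = split_codons(cds)
    if codons and CODON_TO_AA.get(codons[-1]) is None and codons[-1] in {"TAA", "TAG", "TGA"}:
        codons = codons[:-1]
    out = []
    for idx, codon in enumerate(codons):
        aa = CODON_TO_AA.get(codon)
        if aa is None:
            if codon in {"TAA", "TAG", "TGA"}:
                raise ValueError(f"internal stop codon at codon index {idx}")
            out.append("X")  # ambiguous bases
        else:
            out.append(aa)
    return "".join(out)


def backmap_codons(
    aligned_a: str,
    aligned_b: str,
    cds_a: str,
    cds_b: str,
    gene_id: str = "",
) -> CodonPairAlignment:
    """Replace the amino acids of a pairwise protein alignment with their
    encoding codons.

    The ungapped protein sequences must equal the translations of their CDS
    (a terminal stop is ignored).  Columns where either side is a gap are
    skipped; columns whose codon contains an ambiguous base on either side
    are dropped and counted.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences differ in length")
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    for label, aligned, cds in (("A", aligned_a, cds_a), ("B", aligned_b, cds_b)):
        protein = aligned.replace("-", "").upper()
        trans = _translate(cds)
        if len(trans) != len(protein):
            raise ValueError(
                f"side {label}: CDS encodes {len(trans)} residues but protein has {len(protein)}"
            )
        for i, (x, y) in enumerate(zip(protein, trans)):
            if x != y and "X" not in (x, y):
                raise ValueError(
                    f"side {label}: translation mismatch at residue {i} ({x!r} != {y!r})"
                )
    codons_a = split_codons(cds_a)
    codons_b = split_codons(cds_b)
    ia = ib = 0
    kept: list[tuple[str, str]] = []
    dropped = 0
    for col_a, col_b in zip(aligned_a.upper(), aligned_b.upper()):
        ca = cb = None
        if col_a != "-":
            ca = codons_a[ia]
            ia += 1
        if col_b != "-":
            cb = codons_b[ib]
            ib += 1
        if ca is None or cb is None:
            continue
        if set(ca) - set("ACGT") or set(cb) - set("ACGT"):
            dropped += 1
            continue
        kept.append((ca, cb))
    return CodonPairAlignment(gene_id, tuple(kept), len(kept) + dropped, dropped)


def matched_codon_filter(cpa: CodonPairAlignment, mode: Mode) -> CodonPairAlignment:
    """Keep codon pairs with equal G+C counts (``gc_neutral``) or equal A+G
    counts (``purine_neutral``); order preserved, idempotent."""
    if mode == "gc_neutral":
        count = gc_count
    elif mode == "purine_neutral":
        count = purine_count
    else:
        raise ValueError(f"unknown mode {mode!r}")
    kept = tuple(p for p in cpa.pairs if count(p[0]) == count(p[1]))
    return CodonPairAlignment(cpa.gene_id, kept, cpa.n_columns, cpa.n_dropped_ambiguous)


def matched_erk(cpa: CodonPairAlignment) -> tuple[float, float, int]:
    """ERK of each side computed from the retained codons' translations.

    Returns (ERK_A, ERK_B, number of codon pairs used).  Raises when the
    retained set is empty (the caller should skip such over-filtered genes).
    """
    if not cpa.pairs:
        raise ValueError(f"gene {cpa.gene_id!r}: no codon pairs retained")
    aa_a = "".join(CODON_TO_AA[ca] for ca, _ in cpa.pairs)
    aa_b = "".join(CODON_TO_AA[cb] for _, cb in cpa.pairs)
    return (
        erk_score(amino_acid_frequencies(aa_a)),
        erk_score(amino_acid_frequencies(aa_b)),
        len(cpa.pairs),
    )


def matched_erk_table(
    alignments: Sequence[CodonPairAlignment], mode: Mode
):
    """Per-gene matched ERK for a set of ortholog pairs.

    Returns a DataFrame (gene, n_total, n_kept, erk_a, erk_b); genes whose
    retained set is empty after filtering are skipped.
    """
    import pandas as pd

    rows = []
    for cpa in alignments:
        filtered = matched_codon_filter(cpa, mode)
        if not filtered.pairs:
            continue
        erk_a, erk_b, n_kept = matched_erk(filtered)
        rows.append(
            {
                "gene": cpa.gene_id,
                "n_total": len(cpa.pairs),
                "n_kept": n_kept,
                "erk_a": erk_a,
                "erk_b": erk_b,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "n_total", "n_kept", "erk_a", "erk_b"])
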