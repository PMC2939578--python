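"""Amino-acid composition statistics: ERK, CvP-bias and codon-class usage.

ERK sums the fractions of the amino acids enriched on thermophile protein
surfaces (E, R, K) and subtracts the depleted ones (D, N, Q, T, S, H, A).
CvP-bias is the charged-minus-polar alternative, D+E+R+K-N-Q-T-S.  Both are
reported in percentage points (fractions x 100) so that species-level values
land on the scale commonly printed for vertebrate proteomes (around -16).

Codon-class usage splits sense codons into AT-rich and GC-rich classes.  The
default scheme classifies by the encoded amino acid (FYMINK = AT-rich,
GARP = GC-rich); an alternative classifies by the codon's own bases (all
A/T vs all G/C).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

from Bio.Data.CodonTable import standard_dna_table

from .seqio import CdsRecord, ProteinRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

ERK_ENRICHED = frozenset("ERK")
ERK_DEPLETED = frozenset("DNQTSHA")
CVP_CHARGED = frozenset("DERK")
CVP_POLAR = frozenset("NQTS")

AT_RICH_AA = frozenset("FYMINK")
GC_RICH_AA = frozenset("GARP")

CODON_TO_AA: Mapping[str, str] = standard_dna_table.forward_table
STOP_CODONS = frozenset(standard_dna_table.stop_codons)


@dataclass(frozen=True)
class AminoAcidFrequencies:
    """Fractions of the 20 standard amino acids; ambiguity codes and stops
    are excluded from both numerator and denominator."""

    fractions: Mapping[str, float]
    length: int

    def __getitem__(self, aa: str) -> float:
        return self.fractions.get(aa, 0.0)


@dataclass(frozen=True)
class CompositionProfile:
    id: str
    erk: float
    cvp: float
    frequencies: AminoAcidFrequencies


@dataclass(frozen=True)
class CodonClassUsage:
    pct_at_rich: float
    pct_gc_rich: float
    scheme: str
    n_codons: int


def amino_acid_frequencies(sequence: str) -> AminoAcidFrequencies:
    """Count the 20 standard letters; skip X/B/Z/U/* entirely.

    Raises ``ValueError`` when no countable residue remains.
    """
    counts = Counter(sequence.upper())
    total = sum(counts[aa] for aa in AMINO_ACIDS)
    if total == 0:
        raise ValueError("sequence has no countable standard amino acids")
    return AminoAcidFrequencies(
        {aa: counts[aa] / total for aa in AMINO_ACIDS}, total
    )


def erk_score(freqs: AminoAcidFrequencies) -> float:
    """E+R+K - D-N-Q-T-S-H-A, in percentage points."""
    return 100.0 * (
        sum(freqs[a] for a in ERK_ENRICHED) - sum(freqs[a] for a in ERK_DEPLETED)
    )


def cvp_score(freqs: AminoAcidFrequencies) -> float:
    """D+E+R+K - N-Q-T-S (charged minus polar-uncharged), in percentage points."""
    return 100.0 * (
        sum(freqs[a] for a in CVP_CHARGED) - sum(freqs[a] for a in CVP_POLAR)
    )


def composition_profile(record: ProteinRecord) -> CompositionProfile:
    freqs = amino_acid_frequencies(record.sequence)
    return CompositionProfile(record.id, erk_score(freqs), cvp_score(freqs), freqs)


def proteome_bias(
    proteome: Iterable[ProteinRecord], measure: Literal["ERK", "CvP"] = "ERK"
) -> tuple[list[CompositionProfile], float]:
    """Per-protein profiles plus the concatenated-proteome value.

    The species-level value pools residue counts across all proteins
    (equivalently, a length-weighted mean of per-protein values) — it is not
    the unweighted mean of per-protein scores.
    """
    proteome = list(proteome)
    if not proteome:
        raise ValueError("empty proteome")
    profiles = [composition_profile(rec) for rec in proteome]
    pooled = Counter()
    for rec in proteome:
        pooled.update(ch for ch in rec.sequence.upper() if ch in set(AMINO_ACIDS))
    total = sum(pooled.values())
    if total == 0:
        raise ValueError("proteome has no countable residues")
    freqs = AminoAcidFrequencies({aa: pooled[aa] / total for aa in AMINO_ACIDS}, total)
    score = erk_score(freqs) if measure == "ERK" else cvp_score(freqs)
    return profiles, score


def proteome_frequencies(proteome: Iterable[ProteinRecord]) -> AminoAcidFrequencies:
    """Pooled amino-acid frequencies of a whole proteome."""
    pooled = Counter()
    standard = set(AMINO_ACIDS)
    for rec in proteome:
        pooled.update(ch for ch in rec.sequence.upper() if ch in standard)
    total = sum(pooled.values())
    if total == 0:
        raise ValueError("proteome has no countable residues")
    return AminoAcidFrequencies({aa: pooled[aa] / total for aa in AMINO_ACIDS}, total)


def split_codons(cds: str) -> list[str]:
    seq = cds.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def codon_class_fractions(
    cds: CdsRecord | str,
    scheme: Literal["fymink_garp", "all_at_gc"] = "fymink_garp",
) -> CodonClassUsage:
    """%AT-rich and %GC-rich codon usage over all sense codons.

    ``fymink_garp`` classifies by encoded amino acid (AT-rich: F,Y,M,I,N,K;
    GC-rich: G,A,R,P; everything else unclassified).  ``all_at_gc``
    classifies a codon as AT-rich when all three bases are A/T and GC-rich
    when all three are G/C.  A terminal stop codon is allowed; an internal
    stop is an error.  Codons containing ambiguous bases are skipped.
    """
    seq = cds.sequence if isinstance(cds, CdsRecord) else cds
    codons = split_codons(seq)
    n_at = n_gc = n_sense = 0
    for idx, codon in enumerate(codons):
        if codon in STOP_CODONS:
            if idx != len(codons) - 1:
                raise ValueError(f"internal stop codon at codon index {idx}")
            continue
        if set(codon) - set("ACGT"):
            continue
        n_sense += 1
        if scheme == "fymink_garp":
            aa = CODON_TO_AA[codon]
            if aa in AT_RICH_AA:
                n_at += 1
            elif aa in GC_RICH_AA:
                n_gc += 1
        elif scheme == "all_at_gc":
            if set(codon) <= set("AT"):
                n_at += 1
            elif set(codon) <= set("GC"):
                n_gc += 1
        else:
            raise ValueError(f"unknown codon classification scheme {scheme!r}")
    if n_sense == 0:
        raise ValueError("no sense codons to classify")
    return CodonClassUsage(
        100.0 * n_at / n_sense, 100.0 * n_gc / n_sense, scheme, n_sense
    )
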