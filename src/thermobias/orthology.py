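"""Ortholog inference from similarity tables, plus a desk-scale aligner.

Reciprocal best hits (RBH) are the standard heuristic for one-to-one
orthology: two proteins that are each other's top-scoring cross-species
match.  On top of RBH pairs this module builds the two panel constructions
used downstream — life-style-filtered prokaryote sets (keep proteins with at
least one ortholog outside their own temperature group) and
reference-anchored ubiquitous co-ortholog groups (reference proteins with an
RBH partner in every other species of the panel).

``align_pair`` is a small global Needleman-Wunsch (BLOSUM62, BLAST-style
affine gaps 11/1 by default) for aligning hit segments at desk scale;
externally produced alignments are accepted as files wherever alignments are
consumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class OrthologPair:
    species_a: str
    protein_a: str
    species_b: str
    protein_b: str
    bitscore: float

    def mirrored(self) -> "OrthologPair":
        return OrthologPair(
            self.species_b, self.protein_b, self.species_a, self.protein_a, self.bitscore
        )


@dataclass(frozen=True)
class CoOrthologGroup:
    """One reference protein plus exactly one ortholog per non-reference species."""

    reference_id: str
    members: Mapping[str, str]


@dataclass(frozen=True)
class SegmentAlignment:
    query: str
    subject: str
    evalue: float


def best_hits(hits: pd.DataFrame) -> dict[str, str]:
    """Best subject per query: max bit score, ties broken by min e-value,
    then lexicographically smallest subject id."""
    if hits.empty:
        return {}
    df = hits.sort_values(
        ["query", "bitscore", "evalue", "subject"],
        ascending=[True, False, True, True],
        kind="stable",
    )
    top = df.drop_duplicates("query", keep="first")
    return dict(zip(top["query"], top["subject"]))


def reciprocal_best_hits(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    species_a: str = "A",
    species_b: str = "B",
) -> list[OrthologPair]:
    """RBH pairs: (a, b) kept iff b is a's best hit and a is b's best hit.

    Queries without hits are skipped.  Bit score reported is that of the
    A->B best hit.
    """
    fwd = best_hits(hits_ab)
    rev = best_hits(hits_ba)
    score = dict(zip(zip(hits_ab["query"], hits_ab["subject"]), hits_ab["bitscore"]))
    pairs = []
    for a in sorted(fwd):
        b = fwd[a]
        if rev.get(b) == a:
            pairs.append(OrthologPair(species_a, a, species_b, b, float(score[(a, b)])))
    return pairs


def lifestyle_filtered_set(
    pairs: Iterable[OrthologPair], labels: Mapping[str, str]
) -> dict[str, set[str]]:
    """Retain proteins with at least one ortholog outside their own life-style
    group; proteins whose orthologs all share their group (or that have no
    orthologs at all) are dropped."""
    retained: dict[str, set[str]] = {}
    for p in pairs:
        for sp in (p.species_a, p.species_b):
            if sp not in labels:
                raise ValueError(f"species {sp!r} has no life-style label")
        if labels[p.species_a] != labels[p.species_b]:
            retained.setdefault(p.species_a, set()).add(p.protein_a)
            retained.setdefault(p.species_b, set()).add(p.protein_b)
    return retained


def co_ortholog_groups(
    pairs: Iterable[OrthologPair],
    reference: str,
    species_panel: Iterable[str] | None = None,
) -> list[CoOrthologGroup]:
    """Reference-anchored ubiquitous ortholog groups.

    ``pairs`` are RBH pairs each involving the reference species.  A group
    is emitted for every reference protein with an RBH partner in every
    non-reference species of the panel (inferred from the pairs when not
    given explicitly).
    """
    partner: dict[str, dict[str, str]] = {}
    seen_species: set[str] = set()
    for p in pairs:
        if p.species_a == reference:
            ref_id, other_sp, other_id = p.protein_a, p.species_b, p.protein_b
        elif p.species_b == reference:
            ref_id, other_sp, other_id = p.protein_b, p.species_a, p.protein_a
        else:
            raise ValueError(
                f"pair ({p.protein_a}, {p.protein_b}) does not involve reference {reference!r}"
            )
        seen_species.add(other_sp)
        partner.setdefault(ref_id, {})[other_sp] = other_id
    panel = set(species_panel) - {reference} if species_panel else seen_species
    groups = [
        CoOrthologGroup(ref_id, dict(sorted(members.items())))
        for ref_id, members in sorted(partner.items())
        if set(members) >= panel
    ]
    return groups


def align_pair(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    evalue: float = 0.0,
) -> SegmentAlignment:
    """Optimal global alignment of two protein segments.

    Gap costs follow the BLAST convention: a gap of length k costs
    ``gap_open + k * gap_extend``.  Among co-optimal alignments the
    aligner's first traceback is returned, which is deterministic.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(a.upper(), b.upper())[0]
    return SegmentAlignment(str(aln[0]), str(aln[1]), evalue)
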