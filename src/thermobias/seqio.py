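"""Readers and writers for the external formats the pipeline consumes.

Protein and nucleotide FASTA go through :mod:`Bio.SeqIO`; trait tables and
tabular similarity ("hit") tables go through :mod:`pandas`.  All readers
enforce the hygiene the downstream statistics rely on: unique ids, non-empty
upper-cased sequences, legal alphabets, finite temperatures and a single
best HSP per (query, subject) pair.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROTEIN_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")
#: ambiguity codes tolerated in protein input (skipped by composition stats)
PROTEIN_EXTRA = set("XBZU*")
DNA_LETTERS = set("ACGTN")

#: canonical column order of the reduced similarity-table dialect
HIT_COLUMNS = ["query", "subject", "pident", "length", "evalue", "bitscore"]

#: life-style groups used for prokaryote panels, from optimal growth temperature
HYPERTHERMOPHILE = "hyperthermophile"
THERMOPHILE = "thermophile"
MESOPHILE = "mesophile"
ENDOTHERM = "endotherm"
ECTOTHERM = "ectotherm"


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence; ``id`` is the first whitespace token of the header."""

    id: str
    sequence: str


@dataclass(frozen=True)
class CdsRecord:
    """One coding sequence over {A,C,G,T,N}, keyed to a protein id when paired."""

    id: str
    sequence: str


class FastaError(ValueError):
    pass


def _validate(seq: str, allowed: set[str], rec_id: str) -> None:
    for pos, ch in enumerate(seq):
        if ch not in allowed:
            raise FastaError(
                f"illegal character {ch!r} at position {pos} in record {rec_id!r}"
            )


def read_fasta(path, alphabet: Literal["protein", "dna"] = "protein"):
    """Parse a FASTA file into :class:`ProteinRecord` or :class:`CdsRecord` lists.

    Sequences are upper-cased; ids are the first whitespace-delimited header
    token and must be unique.  Empty sequences and characters outside the
    declared alphabet raise :class:`FastaError`.
    """
    if alphabet == "protein":
        allowed, factory = PROTEIN_LETTERS | PROTEIN_EXTRA, ProteinRecord
    elif alphabet == "dna":
        allowed, factory = DNA_LETTERS, CdsRecord
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            raise FastaError(f"duplicate id {rid!r} in {path}")
        seen.add(rid)
        seq = str(rec.seq).upper().replace(" ", "")
        if not seq:
            raise FastaError(f"empty sequence for id {rid!r} in {path}")
        _validate(seq, allowed, rid)
        records.append(factory(rid, seq))
    return records


def write_fasta(records: Iterable[ProteinRecord | CdsRecord], path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


# -- trait tables -----------------------------------------------------------

_RANGE_WITH_LEAD = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*\(")
_BARE_RANGE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*-\s*(\d+(?:\.\d+)?)\s*$")


def parse_temperature(value) -> float:
    """Reduce a temperature cell to a single float.

    Accepts a plain number, a ``"26 (24- 28)"`` style cell (the leading value
    is authoritative) or a bare range ``"24-28"`` (reduced to the midpoint).
    """
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip()
    m = _RANGE_WITH_LEAD.match(text)
    if m:
        return float(m.group(1))
    m = _BARE_RANGE.match(text)
    if m:
        return (float(m.group(1)) + float(m.group(2))) / 2.0
    return float(text)  # raises ValueError on junk


def ogt_group(temperature: float) -> str:
    """Life-style label from optimal growth temperature (hyperthermophile
    >= 80 degC, thermophile 50-80 degC, mesophile <= 50 degC)."""
    if temperature >= 80:
        return HYPERTHERMOPHILE
    if temperature > 50:
        return THERMOPHILE
    return MESOPHILE


def read_trait_table(path) -> pd.DataFrame:
    """Read a TSV of (species, temperature[, group]) rows.

    Temperatures may be ranges (see :func:`parse_temperature`).  Returns a
    DataFrame with columns ``species``, ``temperature`` and ``group`` (NaN
    where absent from the file).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "species" not in cols or "temperature" not in cols:
        raise ValueError(f"{path}: trait table needs 'species' and 'temperature' columns")
    temps = []
    for i, raw in enumerate(df[cols["temperature"]]):
        try:
            temps.append(parse_temperature(raw))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: non-numeric temperature at data row {i + 1}: {raw!r}") from exc
    out = pd.DataFrame(
        {
            "species": df[cols["species"]].astype(str),
            "temperature": temps,
            "group": df[cols["group"]] if "group" in cols else pd.NA,
        }
    )
    if out["species"].duplicated().any():
        dup = out.loc[out["species"].duplicated(), "species"].iloc[0]
        raise ValueError(f"{path}: duplicate species {dup!r}")
    if not out["temperature"].map(lambda t: t == t and abs(t) != float("inf")).all():
        raise ValueError(f"{path}: non-finite temperature")
    return out


def assign_ogt_groups(traits: pd.DataFrame) -> pd.DataFrame:
    """Fill the ``group`` column from OGT thresholds where it is unset."""
    out = traits.copy()
    missing = out["group"].isna()
    out.loc[missing, "group"] = out.loc[missing, "temperature"].map(ogt_group)
    return out


# -- similarity (hit) tables ------------------------------------------------


def reduce_best_hsp(hits: pd.DataFrame) -> pd.DataFrame:
    """Keep one row per (query, subject): highest bit score, then lowest
    e-value, then first occurrence.  Idempotent."""
    if hits.empty:
        return hits.copy()
    df = hits.reset_index(drop=True)
    df = df.sort_values(
        ["query", "subject", "bitscore", "evalue"],
        ascending=[True, True, False, True],
        kind="stable",
    )
    df = df.drop_duplicates(["query", "subject"], keep="first")
    return df.sort_index().reset_index(drop=True)


def read_hit_table(path) -> pd.DataFrame:
    """Read a tabular similarity file (12+ column outfmt-6 dialect or the
    6-column reduced dialect) and reduce to the best HSP per pair.

    Returns a DataFrame with :data:`HIT_COLUMNS`.
    """
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=HIT_COLUMNS)
    if raw.shape[1] >= 12:
        picked = raw.iloc[:, [0, 1, 2, 3, 10, 11]]
    elif raw.shape[1] == 6:
        picked = raw
    else:
        raise ValueError(f"{path}: expected 6 or >=12 tab-separated columns, got {raw.shape[1]}")
    picked = picked.set_axis(HIT_COLUMNS, axis=1).copy()
    for col in ("pident", "length", "evalue", "bitscore"):
        try:
            picked[col] = pd.to_numeric(picked[col])
        except (ValueError, TypeError):
            bad = pd.to_numeric(picked[col], errors="coerce").isna()
            line = int(picked.index[bad][0]) + 1
            raise ValueError(f"{path}: malformed {col} at line {line}") from None
    if (picked["evalue"] < 0).any():
        raise ValueError(f"{path}: negative e-value")
    return reduce_best_hsp(picked)


def write_hit_table(hits: pd.DataFrame, path) -> None:
    hits[HIT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_hit_table_text(text: str) -> pd.DataFrame:
    """Convenience wrapper used by tests and generators: parse from a string."""
    return read_hit_table(io.StringIO(text))
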