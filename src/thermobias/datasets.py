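"""Small bundled reference tables.

``vertebrate_panel()`` returns the published species-level table for the
11-vertebrate panel: typical body/operating temperature, concatenated
co-ortholog ERK, and AT-rich/GC-rich codon usage percentages, with the
endotherm/ectotherm grouping.  Temperature ranges are reduced to their
leading representative value.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .seqio import parse_temperature


def vertebrate_panel() -> pd.DataFrame:
    """Species-level vertebrate panel (11 species).

    Columns: species, class, group (endotherm/ectotherm), temperature
    (degC, single representative value), erk (pp), pct_at_rich, pct_gc_rich.
    """
    path = resources.files("thermobias.data") / "vertebrate_panel.tsv"
    with path.open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["temperature"] = df["temperature"].map(parse_temperature)
    return df
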