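"""Bundled reference data.

``load_sros_te_families`` returns the published per-family survey of the 19
fully characterised *Salpingoeca rosetta* TE families (12 LTR
retrotransposon families in three groups, 7 DNA transposon families):
codon-usage statistics (Nc, Fop, GC3s, non-coding GC), copy numbers and
mapped RNA-Seq read counts.  For DNA transposon families whose 5' and 3'
terminal-repeat counts disagree, ``copy_number`` holds a single point value
inside the published range.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

LTR_GROUPS = ("chromovirus", "gypsy_nonchromo", "copia")


def load_sros_te_families() -> pd.DataFrame:
    """Per-family statistics table, one row per family."""
    ref = resources.files("tescope.data").joinpath("sros_te_families.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
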