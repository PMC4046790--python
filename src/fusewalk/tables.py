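"""Loaders for the packaged fusion tables.

Two fixtures ship with the package: the validated single-cohort fusion
table (13 junctions across 8 samples, with junction/wild-type read support,
cytoband, strands and 1-based breakpoint coordinates) and the recurrent-
partner fusion list spanning both cohorts (one row per fusion occurrence,
TCGA aliquot barcodes preserved).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

DISCOVERY_TCGA_ALIASES = {
    "SN214": "TCGA-74-6583",
    "SN154": "TCGA-74-6573",
    "SN187": "TCGA-74-6578",
}


def _read_packaged(name: str) -> pd.DataFrame:
    ref = resources.files("fusewalk.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def load_table1() -> pd.DataFrame:
    """Validated fusion set of the discovery cohort (one row per fusion)."""
    df = _read_packaged("table1_discovery_fusions.tsv")
    df["wt5"] = pd.to_numeric(df["wt5"], errors="coerce")
    df["wt3"] = pd.to_numeric(df["wt3"], errors="coerce")
    return df


def load_table2() -> pd.DataFrame:
    """Recurrent-partner fusion occurrences across both cohorts."""
    return _read_packaged("table2_recurrent_fusions.tsv")
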