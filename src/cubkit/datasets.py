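"""Bundled reference datasets.

Ships the published pooled ORF12 RSCU profiles of the four porcine
circovirus species circulating in China (PCV-1..PCV-4) together with
the *Sus scrofa* host reference usage, as a small plain-text table.
These fixed profiles let the classification machinery (preferred /
over- / under-represented codons, host-shared preferences) be exercised
and regression-tested without any sequence download.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .codon_stats import RSCUProfile
from .sequence_io import ReferenceUsageTable

PCV_SPECIES = ("PCV1", "PCV2", "PCV3", "PCV4")
HOST_COLUMN = "Sus_scrofa"


def _table() -> pd.DataFrame:
    with resources.files("cubkit.data").joinpath("pcv_rscu.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def pcv_rscu_table() -> pd.DataFrame:
    """The raw bundled table: aa, codon (RNA) and one RSCU column per dataset."""
    return _table()


def pcv_rscu_profiles() -> dict[str, RSCUProfile]:
    """RSCU profiles for PCV-1..4 and the host, keyed by column name."""
    df = _table().set_index("codon")
    return {
        col: RSCUProfile.from_values(df[col].to_dict())
        for col in (*PCV_SPECIES, HOST_COLUMN)
    }


def sus_scrofa_reference() -> ReferenceUsageTable:
    """Host usage as a reference table with relative-adaptiveness weights."""
    df = _table().set_index("codon")
    return ReferenceUsageTable.from_values(df[HOST_COLUMN].to_dict(), units="rscu")
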