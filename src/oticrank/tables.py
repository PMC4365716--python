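"""Packaged worked-example tables.

Two small published summary tables ship with the package as TSV fixtures:
the top 30 probes ranked by otic-vesicle fold change (with hair-cell /
supporting-cell folds, ranks, consensus labels, scores and ranks for the
same probes) and the top 30 probes by consensus rank. They serve as desk
checks for the consensus arithmetic — scores recomputed from printed
per-category ranks, labels recomputed from printed fold-change triples —
without any expression data download.

Genes represented by more than one probe appear multiple times; rows carry a
synthetic ``probe_id`` (gene plus row tag) because the published tables list
gene symbols only. One non-significant direction flag printed inconsistently
("No") is normalized to "NS".
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

TARGET_CATEGORIES = ["OV", "HC", "SC"]


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("oticrank.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col="probe_id")


def top30_by_ov_rank() -> pd.DataFrame:
    """Top 30 probes by OV fold change vs the maximum-expressing reference."""
    return _load("top30_by_ov_rank.tsv")


def top30_by_consensus_rank() -> pd.DataFrame:
    """Top 30 probes by otic consensus rank."""
    return _load("top30_by_consensus_rank.tsv")


def fold_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Per-category fold-change triples with category-named columns."""
    out = df[["ov_fold", "hc_fold", "sc_fold"]].copy()
    out.columns = TARGET_CATEGORIES
    return out


def rank_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Per-category printed ranks with category-named columns."""
    out = df[["ov_rank", "hc_rank", "sc_rank"]].copy()
    out.columns = TARGET_CATEGORIES
    return out
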