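"""Reading expression matrices and sample sheets; writing the ranked table.

Two input dialects are supported:

``plain_tsv``
    probe id, gene symbol, then one intensity column per sample.
``genomestudio``
    GenomeStudio-style sample probe profile: per-sample blocks may carry an
    extra detection p-value column (``Detection Pval`` suffix); detection
    columns are parsed and discarded, since the analysis never uses them.

The ranked output table mirrors the study's supplemental-spreadsheet layout:
one row per probe, per-group means/SDs, per-category fold changes, q-values
and ranks, the reference-vs-reference contrast, consensus labels, score and
rank, sorted by consensus rank.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .matrix import ExpressionMatrix, SampleSheet, LINEAR, LOG2

_DETECTION_TOKENS = ("detection pval", "detection_pval", "detection-pval", "detection p-value")

#: significant digits used for every float in the ranked table; fixed so
#: regression fixtures are byte-stable
TABLE_SIG_DIGITS = 8


def _fail_non_numeric(df: pd.DataFrame, raw: pd.DataFrame) -> None:
    bad = df.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric intensity at probe {df.index[r]!r}, column {df.columns[c]!r}: "
            f"{raw.iat[r, c]!r}"
        )


def read_expression_matrix(
    path, dialect: str = "plain_tsv", scale: str = LINEAR
) -> ExpressionMatrix:
    """Read a tab-delimited probe × sample intensity matrix.

    Column order is preserved. Duplicate probe ids, non-numeric intensity
    cells and empty matrices are hard errors.
    """
    if dialect not in ("plain_tsv", "genomestudio"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3:
        raise ValueError("expression matrix needs probe, symbol and ≥1 intensity column")
    probe_col, symbol_col = df.columns[0], df.columns[1]
    dup = df[probe_col][df[probe_col].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate probe id: {dup.iloc[0]!r}")
    df = df.set_index(probe_col)
    symbols = df[symbol_col]
    intensity_cols = [c for c in df.columns if c != symbol_col]
    if dialect == "genomestudio":
        intensity_cols = [
            c for c in intensity_cols
            if not any(tok in c.lower() for tok in _DETECTION_TOKENS)
        ]
    if not intensity_cols:
        raise ValueError("no intensity columns found")
    raw = df[intensity_cols]
    values = raw.apply(pd.to_numeric, errors="coerce")
    _fail_non_numeric(values, raw)
    if values.isna().to_numpy().any():
        r, c = np.argwhere(values.isna().to_numpy())[0]
        raise ValueError(
            f"missing intensity at probe {values.index[r]!r}, column {values.columns[c]!r}"
        )
    values = values.astype(float)
    values.index.name = None
    return ExpressionMatrix(values=values, gene_symbols=symbols.rename(None), scale=scale)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Companion writer for :func:`read_expression_matrix` (plain_tsv dialect)."""
    out = matrix.values.copy()
    out.insert(0, "Symbol", matrix.gene_symbols)
    out.index.name = "Probe_ID"
    out.to_csv(path, sep="\t", float_format=f"%.{TABLE_SIG_DIGITS}g")


def read_sample_sheet(path, matrix: ExpressionMatrix | None = None) -> SampleSheet:
    """Read a YAML sample sheet.

    Expected keys: ``samples`` (sample id → group), ``roles`` (group →
    ``target``/``reference``) and optional ``target_order``. If ``matrix`` is
    given, every matrix sample must be present in the sheet.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "samples" not in cfg or "roles" not in cfg:
        raise ValueError("sample sheet must define 'samples' and 'roles'")
    sheet = SampleSheet(
        sample_to_group={str(k): str(v) for k, v in cfg["samples"].items()},
        group_roles={str(k): str(v) for k, v in cfg["roles"].items()},
        target_order=[str(g) for g in cfg.get("target_order", [])],
    )
    if matrix is not None:
        sheet.validate_against(matrix)
    return sheet


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "samples": dict(sheet.sample_to_group),
                "roles": dict(sheet.group_roles),
                "target_order": list(sheet.target_order),
            },
            fh,
            sort_keys=False,
        )


def _fmt(x) -> str:
    if isinstance(x, (float, np.floating)):
        return f"{x:.{TABLE_SIG_DIGITS}g}"
    return str(x)


def write_ranked_table(table: pd.DataFrame, path) -> None:
    """Write the assembled ranked results table as TSV.

    ``table`` is the output of :func:`oticrank.pipeline.run_pipeline`'s
    ``ranked_table``; rows are ordered by consensus rank, floats rendered
    with a fixed significant-digit policy so output is byte-stable.
    """
    if "consensus_rank" not in table.columns:
        raise ValueError("ranked table must carry a consensus_rank column")
    out = table.sort_values("consensus_rank", kind="stable")
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, out.columns)) + "\n")
        for row in out.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def read_ranked_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
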