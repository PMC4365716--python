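"""Core in-memory containers for the expression analysis.

An :class:`ExpressionMatrix` is a probes × samples intensity table carried on
a pandas DataFrame, with a scale flag distinguishing raw linear intensities
from log2-transformed values, plus one gene-symbol annotation per probe.
A :class:`SampleSheet` maps samples to groups and groups to roles (target
lineage category vs non-target reference tissue).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LINEAR = "linear"
LOG2 = "log2"

TARGET = "target"
REFERENCE = "reference"


@dataclass
class ExpressionMatrix:
    """Probes × samples intensities with probe annotation.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per sample.
    gene_symbols
        Series aligned to ``values.index``; missing annotation falls back to
        the probe id itself.
    scale
        ``"linear"`` (raw intensities) or ``"log2"``.
    """

    values: pd.DataFrame
    gene_symbols: pd.Series = None
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise ValueError("empty expression matrix")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate probe id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if self.scale not in (LINEAR, LOG2):
            raise ValueError(f"unknown scale {self.scale!r}")
        if not np.issubdtype(self.values.to_numpy().dtype, np.number):
            raise ValueError("expression values must be numeric")
        if self.gene_symbols is None:
            self.gene_symbols = pd.Series(
                self.values.index, index=self.values.index, dtype=object
            )
        else:
            self.gene_symbols = self.gene_symbols.reindex(self.values.index)
            missing = self.gene_symbols.isna()
            if missing.any():
                self.gene_symbols = self.gene_symbols.astype(object)
                self.gene_symbols[missing] = self.values.index[missing]

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values,
            gene_symbols=self.gene_symbols.copy(),
            scale=self.scale if scale is None else scale,
        )


@dataclass
class SampleSheet:
    """Sample → group and group → role assignments.

    ``target_order`` fixes the order of the target lineage categories
    (e.g. OV, HC, SC) used for consensus scoring and output columns.
    """

    sample_to_group: dict[str, str]
    group_roles: dict[str, str]
    target_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for group, role in self.group_roles.items():
            if role not in (TARGET, REFERENCE):
                raise ValueError(f"unknown role {role!r} for group {group!r}")
        for sample, group in self.sample_to_group.items():
            if group not in self.group_roles:
                raise ValueError(f"sample {sample!r} assigned to unknown group {group!r}")
        targets = [g for g, r in self.group_roles.items() if r == TARGET]
        refs = [g for g, r in self.group_roles.items() if r == REFERENCE]
        if not targets:
            raise ValueError("sample sheet defines no target group")
        if not refs:
            raise ValueError("sample sheet defines no reference group")
        if not self.target_order:
            self.target_order = targets
        else:
            unknown = set(self.target_order) - set(targets)
            if unknown:
                raise ValueError(f"target_order names non-target groups: {sorted(unknown)}")
            missing = set(targets) - set(self.target_order)
            if missing:
                raise ValueError(f"target_order misses target groups: {sorted(missing)}")

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.sample_to_group.values():
            if g not in seen:
                seen.append(g)
        return seen

    @property
    def reference_groups(self) -> list[str]:
        return [g for g in self.groups if self.group_roles[g] == REFERENCE]

    @property
    def target_groups(self) -> list[str]:
        return list(self.target_order)

    def samples_of(self, group: str) -> list[str]:
        return [s for s, g in self.sample_to_group.items() if g == group]

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Every matrix sample must be assigned to exactly one group."""
        missing = [s for s in matrix.sample_ids if s not in self.sample_to_group]
        if missing:
            raise ValueError(f"samples missing from sample sheet: {missing}")
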