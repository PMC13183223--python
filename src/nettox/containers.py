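"""Core data containers and their on-disk text formats.

Expression data are log2 intensities (microarray-style) held as a genes x
samples DataFrame with a per-sample case/control label. Target lists are
gene-symbol tables with optional provenance attributes. Abundance tables are
compositional (rows on the simplex), e.g. immune cell-type fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"

TARGET_COLUMNS = ["symbol", "source", "interaction_type", "fit_score", "species"]


@dataclass
class ExpressionMatrix:
    """Two-group log2 expression matrix.

    Parameters
    ----------
    values
        genes x samples DataFrame of log2 intensities; unique gene index.
    groups
        Series mapping every sample ID to ``"case"`` or ``"control"``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene symbols in expression matrix")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"unlabeled samples: {missing[:5]}")
        self.groups = self.groups.loc[self.values.columns]
        bad = set(self.groups.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"group labels must be case/control, got {bad}")
        for g in (CASE, CONTROL):
            if (self.groups == g).sum() < 2:
                raise ValueError(f"fewer than 2 samples in group {g!r}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def group_samples(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    @property
    def case_values(self) -> pd.DataFrame:
        return self.values[self.group_samples(CASE)]

    @property
    def control_values(self) -> pd.DataFrame:
        return self.values[self.group_samples(CONTROL)]

    def write_tsv(self, expr_path, labels_path) -> None:
        out = self.values.copy()
        out.insert(0, "symbol", out.index)
        out.to_csv(expr_path, sep="\t", index=False)
        lab = pd.DataFrame({"sample": self.groups.index, "group": self.groups.values})
        lab.to_csv(labels_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, expr_path, labels_path) -> "ExpressionMatrix":
        df = pd.read_csv(expr_path, sep="\t")
        df = df.set_index(df.columns[0])
        df.index.name = "symbol"
        lab = pd.read_csv(labels_path, sep="\t")
        groups = pd.Series(lab["group"].values, index=lab["sample"].astype(str))
        return cls(df, groups)


def read_series_matrix(path) -> pd.DataFrame:
    """Read the expression block of a GEO series-matrix text file.

    The header block is skipped; only the rows between
    ``!series_matrix_table_begin`` and ``!series_matrix_table_end`` are
    parsed. Returns a probes/genes x samples DataFrame; group labels must be
    supplied separately.
    """
    lines = []
    inside = False
    with open(path) as fh:
        for line in fh:
            tag = line.strip().lower()
            if tag.startswith("!series_matrix_table_begin"):
                inside = True
                continue
            if tag.startswith("!series_matrix_table_end"):
                break
            if inside:
                lines.append(line)
    if not lines:
        raise ValueError(f"no series-matrix table found in {path}")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines)), sep="\t")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str).str.strip('"')
    df.columns = [c.strip('"') for c in df.columns]
    return df


def collapse_by_symbol(values: pd.DataFrame, how: str = "mean") -> pd.DataFrame:
    """Collapse multiple probes mapping to one symbol (default: mean)."""
    if how not in {"mean", "max"}:
        raise ValueError("how must be 'mean' or 'max'")
    grouped = values.groupby(level=0, sort=False)
    return grouped.mean() if how == "mean" else grouped.max()


@dataclass
class TargetSet:
    """Named collection of target entries with unique standardized symbols."""

    name: str
    entries: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=TARGET_COLUMNS))
    n_dropped: int = 0

    def __post_init__(self) -> None:
        df = self.entries.copy()
        for col in TARGET_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[TARGET_COLUMNS]
        if df["symbol"].duplicated().any():
            raise ValueError(f"duplicate symbols in TargetSet {self.name!r}")
        self.entries = df.reset_index(drop=True)

    @property
    def symbols(self) -> set[str]:
        return set(self.entries["symbol"])

    def __len__(self) -> int:
        return len(self.entries)

    def write_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, name: str | None = None) -> "TargetSet":
        df = pd.read_csv(path)
        return cls(name or str(path), df)


@dataclass
class AbundanceTable:
    """Compositional abundance table: samples x components, rows sum to 1."""

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate component names")
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-8):
            warnings.warn("abundance rows do not sum to 1; renormalizing")
            self.values = self.values.div(sums, axis=0)
        self.groups = self.groups.loc[self.values.index]

    def write_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "group", self.groups.values)
        out.insert(0, "sample", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "AbundanceTable":
        df = pd.read_csv(path, sep="\t")
        df = df.set_index("sample")
        groups = df.pop("group")
        return cls(df, groups)
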