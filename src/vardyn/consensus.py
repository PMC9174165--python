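"""Consensus aggregation of per-tool deleteriousness calls.

Many in-silico missense predictors (SIFT, PolyPhen, CADD, ...) disagree on
individual variants; aggregating their binary calls into per-SNP vote counts
and keeping variants called deleterious by a large majority is a standard
prioritisation strategy.  This module provides the vote count, the
high-risk threshold filter (default: at least 15 of 17 tools) and the
pairwise tool-agreement matrix (phi coefficient on binary call vectors,
optionally Pearson on raw scores when available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = [
    "CallTable",
    "AgreementMatrix",
    "vote_counts",
    "missing_counts",
    "filter_high_risk",
    "agreement_matrix",
    "DEFAULT_THRESHOLD",
]

#: Variants called deleterious by at least this many tools are high-risk.
DEFAULT_THRESHOLD = 15


@dataclass
class CallTable:
    """S x K binary deleteriousness calls (1 deleterious, 0 benign, NaN missing)."""

    snp_ids: list[str]
    tool_names: list[str]
    calls: np.ndarray
    scores: np.ndarray | None = None  # optional raw per-tool scores

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, float)
        s, k = len(self.snp_ids), len(self.tool_names)
        if len(set(self.snp_ids)) != s:
            raise ValueError("duplicate snp_ids")
        if len(set(self.tool_names)) != k:
            raise ValueError("duplicate tool_names")
        if self.calls.shape != (s, k):
            raise ValueError(f"calls must be {s} x {k}, got {self.calls.shape}")
        valid = np.isnan(self.calls) | (self.calls == 0) | (self.calls == 1)
        if not valid.all():
            raise ValueError("calls entries must be 0, 1 or missing (NaN)")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_tools(self) -> int:
        return len(self.tool_names)

    @classmethod
    def from_csv(cls, path) -> "CallTable":
        """Read a call table: first column snp_id, one column per tool,
        values 0/1/NA."""
        df = pd.read_csv(path, dtype={0: str})
        if df.shape[1] < 2:
            raise FormatError("call table needs an id column plus >= 1 tool")
        snp_col = df.columns[0]
        tools = list(df.columns[1:])
        calls = df[tools].apply(pd.to_numeric, errors="coerce").to_numpy(float)
        return cls(list(df[snp_col]), tools, calls)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.calls, columns=self.tool_names)
        df.insert(0, "snp_id", self.snp_ids)
        df.to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.snp_ids, columns=self.tool_names)


@dataclass
class AgreementMatrix:
    """Symmetric K x K inter-tool agreement (phi or Pearson), unit diagonal.

    Cells that cannot be estimated (constant call vector, fewer than two
    jointly scored SNPs) are NaN — undefined, not zero.
    """

    tool_names: list[str]
    r: np.ndarray
    kind: str = field(default="phi")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.tool_names, columns=self.tool_names)


def vote_counts(table: CallTable) -> pd.Series:
    """Number of tools calling each SNP deleterious (missing calls excluded)."""
    if table.n_snps == 0 or table.n_tools == 0:
        raise ValueError("empty call table")
    counts = np.nansum(table.calls, axis=1).astype(int)
    return pd.Series(counts, index=table.snp_ids, name="votes")


def missing_counts(table: CallTable) -> pd.Series:
    """Number of tools with no call for each SNP, reported separately."""
    return pd.Series(
        np.isnan(table.calls).sum(axis=1).astype(int),
        index=table.snp_ids, name="missing",
    )


def filter_high_risk(table: CallTable, threshold: int = DEFAULT_THRESHOLD) -> list[str]:
    """SNP ids with at least ``threshold`` deleterious votes.

    Ordered by descending vote count, ties broken lexicographically by id.
    """
    if not 0 < threshold <= table.n_tools:
        raise ValueError(
            f"threshold must be in 1..{table.n_tools}, got {threshold}"
        )
    votes = vote_counts(table)
    hits = votes[votes >= threshold]
    order = sorted(hits.index, key=lambda s: (-hits[s], s))
    return order


def _phi(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two binary vectors (the phi coefficient)."""
    both = ~np.isnan(x) & ~np.isnan(y)
    if both.sum() < 2:
        return np.nan
    xs, ys = x[both], y[both]
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return np.nan  # constant column: undefined, never 0
    return float(((xs - xs.mean()) * (ys - ys.mean())).mean() / (sx * sy))


def agreement_matrix(table: CallTable, use_scores: bool = False) -> AgreementMatrix:
    """Pairwise inter-tool agreement over SNPs both tools scored.

    Binary calls give the phi coefficient; ``use_scores=True`` computes
    plain Pearson on raw scores instead (when available).
    """
    if table.n_tools < 2 or table.n_snps < 2:
        raise ValueError("agreement needs >= 2 tools and >= 2 SNPs")
    data = table.scores if use_scores else table.calls
    if use_scores and table.scores is None:
        raise ValueError("no raw scores available")
    k = table.n_tools
    r = np.full((k, k), np.nan)
    np.fill_diagonal(r, 1.0)
    for i in range(k):
        for j in range(i + 1, k):
            r[i, j] = r[j, i] = _phi(data[:, i], data[:, j])
    return AgreementMatrix(list(table.tool_names), r,
                           kind="pearson" if use_scores else "phi")
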