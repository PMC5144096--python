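"""Diploid-baseline Z-scores and CNL/down-regulation concordance.

For each gene, expression mean and sample standard deviation (n-1
denominator) are computed over the samples that are copy-neutral (diploid)
at that gene; every sample's expression is then standardised against this
baseline.  A sample is *concordant* for a gene when it carries a
copy-number loss there AND its Z-score is strictly below the threshold
(default -2, the COSMIC under-expression criterion).  Genes are ranked by
their concordant-sample count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import LOSS

__all__ = [
    "ConcordanceRecord",
    "read_expression",
    "diploid_baseline",
    "z_score",
    "z_score_matrix",
    "concordant_genes",
    "top_genes",
]


@dataclass(frozen=True)
class ConcordanceRecord:
    """Per-gene set of samples with both CNL and Z below the threshold."""

    symbol: str
    concordant_samples: frozenset[str]
    z_threshold: float = -2.0
    n_concordant: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_concordant", len(self.concordant_samples))


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column = gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicated gene symbols")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicated sample ids")
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative expression values")
    return df


def diploid_baseline(expr: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean/SD over diploid samples.

    Returns columns symbol, mean, sd, n_diploid, usable.  A baseline is
    unusable when fewer than two diploid samples exist or the SD is zero;
    unusable genes are reported, never silently dropped.  Samples present
    in the expression matrix but absent from the call table are treated as
    diploid (no aberrant segment was exported for them).
    """
    diploid_map: dict[str, set[str]] = {}
    d = calls[calls["diploid"]]
    for sym, grp in d.groupby("symbol"):
        diploid_map[sym] = set(grp["sample_id"])
    called_genes = set(calls["symbol"].unique())
    called_samples = set(calls["sample_id"].unique())

    rows = []
    for sym in expr.index:
        base_samples = diploid_map.get(sym, set())
        if sym not in called_genes:
            # gene never seen in the CNV table: every sample is diploid
            base_samples = set(expr.columns)
        else:
            # expression samples absent from the call table count as diploid
            base_samples = base_samples | (set(expr.columns) - called_samples)
        cols = [c for c in expr.columns if c in base_samples]
        vals = expr.loc[sym, cols].to_numpy(dtype=float)
        n = len(vals)
        mean = float(np.mean(vals)) if n else float("nan")
        sd = float(np.std(vals, ddof=1)) if n >= 2 else float("nan")
        usable = n >= 2 and sd > 0
        rows.append((sym, mean, sd, n, usable))
    return pd.DataFrame(rows, columns=["symbol", "mean", "sd", "n_diploid", "usable"])


def z_score(x: float, mean: float, sd: float) -> float:
    """Standard score (x - mean) / sd; NaN (never silent 0) when sd is unusable."""
    if not np.isfinite(sd) or sd <= 0:
        return float("nan")
    return (x - mean) / sd


def z_score_matrix(expr: pd.DataFrame, baselines: pd.DataFrame) -> pd.DataFrame:
    """Z-scores for every (gene, sample); NaN rows for unusable baselines."""
    b = baselines.set_index("symbol")
    mean = b["mean"].reindex(expr.index).to_numpy(dtype=float)
    sd = b["sd"].reindex(expr.index).to_numpy(dtype=float)
    usable = b["usable"].reindex(expr.index).fillna(False).to_numpy(dtype=bool)
    sd_safe = np.where(usable & (sd > 0), sd, np.nan)
    z = (expr.to_numpy(dtype=float) - mean[:, None]) / sd_safe[:, None]
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)


def concordant_genes(
    calls: pd.DataFrame,
    expr: pd.DataFrame,
    z_threshold: float = -2.0,
    symbols: Sequence[str] | None = None,
) -> list[ConcordanceRecord]:
    """Genes with >= 1 sample showing both CNL and Z strictly below threshold.

    ``symbols`` restricts the genes tested (e.g. to the frequent-loss set);
    default is every gene present in both the call table and the matrix.
    Result is sorted by descending concordant-sample count, ties broken by
    symbol.  The threshold comparison is strict: Z exactly at the threshold
    is not under-expressed.
    """
    baselines = diploid_baseline(expr, calls)
    z = z_score_matrix(expr, baselines)
    loss = calls[calls["status"] == LOSS]
    loss_map: dict[str, set[str]] = {
        sym: set(grp["sample_id"]) for sym, grp in loss.groupby("symbol")
    }
    if symbols is None:
        universe = [s for s in z.index if s in set(calls["symbol"])]
    else:
        universe = [s for s in symbols if s in z.index]
    records = []
    for sym in universe:
        loss_samples = loss_map.get(sym, set())
        if not loss_samples:
            continue
        zrow = z.loc[sym]
        down = {c for c in expr.columns if zrow[c] < z_threshold}
        conc = frozenset(loss_samples & down)
        if conc:
            records.append(ConcordanceRecord(sym, conc, z_threshold))
    records.sort(key=lambda r: (-r.n_concordant, r.symbol))
    return records


def top_genes(records: Sequence[ConcordanceRecord], min_samples: int = 50) -> list[str]:
    """Genes whose concordant-sample count strictly exceeds ``min_samples``."""
    return [r.symbol for r in records if r.n_concordant > min_samples]


def records_frame(records: Sequence[ConcordanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.symbol, r.n_concordant, ",".join(sorted(r.concordant_samples)))
            for r in records
        ],
        columns=["symbol", "n_concordant", "concordant_samples"],
    )
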