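"""Ploidy-aware somatic copy-number loss/gain classification.

Implements the COSMIC-style per-segment criteria used for TCGA pan-cancer
copy-number calls.  The thresholds switch at an average genome ploidy of
2.7 (near-diploid versus polyploid tumors):

* loss (CNL):  ploidy <= 2.7 and total_cn == 0,
               or ploidy > 2.7 and total_cn < ploidy - 2.7
* gain (CNG):  ploidy <= 2.7 and total_cn >= 5,
               or ploidy > 2.7 and total_cn >= 9

Per-segment calls are aggregated to per (gene, sample) status, and genes
are then screened with the frequent-loss filter: a gene is retained when
its loss-sample count is at least ``ratio`` (default 2) times its
gain-sample count, with at least one loss observed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CnvThresholds",
    "GeneSampleCall",
    "classify_segment",
    "gene_sample_status",
    "build_call_table",
    "summarize",
    "write_calls",
    "read_calls",
]

LOSS, GAIN, NEUTRAL, AMBIGUOUS = "loss", "gain", "neutral", "ambiguous"


@dataclass(frozen=True)
class CnvThresholds:
    """Copy-number calling thresholds (COSMIC TCGA defaults)."""

    ploidy_cut: float = 2.7      # switches diploid- vs polyploid-regime rules
    loss_cn: float = 0.0         # CNL requires total_cn == loss_cn when ploidy <= cut
    gain_cn_diploid: float = 5.0
    gain_cn_polyploid: float = 9.0


DEFAULT_THRESHOLDS = CnvThresholds()


@dataclass(frozen=True)
class GeneSampleCall:
    """CNV status of one gene in one sample.

    ``diploid`` marks the sample as copy-neutral at this gene and therefore
    usable in the diploid expression baseline.
    """

    symbol: str
    sample_id: str
    status: str
    diploid: bool

    def __post_init__(self) -> None:
        if self.status not in (LOSS, GAIN, NEUTRAL, AMBIGUOUS):
            raise ValueError(f"invalid status {self.status!r}")
        if self.diploid and self.status != NEUTRAL:
            raise ValueError("diploid call must have neutral status")


def classify_segment(
    total_cn: float,
    avg_ploidy: float,
    thresholds: CnvThresholds = DEFAULT_THRESHOLDS,
) -> str:
    """Classify one segment as ``loss``, ``gain`` or ``neutral``.

    Raises ``ValueError`` on negative or non-finite inputs.  The loss and
    gain conditions are mutually exclusive for all valid inputs provided
    ``gain_cn_diploid > loss_cn`` and ``gain_cn_polyploid`` exceeds any
    attainable ``avg_ploidy - ploidy_cut`` margin, which holds for the
    defaults on real tumor ploidies.
    """
    if not (math.isfinite(total_cn) and math.isfinite(avg_ploidy)):
        raise ValueError("total_cn and avg_ploidy must be finite")
    if total_cn < 0:
        raise ValueError(f"total_cn must be >= 0, got {total_cn}")
    if avg_ploidy <= 0:
        raise ValueError(f"avg_ploidy must be > 0, got {avg_ploidy}")
    t = thresholds
    if avg_ploidy <= t.ploidy_cut:
        is_loss = total_cn == t.loss_cn
        is_gain = total_cn >= t.gain_cn_diploid
    else:
        is_loss = total_cn < avg_ploidy - t.ploidy_cut
        is_gain = total_cn >= t.gain_cn_polyploid
    if is_loss and is_gain:  # impossible with sane thresholds; assert the contract
        raise AssertionError(
            f"loss and gain criteria overlap at cn={total_cn}, ploidy={avg_ploidy}"
        )
    if is_loss:
        return LOSS
    if is_gain:
        return GAIN
    return NEUTRAL


def gene_sample_status(
    statuses: Sequence[str], total_cns: Sequence[float]
) -> tuple[str, bool]:
    """Aggregate per-segment statuses for one (gene, sample) pair.

    No overlapping segment at all means the exported profile is copy-neutral
    there, so the pair is neutral and diploid.  A mix of loss and gain
    segments is ``ambiguous`` and excluded from loss/gain counts.  Pairs
    covered only by neutral segments are diploid only when every overlapping
    segment has total copy number exactly 2.
    """
    if len(statuses) != len(total_cns):
        raise ValueError("statuses and total_cns must have equal length")
    if not statuses:
        return NEUTRAL, True
    has_loss = LOSS in statuses
    has_gain = GAIN in statuses
    if has_loss and has_gain:
        return AMBIGUOUS, False
    if has_loss:
        return LOSS, False
    if has_gain:
        return GAIN, False
    return NEUTRAL, all(cn == 2 for cn in total_cns)


def build_call_table(
    overlaps: pd.DataFrame,
    symbols: Iterable[str],
    sample_ids: Iterable[str],
    thresholds: CnvThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per (gene, sample) CNV call table over the full analysis universe.

    ``overlaps`` is the gene-segment overlap table from
    :mod:`cnvconcord.genomic`; pairs absent from it are copy-neutral and
    diploid by construction (aberrant-segments-only export convention).
    Returns a DataFrame with columns symbol, sample_id, status, diploid —
    one row per (symbol, sample) in the cross product.
    """
    symbols = sorted(set(symbols))
    sample_ids = sorted(set(sample_ids))
    seg_status = overlaps.apply(
        lambda r: classify_segment(r["total_cn"], r["avg_ploidy"], thresholds), axis=1
    ) if len(overlaps) else pd.Series([], dtype=str)

    grouped: dict[tuple[str, str], tuple[list[str], list[float]]] = {}
    for (sym, sid), st, cn in zip(
        zip(overlaps["symbol"], overlaps["sample_id"]),
        seg_status,
        overlaps["total_cn"],
    ):
        grouped.setdefault((sym, sid), ([], []))
        grouped[(sym, sid)][0].append(st)
        grouped[(sym, sid)][1].append(cn)

    rows = []
    for sym in symbols:
        for sid in sample_ids:
            sts, cns = grouped.get((sym, sid), ([], []))
            status, diploid = gene_sample_status(sts, cns)
            rows.append((sym, sid, status, diploid))
    return pd.DataFrame(rows, columns=["symbol", "sample_id", "status", "diploid"])


def summarize(calls: pd.DataFrame, ratio: float = 2.0) -> pd.DataFrame:
    """Per-gene loss/gain counts and the frequent-loss flag.

    ``frequent_loss`` is true iff ``n_loss >= ratio * n_gain`` and
    ``n_loss >= 1`` (the extra floor keeps genes with no loss at all from
    passing vacuously when ``n_gain == 0``).  Raises on duplicated
    (gene, sample) rows.
    """
    if calls.duplicated(subset=["symbol", "sample_id"]).any():
        dup = calls[calls.duplicated(subset=["symbol", "sample_id"])].iloc[0]
        raise ValueError(
            f"duplicate call for gene {dup['symbol']!r} sample {dup['sample_id']!r}"
        )
    n_loss = calls[calls["status"] == LOSS].groupby("symbol").size()
    n_gain = calls[calls["status"] == GAIN].groupby("symbol").size()
    symbols = sorted(calls["symbol"].unique())
    out = pd.DataFrame({"symbol": symbols})
    out["n_loss"] = out["symbol"].map(n_loss).fillna(0).astype(int)
    out["n_gain"] = out["symbol"].map(n_gain).fillna(0).astype(int)
    out["frequent_loss"] = (out["n_loss"] >= ratio * out["n_gain"]) & (
        out["n_loss"] >= 1
    )
    return out


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str, "sample_id": str, "status": str})
    df["diploid"] = df["diploid"].astype(bool)
    return df
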