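"""Observed heterozygote leakage inside called ROHs: the ep(P, h) statistic.

Allowing ``h`` heterozygous calls per scanning window lets genotyping errors
be bridged instead of breaking a run, but it also admits genuinely observed
hets into called segments.  ep(P, h) quantifies that leakage for a
population ``P`` at tolerance ``h``: segments of at least 1 Mb are grouped
into length bins, each bin contributes the arithmetic mean over its segments
of the per-segment het fraction (observed hets / SNPs in the segment), and
the bins are combined as a segment-count-weighted mean, expressed as a
percentage.  With the default bins this equals the unbinned mean per-segment
het fraction over all segments of at least 1 Mb.

The per-segment *fraction* (rather than the raw het count) is the adopted
definition: it makes ep directly comparable across platforms whose segments
contain very different SNP numbers, and matches the magnitudes this
statistic is reported at (well below 1%).  The raw-count variant is
available via ``mode="count"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .genotype_model import GenotypeMatrix, ROHCallSet
from .roh_caller import ROHParams, call_segments

#: half-open length bins in Mb covering [1, inf)
DEFAULT_BINS: tuple[tuple[float, float], ...] = (
    (1.0, 1.5),
    (1.5, 5.0),
    (5.0, 10.0),
    (10.0, math.inf),
)


def _check_bins(bins: Sequence[tuple[float, float]]) -> None:
    for (lo, hi), (lo2, _hi2) in zip(bins, bins[1:]):
        if hi != lo2:
            raise ValueError("length bins must be ordered and contiguous")
    if any(lo >= hi for lo, hi in bins):
        raise ValueError("each bin must satisfy lo < hi")


@dataclass(frozen=True)
class EpResult:
    """ep evaluation for one population / channel / tolerance."""

    population: str
    channel: str
    het_tolerance: int | None
    bin_counts: tuple[int, ...]
    bin_values: tuple[float, ...]
    ep_pct: float | None  # None when no segment reaches the first bin


def ep_bin(
    callset: ROHCallSet, lo_mb: float, hi_mb: float, mode: str = "fraction"
) -> tuple[int, float]:
    """Mean per-segment het statistic over segments with length in [lo, hi) Mb.

    Returns ``(n_segments, mean)``; an empty bin returns ``(0, 0.0)`` and
    carries zero weight in :func:`ep`.
    """
    if mode not in ("fraction", "count"):
        raise ValueError(f"mode must be 'fraction' or 'count', got {mode!r}")
    values = [
        seg.n_het_observed / seg.n_snp if mode == "fraction" else float(seg.n_het_observed)
        for seg in callset.segments
        if lo_mb <= seg.length_mb < hi_mb
    ]
    if not values:
        return 0, 0.0
    return len(values), sum(values) / len(values)


def ep(
    callset: ROHCallSet,
    bins: Sequence[tuple[float, float]] = DEFAULT_BINS,
    mode: str = "fraction",
) -> float | None:
    """Segment-count-weighted mean of per-bin het leakage, as a percentage.

    Returns ``None`` when no segment falls in any bin (leakage undefined).
    """
    _check_bins(bins)
    total_weight = 0
    total = 0.0
    for lo, hi in bins:
        n, value = ep_bin(callset, lo, hi, mode=mode)
        total_weight += n
        total += n * value
    if total_weight == 0:
        return None
    return 100.0 * total / total_weight


def ep_result(
    callset: ROHCallSet,
    bins: Sequence[tuple[float, float]] = DEFAULT_BINS,
    mode: str = "fraction",
) -> EpResult:
    """Full per-bin breakdown plus the overall ep percentage."""
    _check_bins(bins)
    counts, values = [], []
    for lo, hi in bins:
        n, value = ep_bin(callset, lo, hi, mode=mode)
        counts.append(n)
        values.append(value)
    total_weight = sum(counts)
    overall = (
        100.0 * sum(n * v for n, v in zip(counts, values)) / total_weight
        if total_weight
        else None
    )
    return EpResult(
        population=callset.population,
        channel=callset.channel,
        het_tolerance=callset.het_tolerance,
        bin_counts=tuple(counts),
        bin_values=tuple(values),
        ep_pct=overall,
    )


def ep_sweep(
    matrix: GenotypeMatrix,
    params: ROHParams | None = None,
    h_values: Sequence[int] = (1, 2, 3, 4, 5),
    population: str = "",
    bins: Sequence[tuple[float, float]] = DEFAULT_BINS,
    mode: str = "fraction",
) -> pd.DataFrame:
    """Call segments at each het tolerance and evaluate ep.

    Returns a tidy frame with one row per (h, bin) plus the overall value
    repeated per row (columns ``population, channel, h, bin_lo_mb, bin_hi_mb,
    n_segments, ep_bin, ep_overall_pct``).
    """
    if params is None:
        params = ROHParams()
    rows = []
    for h in h_values:
        callset = call_segments(matrix, params.with_het_tolerance(h), population)
        res = ep_result(callset, bins=bins, mode=mode)
        for (lo, hi), n, value in zip(bins, res.bin_counts, res.bin_values):
            rows.append(
                {
                    "population": population,
                    "channel": matrix.channel,
                    "h": h,
                    "bin_lo_mb": lo,
                    "bin_hi_mb": hi,
                    "n_segments": n,
                    "ep_bin": value,
                    "ep_overall_pct": res.ep_pct,
                }
            )
    return pd.DataFrame(rows)
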