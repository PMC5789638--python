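"""Population-level ROH summaries and array-vs-WGS statistical comparison.

Three per-individual statistics, computed over segments longer than 1 Mb
(the length above which runs predominantly reflect true autozygosity rather
than linkage disequilibrium): NROH (segment count), mean segment size in Mb,
and SROH (total summed length in Mb).  Channels are compared per population
by a two-sided Mann-Whitney-Wilcoxon rank-sum test on the per-individual
distributions and by Pearson correlation of the paired per-individual
values, for each WGS het tolerance against the array baseline (h = 1).

Length-class summaries use the conventional short (0.3-1 Mb), medium
(1-8 Mb) and long (> 8 Mb) classes; per-individual summed lengths in the
three classes partition the total summed length of all called segments of
at least 0.3 Mb.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_model import ROHCallSet

#: (label, lo_mb, hi_mb) half-open length classes
LENGTH_CLASSES: tuple[tuple[str, float, float], ...] = (
    ("short", 0.3, 1.0),
    ("medium", 1.0, 8.0),
    ("long", 8.0, np.inf),
)


@dataclass(frozen=True)
class ComparisonResult:
    population: str
    statistic: str
    het_tolerance: int
    pearson_r: float | None
    pearson_p: float | None
    mww_p: float


def summarize_individuals(
    callset: ROHCallSet,
    individuals: Sequence[str] | None = None,
    min_mb: float = 1.0,
) -> pd.DataFrame:
    """Per-individual NROH / mean size / SROH over segments longer than ``min_mb``.

    ``individuals`` fixes the rows (individuals without qualifying segments
    report ``nroh = 0``, ``sroh_mb = 0`` and an absent mean size); by default
    only individuals present in the callset appear.
    """
    if individuals is None:
        individuals = callset.individual_ids()
    lengths: dict[str, list[float]] = {iid: [] for iid in individuals}
    for seg in callset.segments:
        if seg.individual_id in lengths and seg.length_mb > min_mb:
            lengths[seg.individual_id].append(seg.length_mb)
    rows = []
    for iid in individuals:
        ls = lengths[iid]
        rows.append(
            {
                "individual_id": iid,
                "nroh": len(ls),
                "mean_size_mb": float(np.mean(ls)) if ls else float("nan"),
                "sroh_mb": float(np.sum(ls)),
            }
        )
    return pd.DataFrame(rows)


def mww_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney-Wilcoxon rank-sum p-value.

    Exact enumeration when both samples have at most 12 observations and no
    value is tied; otherwise the normal approximation with tie and continuity
    corrections.  Two identical constant samples compare as equal (p = 1).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(a) <= 12 and len(b) <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


def pearson_r(
    paired_a: Sequence[float], paired_b: Sequence[float]
) -> tuple[float, float] | None:
    """Product-moment correlation with its t-distribution p-value (n-2 df).

    Returns ``None`` when either vector has zero variance (r undefined).
    Requires at least 3 pairs.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired vectors must have equal length")
    if len(a) < 3:
        raise ValueError("at least 3 pairs are required")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return None
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def compare_channels(
    array_callset: ROHCallSet,
    wgs_callsets: Mapping[int, ROHCallSet],
    individuals: Sequence[str],
    min_mb: float = 1.0,
) -> pd.DataFrame:
    """Compare array (h = 1) against WGS callsets over a het-tolerance sweep.

    For each statistic (nroh, mean_size, sroh) and each WGS tolerance ``h``:
    the MWW p-value between the per-individual distributions and the Pearson
    correlation of the paired values.  Individuals absent from either side's
    ``individuals`` list raise; ``individuals`` should be the common cohort.
    Mean sizes of individuals without qualifying segments are excluded from
    the MWW sample and treated as 0 for the correlation pairing.
    """
    arr = summarize_individuals(array_callset, individuals, min_mb)
    extra = set(array_callset.individual_ids()) - set(individuals)
    for h, cs in wgs_callsets.items():
        extra |= set(cs.individual_ids()) - set(individuals)
    if extra:
        raise ValueError(f"individuals outside the common cohort: {sorted(extra)}")
    rows = []
    for h in sorted(wgs_callsets):
        w = summarize_individuals(wgs_callsets[h], individuals, min_mb)
        for stat_name in ("nroh", "mean_size_mb", "sroh_mb"):
            x = arr[stat_name].to_numpy(dtype=float)
            y = w[stat_name].to_numpy(dtype=float)
            if stat_name == "mean_size_mb":
                mww_p = mww_test(x[~np.isnan(x)], y[~np.isnan(y)])
                x = np.nan_to_num(x)
                y = np.nan_to_num(y)
            else:
                mww_p = mww_test(x, y)
            pr = pearson_r(x, y)
            rows.append(
                {
                    "population": array_callset.population,
                    "statistic": {"nroh": "nroh", "mean_size_mb": "mean_size",
                                  "sroh_mb": "sroh"}[stat_name],
                    "h": h,
                    "pearson_r": pr[0] if pr else float("nan"),
                    "pearson_p": pr[1] if pr else float("nan"),
                    "mww_p": mww_p,
                }
            )
    return pd.DataFrame(rows)


def comparison_matrices(results: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Pivot comparison rows into heatmap matrices (populations x h).

    Returns one matrix per statistic and quantity, keyed e.g.
    ``"nroh_pearson_r"`` / ``"nroh_mww_p"``.
    """
    out: dict[str, pd.DataFrame] = {}
    for stat_name in results["statistic"].unique():
        sub = results[results["statistic"] == stat_name]
        for col in ("pearson_r", "mww_p"):
            out[f"{stat_name}_{col}"] = sub.pivot(
                index="population", columns="h", values=col
            )
    return out


def length_class_sums(
    callset: ROHCallSet,
    individuals: Sequence[str] | None = None,
    classes: Sequence[tuple[str, float, float]] = LENGTH_CLASSES,
) -> pd.DataFrame:
    """Per-individual summed segment length (Mb) in each length class.

    Returns one row per individual with one column per class plus ``total``;
    the population mean is a ``.mean()`` away.
    """
    if individuals is None:
        individuals = callset.individual_ids()
    sums = {iid: {label: 0.0 for label, _, _ in classes} for iid in individuals}
    for seg in callset.segments:
        if seg.individual_id not in sums:
            continue
        for label, lo, hi in classes:
            if lo <= seg.length_mb < hi:
                sums[seg.individual_id][label] += seg.length_mb
                break
    rows = []
    for iid in individuals:
        row = {"individual_id": iid, **sums[iid]}
        row["total"] = sum(sums[iid].values())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# optional plotting helpers (numerical outputs never depend on these)
# ---------------------------------------------------------------------------

def plot_violin(per_channel: Mapping[str, Sequence[float]], title: str, path: str) -> None:
    """Violin plot (kernel density, interquartile bar, median dot) per channel."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(per_channel)
    data = [np.asarray(per_channel[k], dtype=float) for k in labels]
    fig, ax = plt.subplots(figsize=(1.2 * len(labels) + 2, 4))
    parts = ax.violinplot(data, showextrema=False)
    for body in parts["bodies"]:
        body.set_alpha(0.6)
    for i, d in enumerate(data, start=1):
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        ax.vlines(i, q1, q3, color="black", lw=4)
        ax.scatter([i], [med], color="white", zorder=3, s=12)
    ax.set_xticks(range(1, len(labels) + 1), labels)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(matrix: pd.DataFrame, title: str, path: str,
                 significance: float | None = None) -> None:
    """Heatmap of a comparison matrix; p-value maps can be thresholded at 0.05."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = matrix.to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(1 + 0.6 * matrix.shape[1], 1 + 0.5 * matrix.shape[0]))
    if significance is not None:
        shown = (values < significance).astype(float)
        cmap = "coolwarm"
    else:
        shown, cmap = values, "viridis"
    im = ax.imshow(shown, aspect="auto", cmap=cmap)
    ax.set_xticks(range(matrix.shape[1]), matrix.columns)
    ax.set_yticks(range(matrix.shape[0]), matrix.index)
    for (i, j), v in np.ndenumerate(values):
        ax.text(j, i, f"{v:.3f}", ha="center", va="center", fontsize=7)
    ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
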