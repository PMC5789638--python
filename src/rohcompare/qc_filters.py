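"""Per-population site QC: minor allele frequency and Hardy-Weinberg filtering.

Sites with sample MAF strictly below the threshold, or with a Hardy-Weinberg
exact-test p-value below the significance level, are removed before ROH
calling.  The MAF cut is strict ("lower than" the threshold is removed; a
site exactly at the threshold is kept).  QC is applied per population and
per technology channel independently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .genotype_model import GenotypeMatrix, HET, HOM_ALT, HOM_REF

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SiteQCStats:
    """Genotype counts, minor allele frequency and HWE p-value for one site."""

    n_called: int
    n_het: int
    n_hom_ref: int
    n_hom_alt: int
    maf: float
    hwe_p: float


def site_stats(matrix: GenotypeMatrix, site_index: int) -> SiteQCStats:
    """Compute :class:`SiteQCStats` for one site over called individuals only."""
    col = matrix.calls[:, site_index]
    n_het = int(np.count_nonzero(col == HET))
    n_hom_ref = int(np.count_nonzero(col == HOM_REF))
    n_hom_alt = int(np.count_nonzero(col == HOM_ALT))
    n_called = n_het + n_hom_ref + n_hom_alt
    if n_called == 0:
        raise ValueError(f"site {site_index} has no called individuals")
    c_alt = 2 * n_hom_alt + n_het
    c_ref = 2 * n_hom_ref + n_het
    maf = min(c_alt, c_ref) / (2 * n_called)
    return SiteQCStats(
        n_called=n_called,
        n_het=n_het,
        n_hom_ref=n_hom_ref,
        n_hom_alt=n_hom_alt,
        maf=maf,
        hwe_p=hwe_exact_p(n_het, n_hom_ref, n_hom_alt),
    )


@lru_cache(maxsize=200_000)
def _hwe_exact_cached(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    n = n_het + n_hom_minor + n_hom_major
    n_minor = 2 * n_hom_minor + n_het  # minor allele count by construction
    if n_minor == 0:
        return 1.0
    # Conditional on n individuals and the allele counts, the probability of
    # k heterozygotes is proportional to 2^k * n! / (n_aa! * k! * n_bb!) with
    # n_aa = (n_minor - k)/2.  Work with the exact integer numerators so the
    # two-sided tail (sum of configurations no more probable than observed)
    # involves no floating-point comparisons.
    n_fact = math.factorial(n)
    weights: dict[int, int] = {}
    for k in range(n_minor % 2, n_minor + 1, 2):
        n_aa = (n_minor - k) // 2
        n_bb = n - n_aa - k
        if n_bb < 0:
            continue
        weights[k] = (
            2**k * n_fact
            // (math.factorial(n_aa) * math.factorial(k) * math.factorial(n_bb))
        )
    w_obs = weights[n_het]
    numer = sum(w for w in weights.values() if w <= w_obs)
    denom = sum(weights.values())
    return numer / denom


def hwe_exact_p(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Two-sided Hardy-Weinberg exact test p-value.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose conditional probability does not exceed that of
    the observed count.  Monomorphic sites return 1.  The computation is
    exact (integer arithmetic) up to the final division.
    """
    if min(n_het, n_hom_ref, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    if n_het + n_hom_ref + n_hom_alt < 1:
        raise ValueError("at least one called genotype is required")
    # symmetric in the two homozygote classes; canonicalize for the cache
    return _hwe_exact_cached(n_het, min(n_hom_ref, n_hom_alt), max(n_hom_ref, n_hom_alt))


def hwe_chisq_p(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """One-df chi-square HWE test (no continuity correction), for comparison."""
    from scipy.stats import chi2

    n = n_het + n_hom_ref + n_hom_alt
    if n < 1:
        raise ValueError("at least one called genotype is required")
    p = (2 * n_hom_alt + n_het) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p**2])
    obs = np.array([n_hom_ref, n_het, n_hom_alt])
    stat = float(np.sum((obs - exp) ** 2 / exp))
    return float(chi2.sf(stat, df=1))


def apply_qc(
    matrix: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_alpha: float = 0.001,
    use_chisq: bool = False,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove sites failing the MAF or HWE criterion.

    Returns the filtered matrix and a removal report with one row per removed
    site (columns ``site_id``, ``reason`` in {``maf``, ``hwe``, ``no_calls``}
    and the offending statistic).  Sites failing both criteria are reported
    under ``maf``.  Raises if no site survives.
    """
    calls = matrix.calls
    n_het = np.count_nonzero(calls == HET, axis=0)
    n_hom_ref = np.count_nonzero(calls == HOM_REF, axis=0)
    n_hom_alt = np.count_nonzero(calls == HOM_ALT, axis=0)
    n_called = n_het + n_hom_ref + n_hom_alt

    c_alt = 2 * n_hom_alt + n_het
    c_ref = 2 * n_hom_ref + n_het
    with np.errstate(divide="ignore", invalid="ignore"):
        maf = np.minimum(c_alt, c_ref) / (2 * np.maximum(n_called, 1))

    hwe_test = hwe_chisq_p if use_chisq else hwe_exact_p
    keep = np.ones(matrix.n_sites, dtype=bool)
    records: list[tuple[str, str, float]] = []
    for j in range(matrix.n_sites):
        if n_called[j] == 0:
            keep[j] = False
            records.append((matrix.site_ids[j], "no_calls", float("nan")))
            continue
        if maf[j] < maf_min:
            keep[j] = False
            records.append((matrix.site_ids[j], "maf", float(maf[j])))
            continue
        p = hwe_test(int(n_het[j]), int(n_hom_ref[j]), int(n_hom_alt[j]))
        if p < hwe_alpha:
            keep[j] = False
            records.append((matrix.site_ids[j], "hwe", p))

    report = pd.DataFrame(records, columns=["site_id", "reason", "statistic"])
    n_maf = int((report["reason"] == "maf").sum())
    n_hwe = int((report["reason"] == "hwe").sum())
    log.info(
        "apply_qc(%s): removed %d/%d sites (%d maf < %g, %d hwe p < %g)",
        matrix.channel, len(records), matrix.n_sites, n_maf, maf_min, n_hwe, hwe_alpha,
    )
    if matrix.n_sites and not keep.any():
        raise ValueError(
            f"QC removed all {matrix.n_sites} sites "
            f"({n_maf} by MAF, {n_hwe} by HWE)"
        )
    return matrix.subset_sites(keep), report
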