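"""Observational sliding-window ROH detection (PLINK ``--homozyg`` semantics).

A fixed-size window of ``window_snp`` consecutive sites slides along each
chromosome; a window is *homozygous* when it contains at most ``window_het``
heterozygous and at most ``window_missing`` missing calls.  A site enters the
candidate ROH state when the fraction of homozygous windows among all windows
covering it reaches ``window_threshold``; near chromosome ends the actual
number of covering windows is the denominator.  Maximal runs of candidate
sites are split wherever two consecutive sites are more than ``max_gap_kb``
apart, trimmed so both ends are non-het and non-missing, and retained when
they satisfy the final SNP-count, length and density thresholds.

The defaults reproduce the standard PLINK 1.9 parameterization used for
cross-technology ROH comparison: windows of 50 SNPs, threshold 0.05, final
segments of at least 50 SNPs and 300 kb with at least 1 SNP per 50 kb, runs
broken at gaps above 1 Mb.  The het tolerance ``window_het`` is the tunable
of interest (1 for array data, 1-5 for low-coverage WGS).

There is no randomness anywhere in the caller: identical input and
parameters give byte-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .genotype_model import (
    GenotypeMatrix,
    HET,
    MISSING,
    ROHCallSet,
    ROHSegment,
)

# slack for the window-threshold comparison: the proportion test is a
# rational comparison (hom windows / covering windows >= threshold) evaluated
# in floats; the epsilon keeps e.g. 1/20 >= 0.05 true despite 0.05 having no
# exact binary representation.
_THRESHOLD_EPS = 1e-9


@dataclass(frozen=True)
class ROHParams:
    """PLINK-style ROH calling parameters (names mirror the PLINK flags)."""

    min_snp_final: int = 50          # homozyg-snp
    min_kb_final: float = 300.0      # homozyg-kb
    density_kb_per_snp: float = 50.0  # homozyg-density
    max_gap_kb: float = 1000.0       # homozyg-gap
    window_snp: int = 50             # homozyg-window-snp
    window_het: int = 1              # homozyg-window-het
    window_missing: int = 5          # homozyg-window-missing
    window_threshold: float = 0.05   # homozyg-window-threshold

    def __post_init__(self) -> None:
        if min(self.min_snp_final, self.window_snp) < 1:
            raise ValueError("SNP-count parameters must be positive")
        if min(self.min_kb_final, self.density_kb_per_snp, self.max_gap_kb) <= 0:
            raise ValueError("kb parameters must be positive")
        if min(self.window_het, self.window_missing) < 0:
            raise ValueError("window tolerances must be non-negative")
        if not 0 < self.window_threshold <= 1:
            raise ValueError("window_threshold must be in (0, 1]")

    def with_het_tolerance(self, h: int) -> "ROHParams":
        return replace(self, window_het=h)

    @classmethod
    def from_plink_dict(cls, d: dict) -> "ROHParams":
        mapping = {
            "homozyg_snp": "min_snp_final",
            "homozyg_kb": "min_kb_final",
            "homozyg_density": "density_kb_per_snp",
            "homozyg_gap": "max_gap_kb",
            "homozyg_window_snp": "window_snp",
            "homozyg_window_het": "window_het",
            "homozyg_window_missing": "window_missing",
            "homozyg_window_threshold": "window_threshold",
        }
        kwargs = {}
        for key, value in d.items():
            if key not in mapping:
                raise KeyError(f"unknown ROH parameter {key!r}")
            kwargs[mapping[key]] = value
        return cls(**kwargs)

    def to_plink_dict(self) -> dict:
        return {
            "homozyg_snp": self.min_snp_final,
            "homozyg_kb": self.min_kb_final,
            "homozyg_density": self.density_kb_per_snp,
            "homozyg_gap": self.max_gap_kb,
            "homozyg_window_snp": self.window_snp,
            "homozyg_window_het": self.window_het,
            "homozyg_window_missing": self.window_missing,
            "homozyg_window_threshold": self.window_threshold,
        }


def window_flags(calls: np.ndarray, params: ROHParams) -> np.ndarray:
    """Homozygosity flag for every complete window on one chromosome.

    ``calls`` is the ordered per-chromosome call vector of one individual.
    Window ``i`` covers sites ``i .. i + window_snp - 1``; it is flagged when
    its het count is at most ``window_het`` and its missing count at most
    ``window_missing``.  Returns a boolean array of length
    ``max(0, n_sites - window_snp + 1)``.
    """
    calls = np.asarray(calls)
    n = len(calls)
    w = params.window_snp
    if n < w:
        return np.zeros(0, dtype=bool)
    het_cum = np.concatenate(([0], np.cumsum(calls == HET)))
    mis_cum = np.concatenate(([0], np.cumsum(calls == MISSING)))
    het_in_win = het_cum[w:] - het_cum[:-w]
    mis_in_win = mis_cum[w:] - mis_cum[:-w]
    return (het_in_win <= params.window_het) & (mis_in_win <= params.window_missing)


def snp_homozygosity_state(
    flags: np.ndarray, n_sites: int, params: ROHParams
) -> np.ndarray:
    """Per-site candidate-ROH state from window flags.

    Site ``s`` is in-state when the fraction of homozygous windows among the
    windows covering it is at least ``window_threshold``; sites covered by
    zero windows (chromosome shorter than one window) are never in-state.
    """
    w = params.window_snp
    n_win = len(flags)
    if n_win == 0:
        return np.zeros(n_sites, dtype=bool)
    s = np.arange(n_sites)
    lo = np.maximum(0, s - w + 1)          # first window covering site s
    hi = np.minimum(s, n_win - 1)          # last window covering site s
    flag_cum = np.concatenate(([0], np.cumsum(flags)))
    hom_cov = flag_cum[hi + 1] - flag_cum[lo]
    total_cov = hi - lo + 1
    return hom_cov >= params.window_threshold * total_cov - _THRESHOLD_EPS


def _segments_for_chromosome(
    calls: np.ndarray,
    positions: np.ndarray,
    params: ROHParams,
    individual_id: str,
    chromosome: int,
) -> list[ROHSegment]:
    state = snp_homozygosity_state(window_flags(calls, params), len(calls), params)
    if not state.any():
        return []
    gap_bp = params.max_gap_kb * 1000.0
    is_hom = (calls != HET) & (calls != MISSING)
    het = calls == HET

    # maximal runs of in-state sites, additionally broken at large gaps
    idx = np.flatnonzero(state)
    # boundaries where consecutive in-state indices are non-adjacent or the
    # physical gap between consecutive sites exceeds the limit
    splits = np.flatnonzero(
        (np.diff(idx) != 1) | (np.diff(positions[idx]) > gap_bp)
    )
    starts = np.concatenate(([0], splits + 1))
    ends = np.concatenate((splits, [len(idx) - 1]))

    segments: list[ROHSegment] = []
    min_len_bp = params.min_kb_final * 1000.0
    for s0, e0 in zip(starts, ends):
        a, b = int(idx[s0]), int(idx[e0])
        # trim so the first and last site are non-het, non-missing
        while a <= b and not is_hom[a]:
            a += 1
        while b >= a and not is_hom[b]:
            b -= 1
        if a > b:
            continue
        n_snp = b - a + 1
        length_bp = int(positions[b] - positions[a] + 1)
        if n_snp < params.min_snp_final:
            continue
        if length_bp < min_len_bp:
            continue
        # density: at least one SNP per density_kb_per_snp kilobases
        if n_snp * params.density_kb_per_snp * 1000.0 < length_bp:
            continue
        segments.append(
            ROHSegment(
                individual_id=individual_id,
                chromosome=int(chromosome),
                start_pos=int(positions[a]),
                end_pos=int(positions[b]),
                n_snp=n_snp,
                n_het_observed=int(np.count_nonzero(het[a : b + 1])),
            )
        )
    return segments


def call_segments(
    matrix: GenotypeMatrix,
    params: ROHParams | None = None,
    population: str = "",
) -> ROHCallSet:
    """Call ROH segments for every individual in a (QC-filtered) matrix."""
    if params is None:
        params = ROHParams()
    segments: list[ROHSegment] = []
    chrom_values = np.unique(matrix.chromosomes)
    chrom_slices = {
        int(c): np.flatnonzero(matrix.chromosomes == c) for c in chrom_values
    }
    for i, iid in enumerate(matrix.individuals):
        row = matrix.calls[i]
        for c, cols in chrom_slices.items():
            segments.extend(
                _segments_for_chromosome(
                    row[cols], matrix.positions[cols], params, iid, c
                )
            )
    return ROHCallSet(
        segments=segments,
        params=params,
        channel=matrix.channel,
        population=population,
        het_tolerance=params.window_het,
    )


def call_sweep(
    matrix: GenotypeMatrix,
    params: ROHParams | None = None,
    h_values: Sequence[int] = (1, 2, 3, 4, 5),
    population: str = "",
) -> dict[int, ROHCallSet]:
    """Call segments at each het tolerance in ``h_values``."""
    if params is None:
        params = ROHParams()
    return {
        h: call_segments(matrix, params.with_het_tolerance(h), population)
        for h in h_values
    }
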