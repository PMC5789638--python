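"""Paired array/WGS genotype simulator with planted autozygous tracts.

The generator emulates the statistical structure the cross-technology ROH
analysis assumes: diploid autosomes carrying planted autozygous tracts,
observed through two channels that share the same underlying genotypes but
differ in site density and error profile.

* Sites are placed at jittered regular spacing; the array channel is a
  random positional subset of the WGS sites (about one in 6.5 at the default
  spacings of 7.1 kb vs 1.1 kb), so the two channels share a site universe
  by construction.
* Per-site alternate-allele frequencies are uniform on [0.05, 0.5] and
  background genotypes are drawn independently per site under Hardy-Weinberg
  proportions.  Linkage disequilibrium is deliberately not modelled: the
  analysis targets runs above 1 Mb and a 50-SNP minimum, where chance
  homozygous runs under independence are vanishingly rare.
* Inside planted tracts the true genotype is autozygous: a single allele is
  drawn at the site frequency and doubled, so the truth layer contains no
  het anywhere in a tract.
* Observation noise per channel: false heterozygotes placed uniformly at
  random over truly homozygous sites at a per-Mb rate (an error process
  blind to autozygosity, the low-coverage WGS failure mode); false
  homozygotes on truly het sites (allele dropout, either homozygote with
  equal probability); and uniform missingness.

All randomness derives from the single seed in :class:`SimConfig`;
identical seed and configuration give byte-identical output files.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .genotype_model import (
    GenotypeMatrix,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    ROHCallSet,
    write_vcf,
)

#: default expected tract counts per individual by length class (Mb)
DEFAULT_TRACT_RATES: tuple[tuple[float, float, float], ...] = (
    (0.3, 1.0, 4.0),
    (1.0, 1.5, 2.0),
    (1.5, 5.0, 2.0),
    (5.0, 10.0, 1.0),
    (10.0, 16.0, 0.3),
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the dual-channel simulator.

    Defaults give 20 individuals over 4 chromosomes of 50 Mb, WGS sites
    every ~1.1 kb with a 2.4/Mb false-het rate, array sites every ~7.1 kb
    with no false hets.  ``zul`` (0.3/Mb) and ``jpt`` (4.5/Mb) presets mirror
    the extremes of the published per-population error range.
    """

    n_individuals: int = 20
    n_chromosomes: int = 4
    chromosome_length_bp: int = 50_000_000
    array_spacing_bp: int = 7_100
    wgs_spacing_bp: int = 1_100
    maf_low: float = 0.05
    maf_high: float = 0.5
    tract_rates: tuple[tuple[float, float, float], ...] = DEFAULT_TRACT_RATES
    wgs_false_het_per_mb: float = 2.4
    array_false_het_per_mb: float = 0.0
    wgs_false_hom_rate: float = 0.02
    array_false_hom_rate: float = 0.0
    wgs_missing_rate: float = 0.002
    array_missing_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.array_spacing_bp, self.wgs_spacing_bp) < 1:
            raise ValueError("site spacings must be >= 1 bp")
        rates = (
            self.wgs_false_het_per_mb, self.array_false_het_per_mb,
            self.wgs_false_hom_rate, self.array_false_hom_rate,
            self.wgs_missing_rate, self.array_missing_rate,
        )
        if min(rates) < 0:
            raise ValueError("error rates must be >= 0")
        for lo, hi, rate in self.tract_rates:
            if not 0 < lo < hi:
                raise ValueError("tract length classes must satisfy 0 < lo < hi")
            if hi * 1e6 > self.chromosome_length_bp:
                raise ValueError(
                    f"tract class up to {hi} Mb exceeds chromosome length "
                    f"{self.chromosome_length_bp / 1e6} Mb"
                )
            if rate < 0:
                raise ValueError("tract rates must be >= 0")

    @property
    def genome_span_bp(self) -> int:
        return self.n_chromosomes * self.chromosome_length_bp

    @property
    def genome_span_mb(self) -> float:
        return self.genome_span_bp / 1e6


def preset(name: str, **overrides) -> SimConfig:
    """Named error presets: ``default`` 2.4/Mb, ``zul`` 0.3, ``jpt`` 4.5, ``clean`` 0."""
    rates = {"default": 2.4, "zul": 0.3, "jpt": 4.5, "clean": 0.0}
    if name not in rates:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(rates)}")
    kwargs = {"wgs_false_het_per_mb": rates[name]}
    if name == "clean":
        kwargs.update(
            wgs_false_hom_rate=0.0, array_false_hom_rate=0.0,
            wgs_missing_rate=0.0, array_missing_rate=0.0,
        )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@dataclass
class SimTruth:
    """Planted tracts and realized per-channel error sites."""

    tracts: pd.DataFrame         # individual_id, chromosome, start, end (1-based incl.)
    false_het: dict[str, pd.DataFrame]   # channel -> individual_id, chromosome, pos
    false_hom: dict[str, pd.DataFrame]
    config: SimConfig
    seed: int

    def tracts_for(self, individual_id: str) -> pd.DataFrame:
        return self.tracts[self.tracts["individual_id"] == individual_id]


def _place_sites(rng: np.random.Generator, spacing: int, length: int) -> np.ndarray:
    """Jittered regular spacing: uniform gaps in [0.5, 1.5) x spacing."""
    n_max = int(length / (0.5 * spacing)) + 2
    gaps = rng.integers(int(0.5 * spacing), int(1.5 * spacing), size=n_max)
    pos = np.cumsum(gaps)
    return pos[pos <= length].astype(np.int64)


def _plant_tracts(
    rng: np.random.Generator, config: SimConfig, individual_id: str
) -> list[tuple[str, int, int, int]]:
    tracts: list[tuple[str, int, int, int]] = []
    occupied: dict[int, list[tuple[int, int]]] = {
        c: [] for c in range(1, config.n_chromosomes + 1)
    }
    demands: list[int] = []
    for lo, hi, rate in config.tract_rates:
        for _ in range(rng.poisson(rate)):
            demands.append(int(rng.uniform(lo, hi) * 1e6))
    # longest first: rejection sampling stays reliable near capacity
    for length in sorted(demands, reverse=True):
        for _attempt in range(200):
            chrom = int(rng.integers(1, config.n_chromosomes + 1))
            start = int(rng.integers(1, config.chromosome_length_bp - length + 1))
            end = start + length - 1
            if all(end < s or start > e for s, e in occupied[chrom]):
                occupied[chrom].append((start, end))
                tracts.append((individual_id, chrom, start, end))
                break
        else:
            raise RuntimeError(
                f"could not place a {length / 1e6:.1f} Mb tract for "
                f"{individual_id}: genome capacity exhausted "
                f"({sum(e - s for c in occupied.values() for s, e in c) / 1e6:.0f} "
                f"Mb already occupied of {config.genome_span_mb:.0f} Mb)"
            )
    return tracts


def simulate(
    config: SimConfig | None = None, outdir: str | None = None
) -> tuple[GenotypeMatrix, GenotypeMatrix, SimTruth]:
    """Generate paired array/WGS observations and the underlying truth.

    When ``outdir`` is given, also writes ``array.vcf``, ``wgs.vcf``,
    ``truth.bed`` (0-based half-open) and ``sim_config.json`` there.
    """
    if config is None:
        config = SimConfig()
    rng = np.random.default_rng(config.seed)
    individuals = [f"ind{i + 1:03d}" for i in range(config.n_individuals)]

    # site maps: WGS dense grid per chromosome, array a positional subset
    wgs_chrom, wgs_pos = [], []
    for c in range(1, config.n_chromosomes + 1):
        pos = _place_sites(rng, config.wgs_spacing_bp, config.chromosome_length_bp)
        wgs_chrom.append(np.full(len(pos), c, dtype=np.int16))
        wgs_pos.append(pos)
    chroms = np.concatenate(wgs_chrom)
    positions = np.concatenate(wgs_pos)
    n_wgs = len(positions)
    array_mask = rng.random(n_wgs) < config.wgs_spacing_bp / config.array_spacing_bp

    p_alt = rng.uniform(config.maf_low, config.maf_high, size=n_wgs)
    ref = np.array(["A"] * n_wgs)
    alt = np.array(["G"] * n_wgs)
    site_ids = [f"snp{c}_{p}" for c, p in zip(chroms, positions)]

    # planted autozygous tracts
    tract_records: list[tuple[str, int, int, int]] = []
    for iid in individuals:
        tract_records.extend(_plant_tracts(rng, config, iid))
    tracts = pd.DataFrame(
        tract_records, columns=["individual_id", "chromosome", "start", "end"]
    )

    # truth genotypes: HWE background, forced autozygous inside tracts
    truth = np.empty((config.n_individuals, n_wgs), dtype=np.int8)
    chrom_offsets = {
        int(c): np.flatnonzero(chroms == c) for c in range(1, config.n_chromosomes + 1)
    }
    for i, iid in enumerate(individuals):
        g = rng.binomial(2, p_alt).astype(np.int8)
        for _, row in tracts[tracts["individual_id"] == iid].iterrows():
            cols = chrom_offsets[int(row["chromosome"])]
            pos_c = positions[cols]
            a = np.searchsorted(pos_c, row["start"], side="left")
            b = np.searchsorted(pos_c, row["end"], side="right")
            sel = cols[a:b]
            g[sel] = 2 * rng.binomial(1, p_alt[sel]).astype(np.int8)
        truth[i] = g

    def observe(
        channel: str,
        cols: np.ndarray,
        false_het_per_mb: float,
        false_hom_rate: float,
        missing_rate: float,
    ) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
        calls = truth[:, cols].copy()
        sub_chroms = chroms[cols]
        sub_pos = positions[cols]
        fh_rows, fhom_rows = [], []
        span_mb = config.genome_span_mb
        for i, iid in enumerate(individuals):
            row = calls[i]
            hom_idx = np.flatnonzero(row != HET)
            if false_het_per_mb > 0 and len(hom_idx):
                p_flip = min(1.0, false_het_per_mb * span_mb / len(hom_idx))
                flips = hom_idx[rng.random(len(hom_idx)) < p_flip]
                row[flips] = HET
                fh_rows.extend(
                    (iid, int(c), int(p))
                    for c, p in zip(sub_chroms[flips], sub_pos[flips])
                )
            het_idx = np.flatnonzero(truth[i, cols] == HET)
            if false_hom_rate > 0 and len(het_idx):
                drops = het_idx[rng.random(len(het_idx)) < false_hom_rate]
                row[drops] = np.where(
                    rng.random(len(drops)) < 0.5, HOM_REF, HOM_ALT
                ).astype(np.int8)
                fhom_rows.extend(
                    (iid, int(c), int(p))
                    for c, p in zip(sub_chroms[drops], sub_pos[drops])
                )
            if missing_rate > 0:
                row[rng.random(len(row)) < missing_rate] = MISSING
        matrix = GenotypeMatrix(
            chroms[cols], positions[cols],
            [site_ids[j] for j in cols],
            [ref[j] for j in cols], [alt[j] for j in cols],
            individuals, calls, channel,
        )
        errors = pd.DataFrame(fh_rows, columns=["individual_id", "chromosome", "pos"])
        dropouts = pd.DataFrame(fhom_rows, columns=["individual_id", "chromosome", "pos"])
        return matrix, errors, dropouts

    all_cols = np.arange(n_wgs)
    # array first, then wgs: a fixed order keeps the draw sequence reproducible
    array_matrix, fh_a, fhom_a = observe(
        "array", np.flatnonzero(array_mask),
        config.array_false_het_per_mb, config.array_false_hom_rate,
        config.array_missing_rate,
    )
    wgs_matrix, fh_w, fhom_w = observe(
        "wgs", all_cols,
        config.wgs_false_het_per_mb, config.wgs_false_hom_rate,
        config.wgs_missing_rate,
    )
    sim_truth = SimTruth(
        tracts=tracts,
        false_het={"array": fh_a, "wgs": fh_w},
        false_hom={"array": fhom_a, "wgs": fhom_w},
        config=config,
        seed=config.seed,
    )
    if outdir is not None:
        write_sim_outputs(array_matrix, wgs_matrix, sim_truth, outdir)
    return array_matrix, wgs_matrix, sim_truth


def write_truth_bed(truth: SimTruth, path: str) -> None:
    """Planted tracts as BED (0-based half-open, one row per tract)."""
    with open(path, "w") as fh:
        for _, row in truth.tracts.iterrows():
            fh.write(
                f"{row['chromosome']}\t{row['start'] - 1}\t{row['end']}\t"
                f"{row['individual_id']}\n"
            )


def write_sim_outputs(
    array_matrix: GenotypeMatrix,
    wgs_matrix: GenotypeMatrix,
    truth: SimTruth,
    outdir: str,
) -> None:
    os.makedirs(outdir, exist_ok=True)
    write_vcf(array_matrix, os.path.join(outdir, "array.vcf"))
    write_vcf(wgs_matrix, os.path.join(outdir, "wgs.vcf"))
    write_truth_bed(truth, os.path.join(outdir, "truth.bed"))
    with open(os.path.join(outdir, "sim_config.json"), "w") as fh:
        json.dump(asdict(truth.config), fh, indent=2, default=list)
        fh.write("\n")


# ---------------------------------------------------------------------------
# evaluation against planted truth
# ---------------------------------------------------------------------------

def _overlap_bp(
    start: int, end: int, others: np.ndarray
) -> int:
    """Total bp of [start, end] covered by the (sorted, disjoint) intervals."""
    if len(others) == 0:
        return 0
    s = np.maximum(others[:, 0], start)
    e = np.minimum(others[:, 1], end)
    return int(np.sum(np.maximum(0, e - s + 1)))


def truth_overlap(
    callset: ROHCallSet,
    truth: SimTruth,
    classes: tuple[tuple[float, float], ...] = tuple(
        (lo, hi) for lo, hi, _ in DEFAULT_TRACT_RATES
    ),
) -> pd.DataFrame:
    """Base-pair sensitivity/precision of a callset against planted tracts.

    One row per length class (classes refer to *tract* length for
    sensitivity and recovery, *called-segment* length for precision):

    * ``sensitivity`` — overlapped tract bp / total tract bp in class;
    * ``precision`` — overlapped called bp / total called bp in class
      (NaN when nothing was called in the class);
    * ``recovered`` — fraction of tracts with >= 50% reciprocal overlap
      with a single called segment;
    * ``calls_per_tract`` — mean number of called segments intersecting
      each tract (fragmentation).
    """
    seg_by_key: dict[tuple[str, int], list | np.ndarray] = {}
    for seg in callset.segments:
        seg_by_key.setdefault((seg.individual_id, seg.chromosome), []).append(
            (seg.start_pos, seg.end_pos)
        )
    seg_by_key = {
        k: np.array(sorted(v), dtype=np.int64) for k, v in seg_by_key.items()
    }
    tract_by_key: dict[tuple[str, int], list | np.ndarray] = {}
    for _, row in truth.tracts.iterrows():
        tract_by_key.setdefault(
            (row["individual_id"], int(row["chromosome"])), []
        ).append((int(row["start"]), int(row["end"])))
    tract_by_key = {
        k: np.array(sorted(v), dtype=np.int64) for k, v in tract_by_key.items()
    }

    rows = []
    for lo, hi in classes:
        lo_bp, hi_bp = lo * 1e6, hi * 1e6
        truth_bp = overlap_t = 0
        called_bp = overlap_c = 0
        n_tracts = n_recovered = n_calls_on_tracts = 0
        for key, tr in tract_by_key.items():
            segs = seg_by_key.get(key, np.empty((0, 2), dtype=np.int64))
            for start, end in tr:
                length = end - start + 1
                if not lo_bp <= length < hi_bp:
                    continue
                n_tracts += 1
                truth_bp += length
                overlap_t += _overlap_bp(start, end, segs)
                hits = 0
                for s, e in segs:
                    inter = min(e, end) - max(s, start) + 1
                    if inter > 0:
                        hits += 1
                        if inter >= 0.5 * length and inter >= 0.5 * (e - s + 1):
                            n_recovered += 1
                n_calls_on_tracts += hits
        for key, segs in seg_by_key.items():
            tr = tract_by_key.get(key, np.empty((0, 2), dtype=np.int64))
            for s, e in segs:
                length = e - s + 1
                if not lo_bp <= length < hi_bp:
                    continue
                called_bp += length
                overlap_c += _overlap_bp(s, e, tr)
        rows.append(
            {
                "class_lo_mb": lo,
                "class_hi_mb": hi,
                "n_tracts": n_tracts,
                "sensitivity": overlap_t / truth_bp if truth_bp else float("nan"),
                "precision": overlap_c / called_bp if called_bp else float("nan"),
                "recovered": n_recovered / n_tracts if n_tracts else float("nan"),
                "calls_per_tract": n_calls_on_tracts / n_tracts if n_tracts else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def bp_sensitivity(
    callset: ROHCallSet, truth: SimTruth, min_tract_mb: float = 1.0
) -> float:
    """Base-pair sensitivity over all planted tracts of at least ``min_tract_mb``."""
    table = truth_overlap(callset, truth, classes=((min_tract_mb, np.inf),))
    return float(table["sensitivity"].iloc[0])
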