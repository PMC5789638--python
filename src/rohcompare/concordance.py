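"""Cross-technology genotype concordance decomposition.

For each individual, genotype calls from an array channel and a WGS channel
are compared over the *shared* site universe: sites present (by chromosome
and position) and non-missing in both channels.  Each shared site falls in
exactly one class:

* concordant — the same four-state call in both channels;
* het-array / hom-WGS — the array says het, WGS says homozygous (either);
* hom-array / het-WGS — the array says homozygous, WGS says het (with array
  genotyping as the gold standard these are the WGS false heterozygotes that
  can break a run of homozygosity);
* hom/hom mismatch — both homozygous but for opposite alleles.  These are
  counted in the total discordance but reported separately from the two
  named het components.

Percentages are computed per individual and averaged within a population.
Per-megabase false-het rates use a configurable autosomal span (default
2800 Mb, the approximate assayable autosomal genome).

The module also ships the published 20-population KGP/AGVP variant-calling
concordance table (Infinium Omni 2.5-8 array vs ~4x WGS) as packaged data,
usable as a reference input for the summary arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .genotype_model import GenotypeMatrix, HET, MISSING

#: approximate autosomal span in Mb used for per-Mb rates
DEFAULT_SPAN_MB = 2800.0


@dataclass(frozen=True)
class IndividualConcordance:
    """Shared-site classification counts for one individual."""

    individual_id: str
    n_shared: int
    n_concordant: int
    n_het_array_hom_wgs: int
    n_hom_array_het_wgs: int
    n_homhom_mismatch: int

    @property
    def concordant_pct(self) -> float:
        return 100.0 * self.n_concordant / self.n_shared

    @property
    def discordant_pct(self) -> float:
        return 100.0 - self.concordant_pct

    @property
    def het_array_hom_wgs_pct(self) -> float:
        return 100.0 * self.n_het_array_hom_wgs / self.n_shared

    @property
    def hom_array_het_wgs_pct(self) -> float:
        return 100.0 * self.n_hom_array_het_wgs / self.n_shared

    @property
    def homhom_mismatch_pct(self) -> float:
        return 100.0 * self.n_homhom_mismatch / self.n_shared


def _shared_site_indices(
    array: GenotypeMatrix, wgs: GenotypeMatrix
) -> tuple[np.ndarray, np.ndarray]:
    keys_a = array.position_keys()
    keys_w = wgs.position_keys()
    _, ia, iw = np.intersect1d(keys_a, keys_w, assume_unique=True, return_indices=True)
    return ia, iw


def per_individual_concordance(
    array: GenotypeMatrix, wgs: GenotypeMatrix, individual_id: str
) -> IndividualConcordance:
    """Classify every shared, jointly called site for one individual."""
    ia, iw = _shared_site_indices(array, wgs)
    ga = array.calls[array.individual_index(individual_id), ia]
    gw = wgs.calls[wgs.individual_index(individual_id), iw]
    called = (ga != MISSING) & (gw != MISSING)
    ga, gw = ga[called], gw[called]
    n_shared = len(ga)
    if n_shared == 0:
        raise ValueError(f"no jointly called shared sites for {individual_id!r}")
    het_a = ga == HET
    het_w = gw == HET
    concordant = ga == gw
    het_a_hom_w = het_a & ~het_w
    hom_a_het_w = ~het_a & het_w
    homhom_mismatch = ~concordant & ~het_a & ~het_w
    return IndividualConcordance(
        individual_id=individual_id,
        n_shared=n_shared,
        n_concordant=int(concordant.sum()),
        n_het_array_hom_wgs=int(het_a_hom_w.sum()),
        n_hom_array_het_wgs=int(hom_a_het_w.sum()),
        n_homhom_mismatch=int(homhom_mismatch.sum()),
    )


def concordance_table(
    array: GenotypeMatrix,
    wgs: GenotypeMatrix,
    populations: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-population concordance decomposition (one row per population).

    ``populations`` maps individual IDs to population labels; by default all
    individuals form a single ``"ALL"`` population.  Mean het counts per
    channel are counted over each channel's full site list (not only shared
    sites), mirroring how per-technology het burdens are tabulated.
    """
    if populations is None:
        populations = {iid: "ALL" for iid in array.individuals}
    rows = []
    for iid in array.individuals:
        if iid not in wgs.individuals:
            raise KeyError(f"individual {iid!r} missing from wgs channel")
        ic = per_individual_concordance(array, wgs, iid)
        het_w = int(np.count_nonzero(wgs.calls[wgs.individual_index(iid)] == HET))
        het_a = int(np.count_nonzero(array.calls[array.individual_index(iid)] == HET))
        rows.append(
            {
                "individual_id": iid,
                "population": populations.get(iid, "ALL"),
                "mean_het_wgs": het_w,
                "mean_het_array": het_a,
                "concordant_pct": ic.concordant_pct,
                "discordant_pct": ic.discordant_pct,
                "het_array_hom_wgs_pct": ic.het_array_hom_wgs_pct,
                "hom_array_het_wgs_pct": ic.hom_array_het_wgs_pct,
                "homhom_mismatch_pct": ic.homhom_mismatch_pct,
            }
        )
    per_ind = pd.DataFrame(rows)
    return (
        per_ind.drop(columns="individual_id")
        .groupby("population", sort=True)
        .mean()
        .reset_index()
    )


def roh_error(
    array: GenotypeMatrix,
    wgs: GenotypeMatrix,
    span_mb: float = DEFAULT_SPAN_MB,
) -> pd.DataFrame:
    """Rate of WGS false heterozygotes able to break a ROH, per individual.

    Both matrices are expected to have passed QC already.  Returns one row
    per individual with the count of hom-array/het-WGS sites, their
    percentage of shared sites, and the per-Mb rate over ``span_mb``.
    """
    rows = []
    for iid in array.individuals:
        ic = per_individual_concordance(array, wgs, iid)
        rows.append(
            {
                "individual_id": iid,
                "n_false_het": ic.n_hom_array_het_wgs,
                "pct_of_shared": ic.hom_array_het_wgs_pct,
                "per_mb": ic.n_hom_array_het_wgs / span_mb,
            }
        )
    return pd.DataFrame(rows)


def false_het_rate_per_mb(n_false_het: float, span_mb: float = DEFAULT_SPAN_MB) -> float:
    """Mean per-individual false-het count expressed per megabase."""
    return n_false_het / span_mb


def het_density(matrix: GenotypeMatrix, span_bp: float = DEFAULT_SPAN_MB * 1e6) -> float:
    """Mean kb between heterozygous calls (span / mean per-individual het count).

    Raises when no individual carries a het call (density undefined).
    """
    het_counts = np.count_nonzero(matrix.calls == HET, axis=1)
    mean_het = het_counts.mean() if len(het_counts) else 0.0
    if mean_het == 0:
        raise ValueError("no heterozygous calls: het density undefined")
    return span_bp / mean_het / 1000.0


def load_published_concordance() -> pd.DataFrame:
    """Published KGP/AGVP 20-population variant-calling concordance table."""
    ref = resources.files("rohcompare.data") / "kgp_agvp_variant_calling.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def summarize_concordance(table: pd.DataFrame) -> dict[str, float]:
    """Cross-population summary of a concordance table.

    Works on :func:`concordance_table` output or the published table: means
    of the percentage columns, the WGS/array het-count ratio and the implied
    WGS het spacing in kb over the default autosomal span.
    """
    mean_het_wgs = float(table["mean_het_wgs"].mean())
    mean_het_array = float(table["mean_het_array"].mean())
    return {
        "mean_concordant_pct": float(table["concordant_pct"].mean()),
        "mean_discordant_pct": float(table["discordant_pct"].mean()),
        "mean_het_array_hom_wgs_pct": float(table["het_array_hom_wgs_pct"].mean()),
        "mean_hom_array_het_wgs_pct": float(table["hom_array_het_wgs_pct"].mean()),
        "mean_het_wgs": mean_het_wgs,
        "mean_het_array": mean_het_array,
        "wgs_array_het_ratio": mean_het_wgs / mean_het_array,
        "wgs_het_spacing_kb": DEFAULT_SPAN_MB * 1e6 / mean_het_wgs / 1000.0,
        "array_het_spacing_kb": DEFAULT_SPAN_MB * 1e6 / mean_het_array / 1000.0,
    }
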