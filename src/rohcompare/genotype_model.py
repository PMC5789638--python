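"""Core genotype and ROH data containers plus readers/writers for standard formats.

Genotype calls are stored as a dense ``int8`` matrix (individuals x sites)
using the four-state encoding :data:`HOM_REF`, :data:`HET`, :data:`HOM_ALT`,
:data:`MISSING`.  Heterozygosity is genotype-level: any call with two
different alleles counts as het, phase is ignored.  Coordinates are 1-based
and segment ends are inclusive, matching PLINK ``.hom`` reporting, so
``length_bp = end - start + 1``.

Only the 22 human autosomes are modelled; records on other contigs are
skipped on read (``chr`` prefixes are stripped before the check).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)

# four-state genotype encoding
HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

CALL_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}

_HOM_COLUMNS = ("IID", "CHR", "POS1", "POS2", "KB", "NSNP", "NHET")


@dataclass(frozen=True)
class Site:
    """A biallelic autosomal SNP site (1-based position)."""

    chromosome: int
    position: int
    site_id: str
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if not 1 <= self.chromosome <= 22:
            raise ValueError(f"chromosome must be an autosome 1-22, got {self.chromosome}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt allele identical at {self.site_id}")


class GenotypeMatrix:
    """Diploid genotype calls for one technology channel.

    Parameters
    ----------
    chromosomes, positions
        Per-site arrays, sorted by chromosome then position, strictly
        increasing within each chromosome.
    site_ids, ref_alleles, alt_alleles
        Per-site identifiers and allele symbols.
    individuals
        Ordered individual IDs (rows of ``calls``).
    calls
        ``(n_individuals, n_sites)`` int8 array in the four-state encoding.
    channel
        Tag, ``"array"`` or ``"wgs"``.
    """

    def __init__(
        self,
        chromosomes: np.ndarray,
        positions: np.ndarray,
        site_ids: Sequence[str],
        ref_alleles: Sequence[str],
        alt_alleles: Sequence[str],
        individuals: Sequence[str],
        calls: np.ndarray,
        channel: str,
    ) -> None:
        self.chromosomes = np.asarray(chromosomes, dtype=np.int16)
        self.positions = np.asarray(positions, dtype=np.int64)
        self.site_ids = list(site_ids)
        self.ref_alleles = list(ref_alleles)
        self.alt_alleles = list(alt_alleles)
        self.individuals = list(individuals)
        self.calls = np.asarray(calls, dtype=np.int8)
        self.channel = channel
        self._validate()

    def _validate(self) -> None:
        n_sites = len(self.positions)
        if self.calls.shape != (len(self.individuals), n_sites):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {n_sites} sites"
            )
        for arr, name in ((self.site_ids, "site_ids"), (self.ref_alleles, "ref_alleles"),
                          (self.alt_alleles, "alt_alleles")):
            if len(arr) != n_sites:
                raise ValueError(f"{name} length {len(arr)} != {n_sites} sites")
        if n_sites:
            if np.any((self.chromosomes < 1) | (self.chromosomes > 22)):
                raise ValueError("chromosome labels must be autosomes 1-22")
            order = np.lexsort((self.positions, self.chromosomes))
            if not np.array_equal(order, np.arange(n_sites)):
                raise ValueError("sites must be sorted by chromosome then position")
            same_chrom = self.chromosomes[1:] == self.chromosomes[:-1]
            if np.any(same_chrom & (np.diff(self.positions) <= 0)):
                raise ValueError("positions must be strictly increasing within a chromosome")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def site(self, index: int) -> Site:
        return Site(
            chromosome=int(self.chromosomes[index]),
            position=int(self.positions[index]),
            site_id=self.site_ids[index],
            ref_allele=self.ref_alleles[index],
            alt_allele=self.alt_alleles[index],
        )

    def individual_index(self, individual_id: str) -> int:
        try:
            return self.individuals.index(individual_id)
        except ValueError:
            raise KeyError(
                f"individual {individual_id!r} not present in {self.channel} channel"
            ) from None

    def subset_sites(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given site mask / index array."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.chromosomes[idx],
            self.positions[idx],
            [self.site_ids[i] for i in idx],
            [self.ref_alleles[i] for i in idx],
            [self.alt_alleles[i] for i in idx],
            self.individuals,
            self.calls[:, idx],
            self.channel,
        )

    def position_keys(self) -> np.ndarray:
        """Encode (chromosome, position) pairs as sortable int64 keys."""
        return self.chromosomes.astype(np.int64) * 10**10 + self.positions

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.chromosomes, other.chromosomes)
            and np.array_equal(self.positions, other.positions)
            and self.site_ids == other.site_ids
            and self.ref_alleles == other.ref_alleles
            and self.alt_alleles == other.alt_alleles
            and self.individuals == other.individuals
            and np.array_equal(self.calls, other.calls)
            and self.channel == other.channel
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix({self.n_individuals} individuals x {self.n_sites} sites, "
            f"channel={self.channel!r})"
        )


@dataclass(frozen=True)
class ROHSegment:
    """One called run of homozygosity (1-based, both ends inclusive)."""

    individual_id: str
    chromosome: int
    start_pos: int
    end_pos: int
    n_snp: int
    n_het_observed: int

    def __post_init__(self) -> None:
        if self.start_pos > self.end_pos:
            raise ValueError("start_pos must be <= end_pos")
        if self.n_snp < 1:
            raise ValueError("segment must contain at least one site")
        if self.n_het_observed > self.n_snp:
            raise ValueError("n_het_observed cannot exceed n_snp")

    @property
    def length_bp(self) -> int:
        return self.end_pos - self.start_pos + 1

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6


@dataclass
class ROHCallSet:
    """Called ROH segments for one channel / population / het tolerance."""

    segments: list[ROHSegment]
    params: "object" = None  # ROHParams; kept loose to avoid a circular import
    channel: str = ""
    population: str = ""
    het_tolerance: int | None = None

    def __post_init__(self) -> None:
        by_key: dict[tuple[str, int], list[ROHSegment]] = {}
        for seg in self.segments:
            by_key.setdefault((seg.individual_id, seg.chromosome), []).append(seg)
        for segs in by_key.values():
            segs = sorted(segs, key=lambda s: s.start_pos)
            for a, b in zip(segs, segs[1:]):
                if b.start_pos <= a.end_pos:
                    raise ValueError(
                        f"overlapping segments for {a.individual_id} chr{a.chromosome}: "
                        f"{a.start_pos}-{a.end_pos} and {b.start_pos}-{b.end_pos}"
                    )

    def for_individual(self, individual_id: str) -> list[ROHSegment]:
        return [s for s in self.segments if s.individual_id == individual_id]

    def individual_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.segments:
            seen.setdefault(s.individual_id)
        return list(seen)

    def __len__(self) -> int:
        return len(self.segments)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _normalize_chrom(label: str) -> int | None:
    """Map a contig label to an autosome number, or None if not 1..22."""
    if label.lower().startswith("chr"):
        label = label[3:]
    try:
        c = int(label)
    except ValueError:
        return None
    return c if 1 <= c <= 22 else None


def read_vcf(path: str, channel: str) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF into a :class:`GenotypeMatrix`.

    Only the GT subfield is consulted; phased and unphased genotypes are
    treated identically and half-missing calls become missing.  Multi-allelic
    records, non-SNP records and contigs outside the 22 autosomes are skipped
    (counts are logged).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    individuals = list(vcf.samples)
    chroms: list[int] = []
    positions: list[int] = []
    site_ids: list[str] = []
    refs: list[str] = []
    alts: list[str] = []
    columns: list[np.ndarray] = []
    n_skipped_nonsnp = 0
    n_skipped_contig = 0
    bases = {"A", "C", "G", "T"}
    for variant in vcf:
        chrom = _normalize_chrom(variant.CHROM)
        if chrom is None:
            n_skipped_contig += 1
            continue
        if (
            len(variant.ALT) != 1
            or len(variant.REF) != 1
            or len(variant.ALT[0]) != 1
            or variant.REF not in bases
            or variant.ALT[0] not in bases
        ):
            n_skipped_nonsnp += 1
            continue
        # gts012: 0=hom_ref, 1=het, 2=hom_alt, 3=unknown
        gt = np.asarray(variant.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        chroms.append(chrom)
        positions.append(variant.POS)
        site_ids.append(variant.ID or f"{chrom}:{variant.POS}")
        refs.append(variant.REF)
        alts.append(variant.ALT[0])
        columns.append(gt)
    vcf.close()
    if n_skipped_nonsnp or n_skipped_contig:
        log.info(
            "read_vcf(%s): skipped %d multi-allelic/non-SNP and %d off-autosome records",
            path, n_skipped_nonsnp, n_skipped_contig,
        )
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(individuals), 0), dtype=np.int8)
    )
    matrix = GenotypeMatrix(
        np.array(chroms, dtype=np.int16),
        np.array(positions, dtype=np.int64),
        site_ids, refs, alts, individuals, calls, channel,
    )
    return matrix


def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write a :class:`GenotypeMatrix` as a minimal VCF 4.2 text file."""
    code_to_gt = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(set(int(c) for c in matrix.chromosomes)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.individuals) + "\n")
        for j in range(matrix.n_sites):
            row = [
                str(int(matrix.chromosomes[j])),
                str(int(matrix.positions[j])),
                matrix.site_ids[j],
                matrix.ref_alleles[j],
                matrix.alt_alleles[j],
                ".", ".", ".", "GT",
            ]
            row.extend(code_to_gt[int(g)] for g in matrix.calls[:, j])
            fh.write("\t".join(row) + "\n")


def read_ped_map(
    ped_path: str,
    map_path: str,
    channel: str = "array",
    ref_alleles: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Read PLINK text PED/MAP files.

    ``ref_alleles`` optionally fixes the reference allele per site; without it
    the lexicographically smaller observed allele is taken as reference (the
    het/hom distinction does not depend on this choice).  ``0`` alleles mean
    missing; a half-missing pair is treated as missing.
    """
    sites: list[tuple[int, int, str]] = []
    with open(map_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.split()
            chrom = _normalize_chrom(parts[0])
            if chrom is None:
                raise ValueError(f"MAP contig {parts[0]!r} is not an autosome 1-22")
            sites.append((chrom, int(parts[3]), parts[1]))
    n_sites = len(sites)

    individuals: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.split()
            expected = 6 + 2 * n_sites
            if len(parts) != expected:
                raise ValueError(
                    f"PED line has {len(parts)} columns, expected {expected} "
                    f"(6 + 2 x {n_sites} MAP rows)"
                )
            individuals.append(parts[1])
            allele_rows.append(
                [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(n_sites)]
            )

    refs: list[str] = []
    alts: list[str] = []
    calls = np.full((len(individuals), n_sites), MISSING, dtype=np.int8)
    for j in range(n_sites):
        observed = sorted(
            {a for row in allele_rows for a in row[j] if a != "0"}
        )
        if ref_alleles is not None:
            ref = ref_alleles[j]
            others = [a for a in observed if a != ref]
            alt = others[0] if others else ("A" if ref != "A" else "G")
        else:
            ref = observed[0] if observed else "A"
            alt = observed[1] if len(observed) > 1 else ("G" if ref != "G" else "A")
        refs.append(ref)
        alts.append(alt)
        for i, row in enumerate(allele_rows):
            a, b = row[j]
            if a == "0" or b == "0":
                calls[i, j] = MISSING
            elif a != b:
                calls[i, j] = HET
            elif a == ref:
                calls[i, j] = HOM_REF
            else:
                calls[i, j] = HOM_ALT

    order = np.lexsort(
        (np.array([p for _, p, _ in sites]), np.array([c for c, _, _ in sites]))
    )
    return GenotypeMatrix(
        np.array([sites[k][0] for k in order], dtype=np.int16),
        np.array([sites[k][1] for k in order], dtype=np.int64),
        [sites[k][2] for k in order],
        [refs[k] for k in order],
        [alts[k] for k in order],
        individuals,
        calls[:, order],
        channel,
    )


def write_hom_table(callset: ROHCallSet, path: str) -> None:
    """Write a PLINK ``.hom``-style tab-separated segment table."""
    with open(path, "w") as fh:
        fh.write("\t".join(_HOM_COLUMNS) + "\n")
        for seg in callset.segments:
            fh.write(
                "\t".join(
                    [
                        seg.individual_id,
                        str(seg.chromosome),
                        str(seg.start_pos),
                        str(seg.end_pos),
                        f"{seg.length_bp / 1000:.3f}",
                        str(seg.n_snp),
                        str(seg.n_het_observed),
                    ]
                )
                + "\n"
            )


def read_hom_table(
    path: str,
    params=None,
    channel: str = "",
    population: str = "",
    het_tolerance: int | None = None,
) -> ROHCallSet:
    """Read a ``.hom``-style table written by :func:`write_hom_table`."""
    segments: list[ROHSegment] = []
    with open(path) as fh:
        header = fh.readline().split()
        if tuple(header) != _HOM_COLUMNS:
            raise ValueError(f"unexpected .hom header {header}")
        for line in fh:
            if not line.strip():
                continue
            iid, chrom, pos1, pos2, _kb, nsnp, nhet = line.split("\t")
            segments.append(
                ROHSegment(
                    individual_id=iid,
                    chromosome=int(chrom),
                    start_pos=int(pos1),
                    end_pos=int(pos2),
                    n_snp=int(nsnp),
                    n_het_observed=int(nhet),
                )
            )
    return ROHCallSet(
        segments=segments,
        params=params,
        channel=channel,
        population=population,
        het_tolerance=het_tolerance,
    )
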