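"""Genotype input, encoding, filtering and nucleotide diversity.

Diploid biallelic genotypes are held in a dense ``GenotypeMatrix`` of
per-site codes (HOM_REF/HET/HOM_ALT/MISSING).  The HET and the two
homozygote states are the "pseudo-alleles" that all downstream homogeneity
statistics operate on: at a biallelic SNP an unphased diploid has one of
at most three distinguishable genotype states, so haplotype-style scans
can run on genotype identity instead of phased haplotypes.

Coordinate conventions: VCF positions are 1-based and so are all internal
positions; BED input/output is 0-based half-open, converted at the I/O
boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# genotype codes (int8)
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_CODE_LABELS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


@dataclass(frozen=True)
class VariantSite:
    """One biallelic SNP: chromosome, 1-based position, ref and alt allele."""

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt allele must differ")


@dataclass(frozen=True)
class SiteFilterConfig:
    """Site-level filters applied at load time.

    Parameters
    ----------
    max_missing_fraction:
        Sites with a larger fraction of missing calls are dropped (default
        0.10).  Remaining missing calls are retained and handled
        per-statistic.
    keep_filters:
        VCF FILTER values accepted; records with any other value are
        dropped.  Default accepts PASS and ".".
    """

    max_missing_fraction: float = 0.10
    keep_filters: frozenset[str] = frozenset({"PASS", "."})


@dataclass(frozen=True)
class MultisiteGenotype:
    """One sample's ordered pseudo-allele states over a SNP window."""

    sample: str
    states: np.ndarray  # int8 codes, length == window size


class GenotypeMatrix:
    """Unphased diploid genotype calls for n samples at m biallelic SNPs.

    ``calls`` is an (n_samples, n_sites) int8 array of genotype codes.
    Sites are sorted by (chromosome, position) with no duplicates;
    chromosome order is the order of first appearance in the input.
    """

    def __init__(
        self,
        samples: Sequence[str],
        chromosomes: np.ndarray,
        positions: np.ndarray,
        ref_alleles: np.ndarray,
        alt_alleles: np.ndarray,
        calls: np.ndarray,
    ) -> None:
        self.samples = list(samples)
        self.chromosomes = np.asarray(chromosomes, dtype=object)
        self.positions = np.asarray(positions, dtype=np.int64)
        self.ref_alleles = np.asarray(ref_alleles, dtype=object)
        self.alt_alleles = np.asarray(alt_alleles, dtype=object)
        self.calls = np.asarray(calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.positions)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.positions)} sites"
            )
        for arr in (self.chromosomes, self.ref_alleles, self.alt_alleles):
            if len(arr) != len(self.positions):
                raise ValueError("site metadata arrays have inconsistent lengths")

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def sites(self) -> list[VariantSite]:
        return [
            VariantSite(c, int(p), r, a)
            for c, p, r, a in zip(
                self.chromosomes, self.positions, self.ref_alleles, self.alt_alleles
            )
        ]

    def chromosome_names(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chromosomes:
            seen.setdefault(c, None)
        return list(seen)

    def chromosome_slice(self, chromosome: str) -> slice:
        idx = np.flatnonzero(self.chromosomes == chromosome)
        if idx.size == 0:
            raise KeyError(f"chromosome {chromosome!r} not in matrix")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def by_chromosome(self) -> Iterator[tuple[str, "GenotypeMatrix"]]:
        for chrom in self.chromosome_names():
            yield chrom, self.subset_sites(self.chromosome_slice(chrom))

    def subset_sites(self, index) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.samples,
            self.chromosomes[index],
            self.positions[index],
            self.ref_alleles[index],
            self.alt_alleles[index],
            self.calls[:, index],
        )

    def subset_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        try:
            rows = [self.samples.index(s) for s in names]
        except ValueError as exc:
            raise KeyError(f"unknown sample in subset: {exc}") from exc
        return GenotypeMatrix(
            list(names),
            self.chromosomes,
            self.positions,
            self.ref_alleles,
            self.alt_alleles,
            self.calls[rows, :],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and np.array_equal(self.chromosomes, other.chromosomes)
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.ref_alleles, other.ref_alleles)
            and np.array_equal(self.alt_alleles, other.alt_alleles)
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix({self.n_samples} samples x {self.n_sites} sites, "
            f"{len(self.chromosome_names())} chromosome(s))"
        )

    # -- serialization -------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write a debugging TSV: one row per sample, one column per site."""
        with open(path, "w") as fh:
            header = ["sample"] + [
                f"{c}:{p}" for c, p in zip(self.chromosomes, self.positions)
            ]
            fh.write("\t".join(header) + "\n")
            for i, s in enumerate(self.samples):
                fh.write(
                    "\t".join([s] + [str(int(v)) for v in self.calls[i]]) + "\n"
                )


def _sort_and_check(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Sort sites by (chromosome-appearance-order, position); reject duplicates."""
    order_of = {c: i for i, c in enumerate(matrix.chromosome_names())}
    keys = np.array([order_of[c] for c in matrix.chromosomes], dtype=np.int64)
    order = np.lexsort((matrix.positions, keys))
    m = matrix.subset_sites(order)
    same_chrom = m.chromosomes[1:] == m.chromosomes[:-1]
    same_pos = m.positions[1:] == m.positions[:-1]
    if np.any(same_chrom & same_pos):
        raise ValueError("duplicate sites (same chromosome and position)")
    return m


def apply_site_filters(
    matrix: GenotypeMatrix, filters: SiteFilterConfig
) -> GenotypeMatrix:
    """Drop sites whose missing-call fraction exceeds the configured ceiling.

    Idempotent: a matrix that already satisfies the ceiling is returned
    unchanged (same object content).
    """
    miss_frac = (matrix.calls == MISSING).mean(axis=0)
    keep = miss_frac <= filters.max_missing_fraction
    if keep.all():
        return matrix
    return matrix.subset_sites(np.flatnonzero(keep))


def read_vcf(
    path: str | Path,
    sample_subset: Sequence[str] | None = None,
    filters: SiteFilterConfig | None = None,
) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF into a :class:`GenotypeMatrix`.

    Indels, multiallelic records and records whose FILTER value is not in
    ``filters.keep_filters`` are dropped; sites whose missing-call fraction
    exceeds ``filters.max_missing_fraction`` (computed over the retained
    samples) are dropped.

    Raises
    ------
    FileNotFoundError / OSError
        if the file cannot be read.
    KeyError
        if ``sample_subset`` contains a sample not present in the VCF.
    ValueError
        if zero sites remain after filtering.
    """
    from cyvcf2 import VCF

    filters = filters or SiteFilterConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    vcf = VCF(str(path))
    all_samples = list(vcf.samples)
    if sample_subset is not None:
        unknown = [s for s in sample_subset if s not in all_samples]
        if unknown:
            raise KeyError(f"samples not present in VCF: {unknown}")
        vcf.set_samples(list(sample_subset))
        samples = list(vcf.samples)
    else:
        samples = all_samples

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    cols: list[np.ndarray] = []
    n_dropped = {"non_snp": 0, "multiallelic": 0, "filter": 0, "missing": 0}
    bases = {"A", "C", "G", "T"}
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_dropped["multiallelic"] += 1
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in bases or alt not in bases:
            n_dropped["non_snp"] += 1
            continue
        filt = rec.FILTER  # None for PASS/'.' under cyvcf2
        filt_label = "PASS" if filt is None else filt
        if filt_label not in filters.keep_filters and not (
            filt is None and "." in filters.keep_filters
        ):
            n_dropped["filter"] += 1
            continue
        # gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        gt = rec.gt_types
        col = np.full(len(samples), MISSING, dtype=np.int8)
        col[gt == 0] = HOM_REF
        col[gt == 1] = HET
        col[gt == 3] = HOM_ALT
        if (col == MISSING).mean() > filters.max_missing_fraction:
            n_dropped["missing"] += 1
            continue
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(ref)
        alts.append(alt)
        cols.append(col)
    vcf.close()
    if not cols:
        raise ValueError(
            f"zero sites retained from {path} after filtering (dropped: {n_dropped})"
        )
    if any(n_dropped.values()):
        logger.info("read_vcf %s: dropped %s", path.name, n_dropped)
    matrix = GenotypeMatrix(
        samples,
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(refs, dtype=object),
        np.array(alts, dtype=object),
        np.stack(cols, axis=1),
    )
    return _sort_and_check(matrix)


def window_genotypes(
    matrix: GenotypeMatrix, focal_index: int, window_snps: int
) -> list[MultisiteGenotype] | None:
    """Multisite genotypes over ``window_snps`` SNPs centered on a focal SNP.

    The window must lie entirely on the focal SNP's chromosome.  Returns
    ``None`` when the focal SNP is closer than ``(window_snps - 1) // 2``
    SNPs to either chromosome end — the caller records "no score here".
    """
    if window_snps % 2 != 1 or window_snps < 1:
        raise ValueError(f"window_snps must be a positive odd integer, got {window_snps}")
    if not 0 <= focal_index < matrix.n_sites:
        raise IndexError(f"focal index {focal_index} out of range")
    half = (window_snps - 1) // 2
    chrom = matrix.chromosomes[focal_index]
    sl = matrix.chromosome_slice(chrom)
    if focal_index - half < sl.start or focal_index + half >= sl.stop:
        return None
    states = matrix.calls[:, focal_index - half : focal_index + half + 1]
    return [
        MultisiteGenotype(sample=s, states=states[i].copy())
        for i, s in enumerate(matrix.samples)
    ]


def nucleotide_diversity(
    matrix: GenotypeMatrix, callable_sites: int | None = None
) -> float:
    """Nucleotide diversity from per-SNP unbiased expected heterozygosity.

    Per SNP the estimator is ``2 p (1 - p) * 2 n_c / (2 n_c - 1)`` with *p*
    the alternate-allele frequency over the ``2 n_c`` non-missing chromosomes
    at that site.  The per-SNP values are summed and divided by
    ``callable_sites``; when ``callable_sites`` is omitted the divisor is the
    SNP count and the result is a variant-sites-only diversity (flagged in
    the log), which is not comparable to genome-wide estimates.
    """
    if matrix.n_sites == 0:
        raise ValueError("empty matrix")
    if callable_sites is not None and callable_sites < matrix.n_sites:
        raise ValueError(
            f"callable_sites ({callable_sites}) < number of SNPs ({matrix.n_sites})"
        )
    calls = matrix.calls
    non_missing = (calls != MISSING).sum(axis=0)  # diploids with a call, n_c
    if np.any(non_missing == 0):
        raise ValueError("site with zero non-missing calls")
    alt_count = np.where(calls == HET, 1, 0).sum(axis=0) + 2 * np.where(
        calls == HOM_ALT, 1, 0
    ).sum(axis=0)
    n_chrom = 2 * non_missing
    p = alt_count / n_chrom
    with np.errstate(invalid="ignore"):
        per_site = 2.0 * p * (1.0 - p) * n_chrom / (n_chrom - 1)
    per_site = np.where(n_chrom > 1, per_site, 0.0)
    total = float(per_site.sum())
    if callable_sites is None:
        logger.info("nucleotide_diversity: variant-sites-only denominator (%d SNPs)",
                    matrix.n_sites)
        return total / matrix.n_sites
    return total / callable_sites
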