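"""Synthetic diploid genotype cohorts with linkage structure and sweeps.

Haplotypes are generated by a founder-copying mosaic (a Li–Stephens-style
model): each of the 2n haplotypes starts from a random founder out of a
pool of K founder haplotypes and, at each successive SNP, switches to a
uniformly chosen founder with a small per-SNP probability.  Small K and a
low switch rate produce the long shared haplotype blocks that the scan
statistics rely on, without a full coalescent-with-recombination
simulator.

Selective sweeps are injected by segment replacement: a chosen fraction
of haplotypes has its states over a span of SNPs overwritten with one
(hard sweep) or several (soft sweep) novel founder segments, giving an
exact, seed-stable truth table for recovery tests.

Two-population cohorts share one founder pool; each population redraws
its founder-choice weights from a Dirichlet whose concentration is
inversely proportional to a drift parameter, so larger drift means more
divergent founder usage and a higher baseline Fst.

Default parameters describe the cohort the scans were designed around:
29 diploid individuals, 10,000 SNPs per chromosome, K = 40 founders,
switch probability 0.02 per SNP, mean inter-SNP spacing 144 bp (so a
201-SNP window spans about 29 kb), founder allele frequencies from a
Beta(0.5, 0.5) with at least one copy of the minor allele in the pool.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from sweepscan.genotype_io import GenotypeMatrix, MISSING

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SweepSpec:
    """One injected sweep.

    ``n_sweep_haplotypes`` = 1 gives a hard sweep (one long haplotype at
    the carrier frequency); >= 2 gives a soft sweep (the carriers are
    split over that many distinct sweeping segments).
    """

    chromosome: str
    center_index: int  # SNP index within the chromosome
    span_snps: int
    carrier_frequency: float  # fraction of haplotypes carrying a sweep segment
    n_sweep_haplotypes: int = 1
    population: int = 0  # which population carries the sweep (two-pop runs)
    whole_individuals: bool = False  # pick carriers as individuals (homozygous)

    def __post_init__(self) -> None:
        if not 0 < self.carrier_frequency <= 1:
            raise ValueError("carrier_frequency must be in (0, 1]")
        if self.n_sweep_haplotypes < 1:
            raise ValueError("n_sweep_haplotypes must be >= 1")
        if self.span_snps < 1:
            raise ValueError("span_snps must be >= 1")


@dataclass(frozen=True)
class TwoPopConfig:
    """Split into two populations copying from a shared founder pool.

    ``drift`` controls how far each population's founder-usage weights
    wander from uniform (Dirichlet concentration 1/drift per founder);
    drift -> 0 makes the populations statistically identical.
    ``n_individuals_b`` defaults to the first population's size.
    """

    drift: float = 0.2
    n_individuals_b: int | None = None

    def __post_init__(self) -> None:
        if self.drift < 0:
            raise ValueError("drift must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    n_individuals: int = 29
    n_snps: int = 10_000
    n_chromosomes: int = 1
    founder_pool_size: int = 40
    switch_probability: float = 0.02
    allele_beta: tuple[float, float] = (0.5, 0.5)
    mean_spacing_bp: float = 144.0
    sweeps: tuple[SweepSpec, ...] = ()
    two_pop: TwoPopConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_individuals, self.n_snps, self.n_chromosomes,
               self.founder_pool_size) < 1:
            raise ValueError("all counts must be positive")
        if not 0 <= self.switch_probability <= 1:
            raise ValueError("switch_probability must be in [0, 1]")
        if self.mean_spacing_bp <= 0:
            raise ValueError("mean_spacing_bp must be positive")

    def chromosome_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class SimulatedCohort:
    """One or two genotype matrices plus the exact truth of injected sweeps."""

    config: SimulationConfig
    matrices: list[GenotypeMatrix]
    truth: list[dict] = field(default_factory=list)
    # internal haplotype store: per population, dict chrom -> (2n, L) int8
    haplotypes: list[dict] = field(default_factory=list)
    positions: dict = field(default_factory=dict)

    @property
    def matrix(self) -> GenotypeMatrix:
        return self.matrices[0]

    def truth_to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config": _config_dict(self.config), "sweeps": self.truth},
                fh, indent=2, default=str,
            )


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["sweeps"] = [asdict(s) for s in config.sweeps]
    return d


def _founder_pool(
    rng: np.random.Generator, config: SimulationConfig, length: int
) -> np.ndarray:
    """K founder haplotypes; every SNP polymorphic within the pool."""
    k = config.founder_pool_size
    a, b = config.allele_beta
    freqs = rng.beta(a, b, size=length)
    founders = (rng.random((k, length)) < freqs).astype(np.int8)
    if k >= 2:
        # enforce minor-allele count >= 1 in the pool by flipping one
        # uniformly chosen founder at monomorphic sites
        colsum = founders.sum(axis=0)
        mono = np.flatnonzero((colsum == 0) | (colsum == k))
        rows = rng.integers(0, k, size=mono.size)
        founders[rows, mono] = 1 - founders[rows, mono]
    return founders


def _mosaic_haplotypes(
    rng: np.random.Generator,
    founders: np.ndarray,
    n_haplotypes: int,
    switch_probability: float,
    founder_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Copy haplotypes from the founder pool with per-SNP switching."""
    k, length = founders.shape
    if founder_weights is None:
        founder_weights = np.full(k, 1.0 / k)
    # founder index path per haplotype, vectorized over SNPs
    switches = rng.random((n_haplotypes, length)) < switch_probability
    switches[:, 0] = True  # initial founder choice
    choices = rng.choice(k, size=(n_haplotypes, length), p=founder_weights)
    # forward-fill founder indices between switch points
    idx = np.where(switches, np.arange(length), 0)
    idx = np.maximum.accumulate(idx, axis=1)
    paths = choices[np.arange(n_haplotypes)[:, None], idx]
    return founders[paths, np.arange(length)[None, :]].astype(np.int8)


def _positions(rng: np.random.Generator, config: SimulationConfig, length: int) -> np.ndarray:
    gaps = np.maximum(
        1, np.round(rng.exponential(config.mean_spacing_bp, size=length)).astype(np.int64)
    )
    return np.cumsum(gaps)


def _genotypes(haplotypes: np.ndarray) -> np.ndarray:
    """Unphased genotype codes from the two haplotypes of each individual."""
    return (haplotypes[0::2] + haplotypes[1::2]).astype(np.int8)


def _build_matrix(
    samples: list[str],
    chrom_names: list[str],
    positions: dict,
    genotype_blocks: dict,
) -> GenotypeMatrix:
    chroms = np.concatenate(
        [np.repeat(c, len(positions[c])) for c in chrom_names]
    ).astype(object)
    pos = np.concatenate([positions[c] for c in chrom_names])
    n_sites = len(pos)
    ref = np.full(n_sites, "A", dtype=object)
    alt = np.full(n_sites, "G", dtype=object)
    calls = np.concatenate([genotype_blocks[c] for c in chrom_names], axis=1)
    return GenotypeMatrix(samples, chroms, pos, ref, alt, calls)


def simulate_neutral(config: SimulationConfig) -> SimulatedCohort:
    """A single-population founder-mosaic cohort (sweeps injected after).

    Bit-identical for identical (config, seed).  Sweeps listed in the
    config are injected via :func:`inject_sweep`.
    """
    rng = np.random.default_rng(config.seed)
    chrom_names = config.chromosome_names()
    samples = [f"ind{i + 1}" for i in range(config.n_individuals)]
    n_hap = 2 * config.n_individuals
    haps: dict[str, np.ndarray] = {}
    positions: dict[str, np.ndarray] = {}
    for chrom in chrom_names:
        founders = _founder_pool(rng, config, config.n_snps)
        haps[chrom] = _mosaic_haplotypes(
            rng, founders, n_hap, config.switch_probability
        )
        positions[chrom] = _positions(rng, config, config.n_snps)
    cohort = SimulatedCohort(
        config=config,
        matrices=[
            _build_matrix(
                samples, chrom_names, positions,
                {c: _genotypes(haps[c]) for c in chrom_names},
            )
        ],
        haplotypes=[haps],
        positions=positions,
    )
    for sweep in config.sweeps:
        inject_sweep(cohort, sweep, rng=rng)
    return cohort


def inject_sweep(
    cohort: SimulatedCohort,
    sweep: SweepSpec,
    rng: np.random.Generator | None = None,
) -> SimulatedCohort:
    """Overwrite a span of haplotypes with sweep segments, in place.

    Selects ``ceil(carrier_frequency * 2n)`` haplotypes of the target
    population at random, partitions them round-robin over
    ``n_sweep_haplotypes`` novel founder segments, and replaces their
    states across the span.  The truth table records the span and the
    carrier haplotype indices.
    """
    if rng is None:
        rng = np.random.default_rng(cohort.config.seed + 1)
    pop = sweep.population
    if pop >= len(cohort.haplotypes):
        raise ValueError(f"population {pop} not present in cohort")
    haps = cohort.haplotypes[pop].get(sweep.chromosome)
    if haps is None:
        raise ValueError(f"chromosome {sweep.chromosome!r} not simulated")
    n_hap, length = haps.shape
    half = sweep.span_snps // 2
    lo = sweep.center_index - half
    hi = lo + sweep.span_snps
    if lo < 0 or hi > length:
        raise ValueError("sweep span exceeds chromosome")
    if sweep.whole_individuals:
        # homozygous carriers: both haplotypes of each chosen individual,
        # so the carrier fraction of *individuals* is carrier_frequency
        n_ind = int(np.ceil(sweep.carrier_frequency * n_hap / 2))
        chosen = rng.choice(n_hap // 2, size=n_ind, replace=False)
        carriers = np.concatenate([2 * chosen, 2 * chosen + 1])
    else:
        n_carriers = int(np.ceil(sweep.carrier_frequency * n_hap))
        carriers = rng.choice(n_hap, size=n_carriers, replace=False)
    if len(carriers) < sweep.n_sweep_haplotypes:
        raise ValueError("carrier_frequency * 2n must be >= n_sweep_haplotypes")
    a, b = cohort.config.allele_beta
    freqs = rng.beta(a, b, size=sweep.span_snps)
    segments = (rng.random((sweep.n_sweep_haplotypes, sweep.span_snps)) < freqs).astype(
        np.int8
    )
    for i, h in enumerate(np.sort(carriers)):
        # whole-individual carriers get one segment per individual so both
        # haplotypes match; otherwise round-robin over haplotypes
        seg = (int(h) // 2 if sweep.whole_individuals else i) % sweep.n_sweep_haplotypes
        haps[h, lo:hi] = segments[seg]
    # rebuild the population's genotype matrix
    chrom_names = cohort.config.chromosome_names()
    samples = cohort.matrices[pop].samples
    cohort.matrices[pop] = _build_matrix(
        samples, chrom_names, cohort.positions,
        {c: _genotypes(cohort.haplotypes[pop][c]) for c in chrom_names},
    )
    pos = cohort.positions[sweep.chromosome]
    cohort.truth.append(
        {
            "chromosome": sweep.chromosome,
            "population": pop,
            "center_index": sweep.center_index,
            "center_position": int(pos[sweep.center_index]),
            "span_start_position": int(pos[lo]),
            "span_end_position": int(pos[hi - 1]),
            "span_snps": sweep.span_snps,
            "carrier_frequency": sweep.carrier_frequency,
            "n_sweep_haplotypes": sweep.n_sweep_haplotypes,
            "carrier_haplotypes": sorted(int(c) for c in carriers),
        }
    )
    return cohort


def simulate_two_pops(config: SimulationConfig) -> SimulatedCohort:
    """Two populations copying from a shared founder pool with drifted weights.

    Sweeps are injected into the population named by each spec's
    ``population`` field, so a post-split sweep in one population leaves
    the other untouched (locally elevated Fst); to emulate a shared
    pre-split sweep, list the same sweep for both populations.
    """
    if config.two_pop is None:
        raise ValueError("config.two_pop is not set")
    rng = np.random.default_rng(config.seed)
    chrom_names = config.chromosome_names()
    n_b = config.two_pop.n_individuals_b or config.n_individuals
    sizes = [config.n_individuals, n_b]
    samples = [
        [f"A{i + 1}" for i in range(sizes[0])],
        [f"B{i + 1}" for i in range(sizes[1])],
    ]
    k = config.founder_pool_size
    drift = config.two_pop.drift
    haps: list[dict[str, np.ndarray]] = [{}, {}]
    positions: dict[str, np.ndarray] = {}
    for chrom in chrom_names:
        founders = _founder_pool(rng, config, config.n_snps)
        positions[chrom] = _positions(rng, config, config.n_snps)
        for pop in (0, 1):
            if drift > 0:
                weights = rng.dirichlet(np.full(k, 1.0 / drift))
            else:
                weights = np.full(k, 1.0 / k)
            haps[pop][chrom] = _mosaic_haplotypes(
                rng, founders, 2 * sizes[pop], config.switch_probability, weights
            )
    cohort = SimulatedCohort(
        config=config,
        matrices=[
            _build_matrix(
                samples[pop], chrom_names, positions,
                {c: _genotypes(haps[pop][c]) for c in chrom_names},
            )
            for pop in (0, 1)
        ],
        haplotypes=haps,
        positions=positions,
    )
    for sweep in config.sweeps:
        inject_sweep(cohort, sweep, rng=rng)
    return cohort


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a GT-only VCF 4.2 for a genotype matrix."""
    code_to_gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in matrix.chromosome_names():
            sl = matrix.chromosome_slice(chrom)
            max_pos = int(matrix.positions[sl].max())
            fh.write(f"##contig=<ID={chrom},length={max_pos + 1000}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for j in range(matrix.n_sites):
            gts = "\t".join(code_to_gt[int(v)] for v in matrix.calls[:, j])
            fh.write(
                f"{matrix.chromosomes[j]}\t{matrix.positions[j]}\t.\t"
                f"{matrix.ref_alleles[j]}\t{matrix.alt_alleles[j]}\t.\tPASS\t.\tGT\t"
                f"{gts}\n"
            )


def make_gene_fixture(
    n_genes: int,
    genome_span: dict[str, int],
    cluster_spec: list[dict] | None = None,
    seed: int = 0,
    gene_length: int = 5_000,
    cds: bool = False,
):
    """Deterministic gene intervals (and optional CDS/FASTA) for testing.

    ``genome_span`` maps chromosome -> length in bp.  ``cluster_spec``
    entries like ``{"chromosome": "chr1", "start": 100000, "n": 3,
    "spacing_bp": 8000, "prefix": "CYP"}`` add tight gene clusters (for
    exercising enrichment masking).  With ``cds=True`` every gene gets a
    single full-length CDS (length trimmed to a multiple of 3) and a
    random reference sequence per chromosome is returned as well.

    Returns ``(genes, sequences)`` where sequences is a dict chromosome ->
    str (empty unless ``cds``).
    """
    from sweepscan.annotation import GeneRecord

    rng = np.random.default_rng(seed)
    genes: list[GeneRecord] = []
    chroms = sorted(genome_span)
    per_chrom = max(1, n_genes // max(1, len(chroms)))
    gid = 0
    for chrom in chroms:
        span = genome_span[chrom]
        n_here = per_chrom if chrom != chroms[-1] else n_genes - gid
        if n_here <= 0:
            continue
        starts = np.sort(
            rng.choice(
                max(1, span - gene_length), size=min(n_here, max(1, span // (2 * gene_length))),
                replace=False,
            )
        ) + 1
        # enforce non-identical starts spacing
        for s in starts:
            gid += 1
            start = int(s)
            end = min(start + gene_length - 1, span)
            length = end - start + 1
            cds_segs = ((start, start + (length - length % 3) - 1),) if cds else ()
            genes.append(
                GeneRecord(
                    gene_id=f"gene{gid:03d}",
                    chromosome=chrom,
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    cds_segments=cds_segs,
                )
            )
    for spec in cluster_spec or []:
        for i in range(spec["n"]):
            start = spec["start"] + i * spec["spacing_bp"]
            end = start + gene_length - 1
            length = end - start + 1
            cds_segs = ((start, start + (length - length % 3) - 1),) if cds else ()
            genes.append(
                GeneRecord(
                    gene_id=f"{spec.get('prefix', 'clu')}{i + 1}",
                    chromosome=spec["chromosome"],
                    start=start,
                    end=end,
                    strand="+",
                    cds_segments=cds_segs,
                )
            )
    genes.sort(key=lambda g: (g.chromosome, g.start, g.gene_id))
    sequences: dict[str, str] = {}
    if cds:
        bases = np.array(list("ACGT"))
        for chrom in chroms:
            sequences[chrom] = "".join(
                rng.choice(bases, size=genome_span[chrom])
            )
    return genes, sequences


def make_category_fixture(
    genes,
    n_categories: int,
    genes_per_category: int = 5,
    seed: int = 0,
    forced_assignments: dict[str, list[str]] | None = None,
):
    """Random gene -> GO-like category map, deterministic given seed.

    ``forced_assignments`` maps category_id -> explicit gene list (added
    verbatim, e.g. to give a paralog cluster a shared category).
    """
    from sweepscan.enrichment import CategoryMap

    rng = np.random.default_rng(seed)
    ids = [g.gene_id for g in genes]
    mapping: dict[str, set[str]] = {}
    for c in range(n_categories):
        size = min(genes_per_category, len(ids))
        members = rng.choice(ids, size=size, replace=False)
        mapping[f"GO:{c + 1:07d}"] = set(members.tolist())
    for cat, members in (forced_assignments or {}).items():
        mapping.setdefault(cat, set()).update(members)
    return CategoryMap(mapping)
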