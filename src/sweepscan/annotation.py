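"""Gene annotation of candidate loci: nearest genes, distance null, gene
scores, and per-gene coding-effect reports.

Distances are measured from a candidate's focal position to the nearest
gene boundary (0 inside the gene).  The permutation null for
candidate-to-gene distances redraws the same number of loci uniformly
among *scored focal positions* (candidates can only arise at scored
positions), re-imposing the same mask-radius spacing, and compares
distance distributions with a Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import stats

from sweepscan.genotype_io import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix
from sweepscan.outliers import CandidateLocus
from sweepscan.sweep_stats import ScoreTrack

logger = logging.getLogger(__name__)

DEFAULT_MAX_GENE_DISTANCE = 20_000


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval (1-based, inclusive) with optional CDS segments.

    ``cds_segments`` is an ordered tuple of (start, end) 1-based inclusive
    intervals in genomic coordinates; for minus-strand genes the coding
    order is the reverse of the genomic order and each segment is read
    reverse-complemented.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    cds_segments: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        last = None
        for s, e in self.cds_segments:
            if s > e or s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: bad CDS segment ({s}, {e})")
            if last is not None and s <= last:
                raise ValueError(f"gene {self.gene_id}: overlapping CDS segments")
            last = e

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)


@dataclass(frozen=True)
class GeneScore:
    gene_id: str
    max_statistic: float
    rank: int  # 1 = highest score


def read_genes(path: str | Path) -> list[GeneRecord]:
    """Read gene intervals from BED (0-based half-open) or GFF3.

    The format is chosen by extension (.bed vs .gff/.gff3).  For GFF3, one
    record per ``gene`` feature is returned, spanning the gene feature
    itself; CDS segments of all its transcripts are merged onto the gene.
    Output is sorted by (chromosome, start) and deduplicated by gene_id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".bed":
        genes = _read_bed(path)
    elif suffix in {".gff", ".gff3"}:
        genes = _read_gff3(path)
    else:
        raise ValueError(f"unrecognized annotation format: {path.name}")
    if not genes:
        raise ValueError(f"no genes parsed from {path}")
    seen: dict[str, GeneRecord] = {}
    for g in genes:
        seen.setdefault(g.gene_id, g)
    out = sorted(seen.values(), key=lambda g: (g.chromosome, g.start, g.gene_id))
    return out


def _read_bed(path: Path) -> list[GeneRecord]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 4 columns")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            strand = parts[5] if len(parts) >= 6 and parts[5] in {"+", "-"} else "+"
            genes.append(
                GeneRecord(
                    gene_id=parts[3],
                    chromosome=parts[0],
                    start=start0 + 1,  # BED is 0-based half-open
                    end=end0,
                    strand=strand,
                )
            )
    return genes


def _read_gff3(path: Path) -> list[GeneRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        cds = sorted(
            set(
                (c.start, c.end)
                for c in db.children(feat, featuretype="CDS")
            )
        )
        merged: list[tuple[int, int]] = []
        for s, e in cds:
            if merged and s <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        genes.append(
            GeneRecord(
                gene_id=feat.id,
                chromosome=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in {"+", "-"} else "+",
                cds_segments=tuple(merged),
            )
        )
    return genes


def write_genes_bed(genes: list[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chromosome}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def nearest_gene(
    locus: CandidateLocus | tuple[str, int], genes: list[GeneRecord]
) -> tuple[str | None, float]:
    """Single closest gene to a focal position; distance 0 inside the gene.

    The locus may be a :class:`CandidateLocus` or a (chromosome, position)
    pair.  Distance to a non-overlapping gene is the bp gap to its nearest
    boundary.  Ties are broken by the smaller gene start (then gene_id).
    Returns (None, inf) when no gene is on the locus's chromosome.
    """
    if isinstance(locus, CandidateLocus):
        chrom, pos = locus.chromosome, locus.focal_position
    else:
        chrom, pos = locus
    best: tuple[float, int, str] | None = None
    for g in genes:
        if g.chromosome != chrom:
            continue
        if g.start <= pos <= g.end:
            d = 0
        else:
            d = min(abs(pos - g.start), abs(pos - g.end))
        key = (d, g.start, g.gene_id)
        if best is None or key < best:
            best = key
    if best is None:
        return None, float("inf")
    return best[2], float(best[0])


def filter_by_gene_distance(
    candidates: list[CandidateLocus],
    genes: list[GeneRecord],
    max_distance: int = DEFAULT_MAX_GENE_DISTANCE,
) -> list[CandidateLocus]:
    """Keep candidates within ``max_distance`` bp (inclusive) of a gene.

    Each retained candidate carries its nearest gene and distance.
    """
    out = []
    for cand in candidates:
        gid, dist = nearest_gene(cand, genes)
        if gid is not None and dist <= max_distance:
            out.append(replace(cand, gene_id=gid, gene_distance=int(dist)))
    return out


def sample_spaced_positions(
    rng: np.random.Generator,
    positions_by_chrom: dict[str, np.ndarray],
    n: int,
    mask_radius_bp: int,
    scheme: str = "snp",
) -> list[tuple[str, int]]:
    """Draw n random loci, keeping the same-chromosome spacing constraint.

    ``scheme="snp"`` (default) draws uniformly among the scored focal
    positions — candidates can only arise at scored positions, so this is
    the matched null.  ``scheme="bp"`` draws positions uniformly in base
    pairs over each chromosome's scored span (chromosomes weighted by
    span).  Draws are accepted greedily while every accepted pair on a
    chromosome is more than ``mask_radius_bp`` apart — the spacing that
    candidate calling imposes.
    """
    if scheme not in {"snp", "bp"}:
        raise ValueError(f"unknown permutation scheme: {scheme!r}")
    if scheme == "snp":
        flat = [
            (chrom, int(p))
            for chrom, arr in sorted(positions_by_chrom.items())
            for p in arr
        ]
        candidates_iter = (flat[i] for i in rng.permutation(len(flat)))
        max_draws = len(flat)
    else:
        chroms = sorted(positions_by_chrom)
        spans = np.array(
            [
                max(1, int(positions_by_chrom[c].max() - positions_by_chrom[c].min()))
                for c in chroms
            ],
            dtype=np.float64,
        )
        weights = spans / spans.sum()
        max_draws = 200 * n

        def _bp_draws():
            for _ in range(max_draws):
                c = chroms[int(rng.choice(len(chroms), p=weights))]
                arr = positions_by_chrom[c]
                yield c, int(rng.integers(int(arr.min()), int(arr.max()) + 1))

        candidates_iter = _bp_draws()
    accepted: list[tuple[str, int]] = []
    taken: dict[str, list[int]] = {}
    for chrom, pos in candidates_iter:
        if all(abs(pos - q) > mask_radius_bp for q in taken.get(chrom, ())):
            accepted.append((chrom, pos))
            taken.setdefault(chrom, []).append(pos)
            if len(accepted) == n:
                return accepted
    raise ValueError(
        f"could not place {n} positions with spacing > {mask_radius_bp} bp"
    )


def distance_null_test(
    candidates: list[CandidateLocus],
    genes: list[GeneRecord],
    tracks: list[ScoreTrack],
    n_permutations: int = 100,
    seed: int | None = None,
    mask_radius_bp: int | None = None,
    scheme: str = "snp",
) -> dict:
    """Permutation null for candidate-to-gene distances.

    Each permutation resamples ``len(candidates)`` loci — uniformly
    without replacement among scored focal positions by default, or
    uniformly in base pairs with ``scheme="bp"`` — re-applying the
    mask-radius spacing, and records their nearest-gene distances.
    Observed distances are compared against the pooled permuted distances
    with a two-sided Wilcoxon rank-sum test (exact for small samples,
    normal approximation with continuity correction otherwise).

    Returns a dict with observed distances, pooled null distances, the
    p-value and the two medians.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if not candidates:
        raise ValueError("no candidates")
    if mask_radius_bp is None:
        radii = [
            (c.masked_end - c.masked_start) // 2 for c in candidates
        ]
        mask_radius_bp = max(radii)
    rng = np.random.default_rng(seed)
    positions_by_chrom = {t.chromosome: np.asarray(t.focal_positions) for t in tracks}
    observed = np.array(
        [nearest_gene(c, genes)[1] for c in candidates], dtype=np.float64
    )
    null: list[float] = []
    for _ in range(n_permutations):
        draws = sample_spaced_positions(
            rng, positions_by_chrom, len(candidates), mask_radius_bp,
            scheme=scheme,
        )
        null.extend(nearest_gene(d, genes)[1] for d in draws)
    null_arr = np.array(null, dtype=np.float64)
    method = "exact" if min(len(observed), len(null_arr)) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(
        observed, null_arr, alternative="two-sided", method=method,
        use_continuity=True,
    )
    return {
        "observed_distances": observed,
        "null_distances": null_arr,
        "p_value": float(res.pvalue),
        "observed_median": float(np.median(observed)),
        "null_median": float(np.median(null_arr)),
    }


def gene_scores(
    tracks: list[ScoreTrack], genes: list[GeneRecord]
) -> list[GeneScore]:
    """Score each gene by the maximal statistic among focal SNPs inside it.

    Genes containing no scored focal SNP are unscored and absent from the
    ranking.  Ranks are descending in score; ties break by gene_id.
    """
    by_chrom = {t.chromosome: t for t in tracks}
    scored: list[tuple[str, float]] = []
    for g in genes:
        t = by_chrom.get(g.chromosome)
        if t is None:
            continue
        lo = np.searchsorted(t.focal_positions, g.start, side="left")
        hi = np.searchsorted(t.focal_positions, g.end, side="right")
        if hi > lo:
            scored.append((g.gene_id, float(t.values[lo:hi].max())))
    if not scored:
        raise ValueError("no gene contains a scored focal SNP")
    scored.sort(key=lambda x: (-x[1], x[0]))
    return [
        GeneScore(gene_id=gid, max_statistic=val, rank=i + 1)
        for i, (gid, val) in enumerate(scored)
    ]


def gene_scores_to_tsv(scores: list[GeneScore], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tgene_id\tmax_statistic\n")
        for s in scores:
            fh.write(f"{s.rank}\t{s.gene_id}\t{s.max_statistic:.10g}\n")


_CODE_TO_GT = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}


def coding_effect_report(
    gene: GeneRecord,
    matrix: GenotypeMatrix,
    reference_sequence: str,
    reference_offset: int = 0,
) -> list[dict]:
    """Classify every SNP in a gene as intronic / synonymous / nonsynonymous.

    ``reference_sequence`` is the + strand reference covering the gene;
    ``reference_offset`` is the 1-based genomic position of its first base
    minus one (so genomic position p maps to ``reference_sequence[p - 1 -
    reference_offset]``).  SNPs outside all CDS segments are intronic; for
    CDS SNPs the reference codon and the alternate-substituted codon are
    translated (reverse-complemented on the minus strand, standard nuclear
    code) and compared.

    Returns one dict per SNP with position, alleles, classification, codon
    number (1-based in coding order), reference/alternate amino acids and
    per-sample genotype counts.  Raises on ref-allele mismatches with the
    reference sequence or a CDS length not divisible by 3.
    """
    from Bio.Seq import Seq

    if gene.cds_segments and gene.cds_length % 3 != 0:
        raise ValueError(
            f"gene {gene.gene_id}: CDS length {gene.cds_length} not divisible by 3"
        )

    def ref_base(pos: int) -> str:
        i = pos - 1 - reference_offset
        if i < 0 or i >= len(reference_sequence):
            raise ValueError(f"reference sequence does not cover position {pos}")
        return reference_sequence[i].upper()

    # coding positions in genomic order
    coding_pos = [
        p for s, e in gene.cds_segments for p in range(s, e + 1)
    ]
    # index in coding order: minus strand reads genomic-descending
    if gene.strand == "-":
        coding_order = {p: i for i, p in enumerate(reversed(coding_pos))}
    else:
        coding_order = {p: i for i, p in enumerate(coding_pos)}
    cds = "".join(ref_base(p) for p in coding_pos)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())

    in_gene = np.flatnonzero(
        (matrix.chromosomes == gene.chromosome)
        & (matrix.positions >= gene.start)
        & (matrix.positions <= gene.end)
    )
    report = []
    for i in in_gene:
        pos = int(matrix.positions[i])
        ref = str(matrix.ref_alleles[i]).upper()
        alt = str(matrix.alt_alleles[i]).upper()
        if ref_base(pos) != ref:
            raise ValueError(
                f"{gene.gene_id} pos {pos}: VCF ref {ref} != reference "
                f"sequence base {ref_base(pos)}"
            )
        col = matrix.calls[:, i]
        counts = {
            label: int((col == code).sum()) for code, label in _CODE_TO_GT.items()
        }
        entry = {
            "chromosome": gene.chromosome,
            "position": pos,
            "ref": ref,
            "alt": alt,
            "genotype_counts": counts,
        }
        if pos not in coding_order:
            entry.update(
                classification="intronic", codon_number=None,
                ref_aa=None, alt_aa=None,
            )
        else:
            ci = coding_order[pos]  # 0-based index into coding sequence
            codon_i = ci // 3
            within = ci % 3
            codon = cds[codon_i * 3 : codon_i * 3 + 3]
            if gene.strand == "-":
                alt_base = str(Seq(alt).reverse_complement())
            else:
                alt_base = alt
            alt_codon = codon[:within] + alt_base + codon[within + 1 :]
            ref_aa = str(Seq(codon).translate())
            alt_aa = str(Seq(alt_codon).translate())
            entry.update(
                classification=(
                    "synonymous" if ref_aa == alt_aa else "nonsynonymous"
                ),
                codon_number=codon_i + 1,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
            )
        report.append(entry)
    return report


def coding_report_to_tsv(report: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chromosome\tposition\tref\talt\tclassification\tcodon_number"
            "\tref_aa\talt_aa\n"
        )
        for r in report:
            fh.write(
                f"{r['chromosome']}\t{r['position']}\t{r['ref']}\t{r['alt']}"
                f"\t{r['classification']}\t{r['codon_number'] or 'NA'}"
                f"\t{r['ref_aa'] or 'NA'}\t{r['alt_aa'] or 'NA'}\n"
            )
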