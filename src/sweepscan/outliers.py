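"""Candidate-locus calling by iterative masking, and cross-track comparisons.

Top-scoring loci are called greedily: take the global maximum among
unmasked scored positions, emit it, mask everything within the mask radius
on its chromosome, repeat.  Masking prevents a single sweep from spawning
many linked candidates.  Ties in score are broken by genomic order
(canonical chromosome-name sort, then position) so the candidate list does
not depend on the order in which chromosome tracks are supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from sweepscan.sweep_stats import ScoreTrack

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 100
DEFAULT_MASK_RADIUS_BP = 100_000


@dataclass(frozen=True)
class CandidateLocus:
    """A top-scoring position with its masked neighbourhood.

    For the homogeneity statistics the position is a focal SNP; for
    windowed Fst it is the window midpoint.
    """

    rank: int
    chromosome: str
    focal_position: int
    score: float
    masked_start: int  # bp, inclusive
    masked_end: int  # bp, inclusive
    statistic_name: str
    gene_id: str | None = None
    gene_distance: int | None = None


def call_top_loci(
    tracks: list[ScoreTrack],
    k: int = DEFAULT_TOP_K,
    mask_radius_bp: int = DEFAULT_MASK_RADIUS_BP,
    mask_mode: str = "bp",
) -> list[CandidateLocus]:
    """Call up to ``k`` top-scoring loci with iterative masking.

    ``mask_mode="bp"`` masks ±``mask_radius_bp`` base pairs around each
    called locus; ``mask_mode="snps"`` masks ±``mask_radius_bp`` *scored
    positions* instead (the radius is then a count).  Fewer than ``k``
    candidates are returned, with a warning, if masking exhausts the
    genome.
    """
    if mask_radius_bp <= 0:
        raise ValueError("mask_radius_bp must be positive")
    if mask_mode not in {"bp", "snps"}:
        raise ValueError(f"unknown mask_mode: {mask_mode!r}")
    if not tracks or all(len(t) == 0 for t in tracks):
        raise ValueError("no scored positions")
    stat_names = {t.statistic_name for t in tracks}
    if len(stat_names) > 1:
        raise ValueError(f"mixed statistics in one call: {sorted(stat_names)}")
    chroms = np.concatenate([np.repeat(t.chromosome, len(t)) for t in tracks])
    pos = np.concatenate([t.focal_positions for t in tracks])
    val = np.concatenate([t.values for t in tracks])
    snp_idx = np.concatenate([np.arange(len(t)) for t in tracks])
    # deterministic global order: score desc, then canonical genomic order
    # (sorted chromosome names, then position), independent of supply order
    chrom_codes = np.unique(chroms.astype(str), return_inverse=True)[1]
    order = np.lexsort((pos, chrom_codes, -val))
    masked = np.zeros(len(pos), dtype=bool)
    candidates: list[CandidateLocus] = []
    for i in order:
        if len(candidates) >= k:
            break
        if masked[i]:
            continue
        same_chrom = chrom_codes == chrom_codes[i]
        if mask_mode == "bp":
            lo = int(pos[i]) - mask_radius_bp
            hi = int(pos[i]) + mask_radius_bp
            masked |= same_chrom & (pos >= lo) & (pos <= hi)
        else:
            lo_i = snp_idx[i] - mask_radius_bp
            hi_i = snp_idx[i] + mask_radius_bp
            masked |= same_chrom & (snp_idx >= lo_i) & (snp_idx <= hi_i)
            lo = int(pos[i]) - 1  # reported interval still in bp
            hi = int(pos[i]) + 1
        candidates.append(
            CandidateLocus(
                rank=len(candidates) + 1,
                chromosome=str(chroms[i]),
                focal_position=int(pos[i]),
                score=float(val[i]),
                masked_start=max(1, lo),
                masked_end=hi,
                statistic_name=next(iter(stat_names)),
            )
        )
    if len(candidates) < k:
        logger.warning(
            "call_top_loci: genome exhausted after %d of %d candidates",
            len(candidates), k,
        )
    return candidates


def candidates_to_tsv(candidates: list[CandidateLocus], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "rank\tchromosome\tposition\tscore\tstatistic\tmasked_start"
            "\tmasked_end\tgene_id\tgene_distance\n"
        )
        for c in candidates:
            fh.write(
                f"{c.rank}\t{c.chromosome}\t{c.focal_position}\t{c.score:.10g}"
                f"\t{c.statistic_name}\t{c.masked_start}\t{c.masked_end}"
                f"\t{c.gene_id or 'NA'}"
                f"\t{c.gene_distance if c.gene_distance is not None else 'NA'}\n"
            )


def candidates_to_bed(candidates: list[CandidateLocus], path) -> None:
    """Masked intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(
                f"{c.chromosome}\t{c.masked_start - 1}\t{c.masked_end}"
                f"\t{c.statistic_name}_rank{c.rank}\t{c.score:.10g}\n"
            )


def _genomewide_values(tracks: list[ScoreTrack]) -> np.ndarray:
    return np.concatenate([t.values for t in tracks])


def cross_percentile(
    candidates: list[CandidateLocus],
    other_tracks: list[ScoreTrack],
    tolerance_bp: int = 5_000,
) -> dict:
    """Empirical percentile of another statistic at candidate positions.

    For each candidate, the other track's value at the nearest scored
    position on the same chromosome (within ``tolerance_bp``) is ranked
    against that track's genome-wide distribution; returns the median
    percentile over matched candidates plus per-candidate detail.
    Unmatched candidates are counted and excluded.
    """
    all_values = np.sort(_genomewide_values(other_tracks))
    if all_values.size == 0:
        raise ValueError("other track has no scored positions")
    by_chrom = {t.chromosome: t for t in other_tracks}
    percentiles: list[float] = []
    detail = []
    n_unmatched = 0
    for cand in candidates:
        track = by_chrom.get(cand.chromosome)
        matched_value = None
        if track is not None and len(track) > 0:
            j = int(np.argmin(np.abs(track.focal_positions - cand.focal_position)))
            if abs(int(track.focal_positions[j]) - cand.focal_position) <= tolerance_bp:
                matched_value = float(track.values[j])
        if matched_value is None:
            n_unmatched += 1
            detail.append((cand.rank, None, None))
            continue
        # mean-rank percentile: average of <= and < ranks
        le = np.searchsorted(all_values, matched_value, side="right")
        lt = np.searchsorted(all_values, matched_value, side="left")
        pct = 100.0 * 0.5 * (le + lt) / all_values.size
        percentiles.append(pct)
        detail.append((cand.rank, matched_value, pct))
    if not percentiles:
        raise ValueError("no candidate matched a scored position in the other track")
    return {
        "median_percentile": float(np.median(percentiles)),
        "percentiles": percentiles,
        "n_matched": len(percentiles),
        "n_unmatched": n_unmatched,
        "per_candidate": detail,
    }


def track_correlation(
    tracks_a: list[ScoreTrack], tracks_b: list[ScoreTrack]
) -> tuple[float, float]:
    """Spearman rank correlation over positions scored in both track sets.

    Positions are matched exactly by (chromosome, position).  Returns
    (rho, p-value); raises if fewer than 10 positions overlap.
    """
    by_chrom_b = {t.chromosome: t for t in tracks_b}
    xs: list[float] = []
    ys: list[float] = []
    for ta in tracks_a:
        tb = by_chrom_b.get(ta.chromosome)
        if tb is None:
            continue
        common, ia, ib = np.intersect1d(
            ta.focal_positions, tb.focal_positions, return_indices=True
        )
        if common.size:
            xs.extend(ta.values[ia])
            ys.extend(tb.values[ib])
    if len(xs) < 10:
        raise ValueError(f"only {len(xs)} overlapping scored positions (need >= 10)")
    rho, p = stats.spearmanr(xs, ys)
    return float(rho), float(p)
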