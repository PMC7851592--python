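"""Candidate evaluation in a second population.

A sweep that started after two populations split leaves homogeneity in
the swept population only; a sweep shared from before the split leaves
elevated scores in both.  Comparing each candidate's statistic value in a
second cohort against that cohort's own genome-wide distribution
therefore reads on sweep timing: few candidates "elevated" in the second
population is consistent with post-split selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from sweepscan.genotype_io import GenotypeMatrix
from sweepscan.outliers import CandidateLocus
from sweepscan.sweep_stats import ScoreTrack

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_MATCH_TOLERANCE_BP = 5_000


@dataclass(frozen=True)
class LocusComparison:
    candidate: CandidateLocus
    matched_position: int
    stat_in_b: float
    percentile_in_b: float  # 0..100, against B's genome-wide track
    elevated: bool


def compare_candidates(
    candidates: list[CandidateLocus],
    tracks_b: list[ScoreTrack],
    alpha: float = DEFAULT_ALPHA,
    tolerance_bp: int = DEFAULT_MATCH_TOLERANCE_BP,
) -> tuple[list[LocusComparison], dict]:
    """Evaluate candidates against a second population's score tracks.

    Each candidate is matched to the nearest scored focal position in B on
    the same chromosome (within ``tolerance_bp``; A and B may segregate
    different SNPs).  The candidate is *elevated* in B when its matched
    value reaches B's genome-wide empirical (1 - alpha) quantile.
    Unmatched candidates are reported and excluded from the summary
    fraction's denominator.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    all_values = np.sort(np.concatenate([t.values for t in tracks_b]))
    if all_values.size == 0:
        raise ValueError("population B track has no scores")
    threshold = float(np.quantile(all_values, 1.0 - alpha))
    by_chrom = {t.chromosome: t for t in tracks_b}
    comparisons: list[LocusComparison] = []
    n_unmatched = 0
    for cand in candidates:
        track = by_chrom.get(cand.chromosome)
        if track is None or len(track) == 0:
            n_unmatched += 1
            continue
        j = int(np.argmin(np.abs(track.focal_positions - cand.focal_position)))
        matched_pos = int(track.focal_positions[j])
        if abs(matched_pos - cand.focal_position) > tolerance_bp:
            n_unmatched += 1
            continue
        value = float(track.values[j])
        le = np.searchsorted(all_values, value, side="right")
        lt = np.searchsorted(all_values, value, side="left")
        pct = 100.0 * 0.5 * (le + lt) / all_values.size
        comparisons.append(
            LocusComparison(
                candidate=cand,
                matched_position=matched_pos,
                stat_in_b=value,
                percentile_in_b=pct,
                elevated=value >= threshold,
            )
        )
    if n_unmatched:
        logger.info("compare_candidates: %d candidates unmatched in B", n_unmatched)
    n_elev = sum(c.elevated for c in comparisons)
    summary = {
        "n_candidates": len(candidates),
        "n_matched": len(comparisons),
        "n_unmatched": n_unmatched,
        "n_elevated": n_elev,
        "fraction_elevated": (n_elev / len(comparisons)) if comparisons else float("nan"),
        "alpha": alpha,
        "threshold": threshold,
    }
    return comparisons, summary


def comparisons_to_tsv(comparisons: list[LocusComparison], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "rank\tchromosome\tposition\tscore_a\tmatched_position_b\tscore_b"
            "\tpercentile_b\televated\n"
        )
        for c in comparisons:
            fh.write(
                f"{c.candidate.rank}\t{c.candidate.chromosome}"
                f"\t{c.candidate.focal_position}\t{c.candidate.score:.10g}"
                f"\t{c.matched_position}\t{c.stat_in_b:.10g}"
                f"\t{c.percentile_in_b:.4f}\t{int(c.elevated)}\n"
            )


def genotype_panel_export(
    matrix: GenotypeMatrix,
    chromosome: str,
    focal_position: int,
    window_snps: int,
    cluster: bool = True,
) -> pd.DataFrame:
    """Export one window's multisite genotypes as a sample x SNP table.

    The window of ``window_snps`` SNPs is centered on the scored SNP
    nearest ``focal_position`` on the chromosome.  With ``cluster=True``
    rows are ordered by identical-genotype class, largest class first
    (ties by first occurrence), which makes sweep structure visible in a
    heatmap; otherwise rows keep input sample order.  Cell values are the
    genotype codes (0 hom-ref, 1 het, 2 hom-alt, -1 missing).
    """
    if window_snps % 2 != 1 or window_snps < 1:
        raise ValueError("window_snps must be a positive odd integer")
    sl = matrix.chromosome_slice(chromosome)
    pos = matrix.positions[sl]
    focal_local = int(np.argmin(np.abs(pos - focal_position)))
    half = (window_snps - 1) // 2
    if focal_local - half < 0 or focal_local + half >= len(pos):
        raise ValueError("window extends past the chromosome end")
    lo = sl.start + focal_local - half
    hi = sl.start + focal_local + half + 1
    window = matrix.calls[:, lo:hi]
    order = np.arange(matrix.n_samples)
    if cluster:
        keys = [window[i].tobytes() for i in range(matrix.n_samples)]
        class_size: dict[bytes, int] = {}
        first_at: dict[bytes, int] = {}
        for i, k in enumerate(keys):
            class_size[k] = class_size.get(k, 0) + 1
            first_at.setdefault(k, i)
        order = np.array(
            sorted(
                range(matrix.n_samples),
                key=lambda i: (-class_size[keys[i]], first_at[keys[i]], i),
            )
        )
    df = pd.DataFrame(
        window[order],
        index=[matrix.samples[i] for i in order],
        columns=[int(p) for p in matrix.positions[lo:hi]],
    )
    df.index.name = "sample"
    return df
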