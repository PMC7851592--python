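"""Two-population Weir–Cockerham Fst per SNP and in sliding windows.

The per-SNP estimator is the diploid two-population theta of Weir &
Cockerham, computed from per-population non-missing sample sizes, allele
frequencies and observed heterozygote proportions.  Per-SNP values are
``a / (a + b + c)`` with *a* the among-population, *b* the
among-individual-within-population and *c* the within-individual variance
component; a site monomorphic in the pooled sample has ``a + b + c = 0``
and is undefined.

Window summaries are arithmetic means of the defined per-SNP ratios in
10-kb windows advancing by 1 kb ("mean per-SNP Fst"); a ratio-of-sums
variant (sum of *a* over sum of *a + b + c*) is available behind a flag.
Negative per-SNP estimates are retained in window means, as is standard —
truncating at zero would bias window means upward.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from sweepscan.genotype_io import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 10_000
DEFAULT_STEP_BP = 1_000
DEFAULT_MIN_SNPS = 5


def _pop_summaries(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n non-missing diploids, alt-allele freq, observed het prop)."""
    non_missing = (calls != MISSING).sum(axis=0).astype(np.float64)
    alt = ((calls == HET).sum(axis=0) + 2 * (calls == HOM_ALT).sum(axis=0)).astype(
        np.float64
    )
    het = (calls == HET).sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * non_missing)
        h = het / non_missing
    return non_missing, p, h


def _intersect_sites(
    pop_a: GenotypeMatrix, pop_b: GenotypeMatrix
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Match sites by (chromosome, position); reconcile or drop allele conflicts.

    Returns (index into A, index into B, flip mask) where flipped sites have
    ref/alt swapped in B relative to A; B's genotype codes are mirrored
    (HOM_REF <-> HOM_ALT) for those.  Sites with incompatible alleles are
    dropped with a logged count.
    """
    key_a = {
        (c, int(p)): i
        for i, (c, p) in enumerate(zip(pop_a.chromosomes, pop_a.positions))
    }
    ia: list[int] = []
    ib: list[int] = []
    flip: list[bool] = []
    n_conflict = 0
    for j, (c, p) in enumerate(zip(pop_b.chromosomes, pop_b.positions)):
        i = key_a.get((c, int(p)))
        if i is None:
            continue
        ra, aa = pop_a.ref_alleles[i], pop_a.alt_alleles[i]
        rb, ab = pop_b.ref_alleles[j], pop_b.alt_alleles[j]
        if (ra, aa) == (rb, ab):
            ia.append(i); ib.append(j); flip.append(False)
        elif (ra, aa) == (ab, rb):
            ia.append(i); ib.append(j); flip.append(True)
        else:
            n_conflict += 1
    if n_conflict:
        logger.warning("wc_fst_per_snp: dropped %d allele-conflict sites", n_conflict)
    if not ia:
        raise ValueError("empty site intersection between the two populations")
    return np.array(ia), np.array(ib), np.array(flip, dtype=bool)


def wc_fst_per_snp(pop_a: GenotypeMatrix, pop_b: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP Weir–Cockerham theta over the shared sites of two cohorts.

    Returns a DataFrame with columns ``chromosome, position, ref, alt,
    n_a, n_b, a, b, c, fst`` sorted by coordinate; ``fst`` is NaN where the
    pooled sample is monomorphic.  Symmetric in the two populations.
    """
    ia, ib, flip = _intersect_sites(pop_a, pop_b)
    calls_a = pop_a.calls[:, ia]
    calls_b = pop_b.calls[:, ib].copy()
    if flip.any():
        sub = calls_b[:, flip]
        mirrored = sub.copy()
        mirrored[sub == HOM_REF] = HOM_ALT
        mirrored[sub == HOM_ALT] = HOM_REF
        calls_b[:, flip] = mirrored

    n1, p1, h1 = _pop_summaries(calls_a)
    n2, p2, h2 = _pop_summaries(calls_b)
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
        denom = a + b + c
        fst = np.where(denom != 0.0, a / np.where(denom != 0.0, denom, 1.0), np.nan)
    df = pd.DataFrame(
        {
            "chromosome": pop_a.chromosomes[ia],
            "position": pop_a.positions[ia],
            "ref": pop_a.ref_alleles[ia],
            "alt": pop_a.alt_alleles[ia],
            "n_a": n1.astype(int),
            "n_b": n2.astype(int),
            "a": a,
            "b": b,
            "c": c,
            "fst": fst,
        }
    )
    order_of = {ch: i for i, ch in enumerate(pop_a.chromosome_names())}
    df = df.sort_values(
        by=["chromosome", "position"],
        key=lambda s: s.map(order_of) if s.name == "chromosome" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    return df


def fst_windows(
    snp_fst: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
    min_snps: int = DEFAULT_MIN_SNPS,
    ratio_of_sums: bool = False,
) -> pd.DataFrame:
    """Sliding-window mean of per-SNP Fst along each chromosome.

    Windows are half-open bp intervals ``[start, start + window_bp)``
    anchored at position 1 and advancing by ``step_bp``.  The default
    summary is the arithmetic mean of the defined per-SNP ratios; with
    ``ratio_of_sums=True`` it is sum(a)/sum(a+b+c) over the window's
    defined SNPs instead.  Windows with fewer than ``min_snps`` defined
    values are emitted with ``mean_fst`` NaN.

    Returns columns ``chromosome, window_start, window_end, n_snps,
    mean_fst`` (1-based inclusive-exclusive bp bounds).
    """
    if window_bp <= 0 or step_bp <= 0:
        raise ValueError("window_bp and step_bp must be positive")
    rows = []
    for chrom, grp in snp_fst.groupby("chromosome", sort=False):
        pos = grp["position"].to_numpy()
        val = grp["fst"].to_numpy()
        a = grp["a"].to_numpy()
        abc = (grp["a"] + grp["b"] + grp["c"]).to_numpy()
        defined = ~np.isnan(val)
        max_pos = int(pos.max())
        start = 1
        while start <= max_pos:
            end = start + window_bp
            in_win = (pos >= start) & (pos < end)
            sel = in_win & defined
            n = int(sel.sum())
            if n < min_snps:
                mean = np.nan
            elif ratio_of_sums:
                denom = abc[sel].sum()
                mean = a[sel].sum() / denom if denom != 0 else np.nan
            else:
                mean = float(val[sel].mean())
            rows.append((chrom, start, end, n, mean))
            start += step_bp
    return pd.DataFrame(
        rows, columns=["chromosome", "window_start", "window_end", "n_snps", "mean_fst"]
    )


def window_fst_to_tracks(windows: pd.DataFrame):
    """Defined window means as per-chromosome ScoreTracks at window midpoints."""
    from sweepscan.sweep_stats import ScoreTrack

    tracks = []
    for chrom, grp in windows.groupby("chromosome", sort=False):
        grp = grp[~grp["mean_fst"].isna()]
        if grp.empty:
            continue
        mid = ((grp["window_start"] + grp["window_end"] - 1) // 2).to_numpy()
        tracks.append(
            ScoreTrack(
                chromosome=chrom,
                focal_positions=mid,
                values=grp["mean_fst"].to_numpy(),
                statistic_name="Fst",
                parameters={},
            )
        )
    return tracks


def windows_to_bed(windows: pd.DataFrame, path: str | Path) -> None:
    """Write window means as BED-like TSV (0-based half-open coordinates)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tn_snps\tmean_fst\n")
        for row in windows.itertuples(index=False):
            mean = "NA" if pd.isna(row.mean_fst) else f"{row.mean_fst:.10g}"
            fh.write(
                f"{row.chromosome}\t{row.window_start - 1}\t{row.window_end - 1}"
                f"\t{row.n_snps}\t{mean}\n"
            )
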