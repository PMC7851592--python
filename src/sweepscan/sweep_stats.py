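"""Haplotype-homogeneity scan statistics on unphased genotypes: G12 and H.

Both statistics run on *multisite genotypes*: per individual, the unphased
genotype states (pseudo-alleles) over a stretch of biallelic SNPs.

G12 is the expected homozygosity of multisite genotypes in a symmetric
window of a fixed number of SNPs around a focal SNP, with the two most
frequent genotype classes pooled:

    G12 = (p1 + p2)^2 + p3^2 + ... + pk^2

where p1 >= p2 >= ... >= pk are the frequencies of the k distinct multisite
genotypes among the n samples.  Pooling the top two classes keeps the
statistic sensitive to soft sweeps, where more than one sweeping haplotype
reaches high frequency.

H at a focal SNP is the mean over all n(n-1)/2 sample pairs of the maximal
pseudo-allele identity tract containing the focal SNP, measured in SNPs; a
pair differing at the focal SNP contributes 0.

Missing genotype states never match anything, including another missing
state: missingness can only weaken a homogeneity signal, never create one.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from sweepscan.genotype_io import MISSING, GenotypeMatrix, MultisiteGenotype

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SNPS = 201


@dataclass
class ScoreTrack:
    """Per-focal-SNP statistic values along one chromosome."""

    chromosome: str
    focal_positions: np.ndarray  # bp, strictly increasing
    values: np.ndarray
    statistic_name: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.focal_positions = np.asarray(self.focal_positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.focal_positions.shape != self.values.shape:
            raise ValueError("positions and values have different lengths")
        if np.any(np.diff(self.focal_positions) <= 0):
            raise ValueError("focal positions must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scores must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self, path: str | Path, mode: str = "w") -> None:
        with open(path, mode) as fh:
            if mode == "w":
                fh.write(f"chromosome\tposition\t{self.statistic_name}\n")
            for p, v in zip(self.focal_positions, self.values):
                fh.write(f"{self.chromosome}\t{p}\t{v:.10g}\n")


def write_tracks_tsv(tracks: list[ScoreTrack], path: str | Path) -> None:
    """Write a set of single-chromosome tracks as one genome-wide TSV."""
    for i, t in enumerate(tracks):
        t.to_tsv(path, mode="w" if i == 0 else "a")


@dataclass(frozen=True)
class GenotypeClassSpectrum:
    """Counts of identical multisite genotypes in one window, descending."""

    class_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.class_counts:
            raise ValueError("empty spectrum")
        if list(self.class_counts) != sorted(self.class_counts, reverse=True):
            raise ValueError("class counts must be ranked descending")

    @property
    def n_samples(self) -> int:
        return int(sum(self.class_counts))

    @property
    def k(self) -> int:
        return len(self.class_counts)


def genotype_spectrum(
    window: list[MultisiteGenotype] | np.ndarray,
    missing_policy: str = "mismatch",
) -> GenotypeClassSpectrum:
    """Group samples into identical-multisite-genotype classes.

    Two samples fall in the same class iff their pseudo-allele states agree
    at every SNP of the window.  Under the default (and only) policy,
    ``"mismatch"``, a MISSING state matches nothing — not even another
    MISSING — so any sample with a missing call in the window is a
    singleton class.
    """
    if missing_policy != "mismatch":
        raise ValueError(f"unknown missing policy: {missing_policy!r}")
    if isinstance(window, np.ndarray):
        states = np.asarray(window, dtype=np.int8)
    else:
        if not window:
            raise ValueError("empty window")
        lengths = {len(g.states) for g in window}
        if len(lengths) != 1:
            raise ValueError(f"ragged window lengths: {sorted(lengths)}")
        states = np.stack([np.asarray(g.states, dtype=np.int8) for g in window])
    if states.ndim != 2 or states.shape[0] == 0:
        raise ValueError("window must be a non-empty 2-D sample x SNP array")
    has_missing = (states == MISSING).any(axis=1)
    counter: Counter[bytes] = Counter(
        states[i].tobytes() for i in np.flatnonzero(~has_missing)
    )
    counts = sorted(counter.values(), reverse=True)
    counts.extend([1] * int(has_missing.sum()))
    counts.sort(reverse=True)
    return GenotypeClassSpectrum(tuple(counts))


def g12(spectrum: GenotypeClassSpectrum) -> float:
    """G12 from a genotype-class spectrum: pool the top two classes.

    With p_i = count_i / n, returns (p1 + p2)^2 + sum_{i>=3} p_i^2; a
    single-class window gives 1.  Computed as an exact integer numerator
    over n^2 so that any per-window recomputation is bitwise identical.
    """
    if spectrum.k == 1:
        return 1.0
    c = spectrum.class_counts
    n = spectrum.n_samples
    numerator = (c[0] + c[1]) ** 2 + sum(x * x for x in c[2:])
    return numerator / (n * n)


def _g12_chromosome(calls: np.ndarray, window_snps: int) -> np.ndarray:
    """G12 at every eligible focal index of one chromosome.

    Uses per-sample byte strings of the whole chromosome so each window's
    genotype classes are counted from cheap byte-slices; a per-sample
    prefix sum of missing calls decides singleton status in O(1).  Matches
    the per-window definition exactly.
    """
    n, length = calls.shape
    half = (window_snps - 1) // 2
    n_focal = length - 2 * half
    if n_focal <= 0:
        return np.empty(0, dtype=np.float64)
    row_bytes = [calls[i].tobytes() for i in range(n)]
    missing_cum = np.zeros((n, length + 1), dtype=np.int32)
    np.cumsum(calls == MISSING, axis=1, out=missing_cum[:, 1:])
    out = np.empty(n_focal, dtype=np.float64)
    n2 = n * n
    for j in range(n_focal):
        lo, hi = j, j + window_snps
        counter: Counter[bytes] = Counter()
        n_singletons = 0
        for i in range(n):
            if missing_cum[i, hi] - missing_cum[i, lo] > 0:
                n_singletons += 1
            else:
                counter[row_bytes[i][lo:hi]] += 1
        counts = sorted(counter.values(), reverse=True)
        counts.extend([1] * n_singletons)
        counts.sort(reverse=True)
        if len(counts) == 1:
            out[j] = 1.0
        else:
            # exact integer numerator: bitwise-equal to any per-window
            # recomputation of the same formula
            numerator = (counts[0] + counts[1]) ** 2 + sum(
                x * x for x in counts[2:]
            )
            out[j] = numerator / n2
    return out


def g12_scan(
    matrix: GenotypeMatrix, window_snps: int = DEFAULT_WINDOW_SNPS
) -> list[ScoreTrack]:
    """G12 at every eligible focal SNP, one track per chromosome.

    Focal SNPs closer than ``(window_snps - 1) // 2`` SNPs to a chromosome
    end receive no score; chromosomes shorter than the window are skipped
    with a warning.
    """
    if window_snps % 2 != 1 or window_snps < 1:
        raise ValueError(f"window_snps must be a positive odd integer, got {window_snps}")
    half = (window_snps - 1) // 2
    tracks: list[ScoreTrack] = []
    for chrom, sub in matrix.by_chromosome():
        if sub.n_sites < window_snps:
            logger.warning(
                "g12_scan: chromosome %s has %d < %d SNPs; skipped",
                chrom, sub.n_sites, window_snps,
            )
            continue
        values = _g12_chromosome(sub.calls, window_snps)
        positions = sub.positions[half : sub.n_sites - half]
        tracks.append(
            ScoreTrack(
                chromosome=chrom,
                focal_positions=positions,
                values=values,
                statistic_name="G12",
                parameters={"window_snps": window_snps},
            )
        )
    return tracks


def pairwise_tract_length(
    a: np.ndarray, b: np.ndarray, focal_index: int
) -> int:
    """Maximal pseudo-allele identity tract (in SNPs) containing the focal SNP.

    Returns 0 when the two samples differ at the focal SNP or either state
    there is missing; otherwise the count of consecutive SNPs, extending
    maximally left and right from the focal SNP, at which the states are
    identical and non-missing.  Tracts truncate at chromosome ends.
    """
    a = np.asarray(a, dtype=np.int8)
    b = np.asarray(b, dtype=np.int8)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("state vectors must be 1-D and cover the same site list")
    if not 0 <= focal_index < len(a):
        raise IndexError(f"focal index {focal_index} out of range")
    mismatch = (a != b) | (a == MISSING) | (b == MISSING)
    if mismatch[focal_index]:
        return 0
    left = focal_index
    while left > 0 and not mismatch[left - 1]:
        left -= 1
    right = focal_index
    while right < len(a) - 1 and not mismatch[right + 1]:
        right += 1
    return right - left + 1


def _h_chromosome(calls: np.ndarray, pair_chunk: int = 128) -> np.ndarray:
    """H at every focal index of one chromosome (vectorized over pairs).

    For each pair the mismatch positions (state difference or missingness)
    are breakpoints; the tract at a focal SNP spans between the nearest
    breakpoints on either side, or is 0 at a breakpoint.
    """
    n, length = calls.shape
    if n < 2:
        raise ValueError("H requires at least 2 samples")
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    idx = np.arange(length, dtype=np.int64)
    total = np.zeros(length, dtype=np.float64)
    missing = calls == MISSING
    for start in range(0, len(pairs), pair_chunk):
        chunk = pairs[start : start + pair_chunk]
        ii = np.array([p[0] for p in chunk])
        jj = np.array([p[1] for p in chunk])
        mism = (calls[ii] != calls[jj]) | missing[ii] | missing[jj]
        # index of last breakpoint at or before each site (-1 if none)
        prev_bp = np.maximum.accumulate(np.where(mism, idx, -1), axis=1)
        # index of first breakpoint at or after each site (length if none)
        next_bp = np.minimum.accumulate(
            np.where(mism, idx, length)[:, ::-1], axis=1
        )[:, ::-1]
        h = np.where(mism, 0, next_bp - prev_bp - 1)
        total += h.sum(axis=0)
    return total / len(pairs)


def h_scan(matrix: GenotypeMatrix) -> list[ScoreTrack]:
    """H at every SNP, one track per chromosome.

    Unlike G12 there is no fixed window: tracts extend as far as identity
    holds and simply truncate at chromosome ends, so every SNP is scored.
    """
    if matrix.n_samples < 2:
        raise ValueError("h_scan requires at least 2 samples")
    tracks: list[ScoreTrack] = []
    for chrom, sub in matrix.by_chromosome():
        values = _h_chromosome(sub.calls)
        tracks.append(
            ScoreTrack(
                chromosome=chrom,
                focal_positions=sub.positions,
                values=values,
                statistic_name="H",
                parameters={},
            )
        )
    return tracks
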