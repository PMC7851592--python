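"""Naive reference implementations used as independent oracles.

Everything here is written directly from the statistic definitions as
straight-line Python, with no shared code paths with the package, so scan
outputs can be checked bitwise against a per-window recomputation.
"""

from __future__ import annotations

import numpy as np

MISSING = -1


def naive_spectrum(window: np.ndarray) -> list[int]:
    """Class counts, descending; a row with any missing call is a singleton."""
    counts: dict[tuple, int] = {}
    singletons = 0
    for row in window:
        if any(v == MISSING for v in row):
            singletons += 1
        else:
            key = tuple(int(v) for v in row)
            counts[key] = counts.get(key, 0) + 1
    return sorted(list(counts.values()) + [1] * singletons, reverse=True)


def naive_g12(window: np.ndarray) -> float:
    counts = naive_spectrum(window)
    if len(counts) == 1:
        return 1.0
    n = sum(counts)
    return ((counts[0] + counts[1]) ** 2 + sum(c * c for c in counts[2:])) / (n * n)


def naive_g12_scan(calls: np.ndarray, window_snps: int) -> np.ndarray:
    """G12 at every eligible focal index of one chromosome."""
    n, length = calls.shape
    half = (window_snps - 1) // 2
    out = []
    for focal in range(half, length - half):
        out.append(naive_g12(calls[:, focal - half : focal + half + 1]))
    return np.array(out)


def naive_tract(a: np.ndarray, b: np.ndarray, focal: int) -> int:
    ok = [
        (x != MISSING) and (y != MISSING) and (x == y)
        for x, y in zip(a.tolist(), b.tolist())
    ]
    if not ok[focal]:
        return 0
    length = 1
    i = focal - 1
    while i >= 0 and ok[i]:
        length += 1
        i -= 1
    i = focal + 1
    while i < len(ok) and ok[i]:
        length += 1
        i += 1
    return length


def naive_h_scan(calls: np.ndarray) -> np.ndarray:
    """H at every focal index of one chromosome."""
    n, length = calls.shape
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    out = np.zeros(length)
    for focal in range(length):
        out[focal] = sum(
            naive_tract(calls[i], calls[j], focal) for i, j in pairs
        ) / len(pairs)
    return out


def brute_force_top_loci(
    entries: list[tuple[str, int, float]], k: int, mask_radius_bp: int
) -> list[tuple[str, int, float]]:
    """Greedy loop written literally: repeat global-max-then-mask.

    ``entries`` are (chromosome, position, score); ties break by sorted
    chromosome name then position.
    """
    remaining = list(entries)
    out = []
    while remaining and len(out) < k:
        best = max(remaining, key=lambda e: (e[2], [-ord(c) for c in e[0]], -e[1]))
        # resolve ties explicitly: smallest (chrom, pos) among max scores
        best_score = max(e[2] for e in remaining)
        tied = [e for e in remaining if e[2] == best_score]
        best = min(tied, key=lambda e: (e[0], e[1]))
        out.append(best)
        remaining = [
            e
            for e in remaining
            if not (e[0] == best[0] and abs(e[1] - best[1]) <= mask_radius_bp)
        ]
    return out


def naive_nearest_gene(
    chrom: str, pos: int, genes: list
) -> tuple[str | None, float]:
    """Exhaustive scan over all gene intervals."""
    best = None
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


def naive_enrichment_discoveries(
    ranked_genes: list[str],
    gene_intervals: dict[str, tuple[str, int, int]],
    category_members: dict[str, set[str]],
    r_max: int,
    min_genes: int,
    mask_bp: int,
) -> list[tuple[str, int]]:
    """The discovery walk written as a literal restatement of the procedure."""
    surviving = list(ranked_genes)
    seen: list[str] = []
    discovered: list[tuple[str, int]] = []
    done: set[str] = set()
    i = 0
    while i < len(surviving) and i < r_max:
        g = surviving[i]
        i += 1
        seen.append(g)
        while True:
            cats = sorted(
                c
                for c, members in category_members.items()
                if c not in done
                and len([x for x in seen if x in members]) >= min_genes
            )
            if not cats:
                break
            c = cats[0]
            members = [x for x in seen if x in category_members[c]]
            contributing = members[:min_genes]
            done.add(c)
            discovered.append((c, i))
            regions = []
            for x in contributing:
                chrom, s, e = gene_intervals[x]
                regions.append((x, chrom, s - mask_bp, e + mask_bp))
            masked = set()
            for x in surviving:
                chrom, s, e = gene_intervals[x]
                for owner, rc, rs, re in regions:
                    if x != owner and chrom == rc and s <= re and e >= rs:
                        masked.add(x)
                        break
            if masked:
                removed_before = sum(1 for x in surviving[:i] if x in masked)
                surviving = [x for x in surviving if x not in masked]
                seen = [x for x in seen if x not in masked]
                i -= removed_before
    return discovered
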