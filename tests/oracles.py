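"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most direct method available —
exhaustive pairwise merging, bisection on the binding polynomial, quadratic
interval scans, per-base-pair expansion — deliberately sharing no code with
the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np

from xlquant.grouping import shared_peptide_fraction


def brute_force_partition(peptide_sets, threshold=0.30, rule="min_set"):
    """Grouping oracle: all-pairs fraction matrix + repeated merging to fixpoint.

    Returns a frozenset of frozensets of entry indices.
    """
    n = len(peptide_sets)
    linked = [
        [
            i != j and shared_peptide_fraction(peptide_sets[i], peptide_sets[j], rule) > threshold
            for j in range(n)
        ]
        for i in range(n)
    ]
    blocks = [{i} for i in range(n)]
    changed = True
    while changed:
        changed = False
        for a in range(len(blocks)):
            for b in range(a + 1, len(blocks)):
                if any(linked[i][j] for i in blocks[a] for j in blocks[b]):
                    blocks[a] |= blocks[b]
                    del blocks[b]
                    changed = True
                    break
            if changed:
                break
    return frozenset(frozenset(b) for b in blocks)


def theta_by_bisection(xt, mt, N, kd, tol=1e-14):
    """Bound-site fraction from the mass-action law Θ/(1−Θ) = Ka (Xt − N Mt Θ)."""
    ka = 1.0 / kd

    def g(theta):
        return theta / (1.0 - theta) - ka * (xt - N * mt * theta)

    lo, hi = 0.0, 1.0 - 1e-16
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if g(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return (lo + hi) / 2.0


def peak_overlaps_any(iv, intervals):
    """Quadratic-scan overlap predicate against raw (unmerged) intervals."""
    return any(o.chrom == iv.chrom and o.start < iv.end and o.end > iv.start for o in intervals)


def venn3_by_scan(a, b, c):
    """Anchor-perspective Venn counts via the quadratic per-peak scan."""
    sets = {a.name: a, b.name: b, c.name: c}
    names = [a.name, b.name, c.name]
    out = {}
    for i, n in enumerate(names):
        o1, o2 = names[(i + 1) % 3], names[(i + 2) % 3]
        counts = {"only": 0, f"with_{o1}": 0, f"with_{o2}": 0, "with_both": 0}
        for iv in sets[n].intervals:
            h1 = peak_overlaps_any(iv, sets[o1].intervals)
            h2 = peak_overlaps_any(iv, sets[o2].intervals)
            key = "with_both" if (h1 and h2) else f"with_{o1}" if h1 else f"with_{o2}" if h2 else "only"
            counts[key] += 1
        out[n] = counts
    return out


def tss_matrix_by_expansion(track, tss, flank, bin_size):
    """TSS matrix oracle: expand the track to one value per base pair, then
    average explicitly over each window bin (zero outside the chromosome)."""
    n_cols = 2 * flank // bin_size
    rows = []
    for chrom, pos, strand in tss:
        if chrom not in track.chrom_lengths:
            continue
        length = track.chrom_lengths[chrom]
        per_bp = np.repeat(track.values[chrom], track.bin_size)[:length]
        row = np.zeros(n_cols)
        for j in range(n_cols):
            acc = 0.0
            for p in range(pos - flank + j * bin_size, pos - flank + (j + 1) * bin_size):
                if 0 <= p < length:
                    acc += per_bp[p]
            row[j] = acc / bin_size
        if strand == "-":
            row = row[::-1]
        rows.append(row)
    return np.vstack(rows) if rows else np.zeros((0, n_cols))
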