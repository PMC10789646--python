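"""Peak-level colocalization summaries on already-called peak sets.

Operations mirror the usual ChIP-seq comparison toolkit: asymmetric
peak-overlap fractions, anchor-perspective three-set Venn classification,
TSS-anchored signal matrices (tornado-plot input) with high-to-low row
sorting, and genome-wide binned-signal correlation.  Coordinates are
0-based half-open throughout (BED convention); the overlap predicate is
any intersection of at least one base pair.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class GenomicInterval(NamedTuple):
    chrom: str
    start: int
    end: int
    strand: str = "."


def _check_interval(iv: GenomicInterval) -> None:
    if iv.start < 0 or iv.start >= iv.end:
        raise ValueError(f"invalid interval {iv}: need 0 <= start < end")
    if iv.strand not in ("+", "-", "."):
        raise ValueError(f"invalid strand {iv.strand!r}")


@dataclass
class PeakSet:
    name: str
    intervals: list[GenomicInterval]

    def __post_init__(self) -> None:
        for iv in self.intervals:
            _check_interval(iv)
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))

    def __len__(self) -> int:
        return len(self.intervals)

    def merged(self) -> "PeakSet":
        """Union of overlapping/adjacent-overlapping intervals within the set."""
        out: list[GenomicInterval] = []
        for iv in self.intervals:
            if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
                prev = out[-1]
                out[-1] = GenomicInterval(prev.chrom, prev.start, max(prev.end, iv.end), ".")
            else:
                out.append(GenomicInterval(iv.chrom, iv.start, iv.end, "."))
        return PeakSet(self.name, out)


class _MergedIndex:
    """Per-chromosome sorted merged intervals for O(log n) overlap queries."""

    def __init__(self, peaks: PeakSet) -> None:
        self.by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for iv in peaks.merged().intervals:
            starts, ends = self.by_chrom.setdefault(iv.chrom, ([], []))
            starts.append(iv.start)
            ends.append(iv.end)

    def overlaps(self, iv: GenomicInterval) -> bool:
        entry = self.by_chrom.get(iv.chrom)
        if entry is None:
            return False
        starts, ends = entry
        # candidate: last merged interval starting before iv.end
        k = bisect_right(starts, iv.end - 1) - 1
        return k >= 0 and ends[k] > iv.start


def overlap_fraction(anchor: PeakSet, other: PeakSet) -> float:
    """Fraction of anchor peaks intersecting (≥1 bp) the merged other set.

    Asymmetric by design: swap arguments for the other perspective.
    """
    if len(anchor) == 0:
        raise ValueError("overlap_fraction undefined for an empty anchor set")
    index = _MergedIndex(other)
    hits = sum(1 for iv in anchor.intervals if index.overlaps(iv))
    return hits / len(anchor)


def venn3(a: PeakSet, b: PeakSet, c: PeakSet) -> dict[str, dict[str, int]]:
    """Anchor-perspective three-set peak classification.

    Each peak of an anchor set is classified by whether it overlaps the
    merged forms of the other two sets, giving four region counts per
    anchor.  Peak-level Venn counts are anchor-dependent, so all three
    perspectives are reported.
    """
    sets = {a.name: a, b.name: b, c.name: c}
    if len(sets) != 3:
        raise ValueError("venn3 requires three distinctly named peak sets")
    names = [a.name, b.name, c.name]
    indexes = {n: _MergedIndex(s) for n, s in sets.items()}
    out: dict[str, dict[str, int]] = {}
    for i, n in enumerate(names):
        o1, o2 = names[(i + 1) % 3], names[(i + 2) % 3]
        counts = {"only": 0, f"with_{o1}": 0, f"with_{o2}": 0, "with_both": 0}
        for iv in sets[n].intervals:
            h1 = indexes[o1].overlaps(iv)
            h2 = indexes[o2].overlaps(iv)
            if h1 and h2:
                counts["with_both"] += 1
            elif h1:
                counts[f"with_{o1}"] += 1
            elif h2:
                counts[f"with_{o2}"] += 1
            else:
                counts["only"] += 1
        out[n] = counts
    return out


@dataclass
class SignalTrack:
    """Binned genome-wide signal: one value vector per chromosome."""

    name: str
    bin_size: int
    chrom_lengths: dict[str, int]
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, length in self.chrom_lengths.items():
            expect = -(-length // self.bin_size)  # ceil
            got = len(self.values.get(chrom, ()))
            if got != expect:
                raise ValueError(f"{chrom}: expected {expect} bins, got {got}")

    def concat(self, chrom_order: Sequence[str] | None = None) -> np.ndarray:
        order = list(chrom_order) if chrom_order else sorted(self.chrom_lengths)
        return np.concatenate([self.values[c] for c in order])


@dataclass
class TssMatrix:
    matrix: np.ndarray           # rows sorted by descending row mean
    row_order: np.ndarray        # permutation into the input TSS list
    edge_flags: np.ndarray       # rows whose window exceeded chromosome bounds
    n_dropped: int               # TSS on unknown chromosomes
    mean_profile: np.ndarray     # column means (line-graph data)


def tss_matrix(
    track: SignalTrack,
    tss: Sequence[tuple[str, int, str]],
    flank: int = 5000,
    bin_size: int = 50,
) -> TssMatrix:
    """Signal matrix over [pos − flank, pos + flank) around each TSS.

    Each row holds per-bin mean signal; minus-strand rows are reversed so
    column 0 is always 5′-most.  Out-of-bounds window parts are zero-padded
    and flagged; rows are sorted high-to-low by row mean (stable).
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    n_cols = 2 * flank // bin_size
    rows: list[np.ndarray] = []
    kept_idx: list[int] = []
    edge: list[bool] = []
    n_dropped = 0
    for idx, (chrom, pos, strand) in enumerate(tss):
        if chrom not in track.chrom_lengths:
            n_dropped += 1
            continue
        length = track.chrom_lengths[chrom]
        vals = track.values[chrom]
        row = np.zeros(n_cols)
        hit_edge = False
        for j in range(n_cols):
            b_start = pos - flank + j * bin_size
            b_end = b_start + bin_size
            if b_start < 0 or b_end > length:
                hit_edge = True
                b_start, b_end = max(b_start, 0), min(b_end, length)
                if b_start >= b_end:
                    continue  # fully outside: stays 0
            # mean over the full window bin; out-of-bounds parts count as 0
            first = b_start // track.bin_size
            last = (b_end - 1) // track.bin_size
            acc = 0.0
            for tb in range(first, last + 1):
                lo = max(b_start, tb * track.bin_size)
                hi = min(b_end, (tb + 1) * track.bin_size, length)
                acc += vals[tb] * (hi - lo)
            row[j] = acc / bin_size
        if strand == "-":
            row = row[::-1]
        rows.append(row)
        kept_idx.append(idx)
        edge.append(hit_edge)
    if n_dropped:
        warnings.warn(f"tss_matrix: dropped {n_dropped} TSS on unknown chromosomes")
    if rows:
        mat = np.vstack(rows)
        order = np.argsort(-mat.mean(axis=1), kind="stable")
        mat = mat[order]
        row_order = np.asarray(kept_idx)[order]
        edge_flags = np.asarray(edge)[order]
        profile = mat.mean(axis=0)
    else:
        mat = np.zeros((0, n_cols))
        row_order = np.zeros(0, dtype=int)
        edge_flags = np.zeros(0, dtype=bool)
        profile = np.zeros(n_cols)
    return TssMatrix(matrix=mat, row_order=row_order, edge_flags=edge_flags, n_dropped=n_dropped, mean_profile=profile)


def signal_correlation(tracks: Sequence[SignalTrack], method: str = "pearson") -> pd.DataFrame:
    """Pairwise correlation of genome-wide bin vectors; symmetric, unit diagonal."""
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    ref = tracks[0]
    for t in tracks[1:]:
        if t.bin_size != ref.bin_size or t.chrom_lengths != ref.chrom_lengths:
            raise ValueError("tracks must share binning and chromosome lengths")
    order = sorted(ref.chrom_lengths)
    vecs = {t.name: t.concat(order) for t in tracks}
    names = [t.name for t in tracks]
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, ni in enumerate(names):
        for j in range(i + 1, len(names)):
            nj = names[j]
            x, y = vecs[ni], vecs[nj]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(f"zero-variance track in pair ({ni}, {nj}); correlation undefined")
                r = np.nan
            elif method == "pearson":
                r = float(stats.pearsonr(x, y).statistic)
            else:
                r = float(stats.spearmanr(x, y).statistic)
            mat.at[ni, nj] = mat.at[nj, ni] = r
    return mat


# ---------------------------------------------------------------------------
# BED / bedGraph I/O

def read_bed(path: str | Path, name: str | None = None) -> PeakSet:
    """Read a BED3/BED6 file into a PeakSet (0-based half-open, as on disk)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    ivs = []
    for r in df.itertuples(index=False):
        strand = str(r[5]) if len(r) > 5 and str(r[5]) in ("+", "-") else "."
        ivs.append(GenomicInterval(str(r[0]), int(r[1]), int(r[2]), strand))
    return PeakSet(name or Path(path).stem, ivs)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(peaks.intervals):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{peaks.name}_{i + 1}\t0\t{iv.strand}\n")


def read_tss_bed(path: str | Path) -> list[tuple[str, int, str]]:
    """Read a BED6 TSS list; each interval's start is taken as the TSS position."""
    peaks = read_bed(path)
    return [(iv.chrom, iv.start, iv.strand) for iv in peaks.intervals]


def read_bedgraph(
    path: str | Path,
    chrom_lengths: dict[str, int],
    bin_size: int,
    name: str | None = None,
) -> SignalTrack:
    """Read a bedGraph into the fixed-bin representation (bin-mean resampling)."""
    values = {c: np.zeros(-(-l // bin_size)) for c, l in chrom_lengths.items()}
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    for r in df.itertuples(index=False):
        chrom, start, end, val = str(r[0]), int(r[1]), int(r[2]), float(r[3])
        if chrom not in values:
            continue
        end = min(end, chrom_lengths[chrom])
        for b in range(start // bin_size, -(-end // bin_size)):
            lo = max(start, b * bin_size)
            hi = min(end, (b + 1) * bin_size)
            width = min((b + 1) * bin_size, chrom_lengths[chrom]) - b * bin_size
            values[chrom][b] += val * (hi - lo) / width
    return SignalTrack(name or Path(path).stem, bin_size, dict(chrom_lengths), values)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.chrom_lengths):
            length = track.chrom_lengths[chrom]
            for b, v in enumerate(track.values[chrom]):
                start = b * track.bin_size
                end = min(start + track.bin_size, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{float(v)!r}\n")
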