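"""Shared-peptide protein grouping.

Two entries are linked when they share more than a threshold fraction of
their peptides (default >30%, fraction of the smaller set); groups are the
connected components of that sharing graph, so merging is transitive
(single linkage).  Member intensities are pooled by per-sample summation
and each group is represented by its highest-abundance member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .proteingroups import ProteinEntry

MIN_SET = "min_set"
JACCARD = "jaccard"


@dataclass(frozen=True)
class GroupingConfig:
    share_threshold: float = 0.30
    denominator_rule: str = MIN_SET
    # pool member intensities by summation; if False keep the representative's
    merge_intensities: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.share_threshold <= 1):
            raise ValueError("share_threshold must be in (0, 1]")
        if self.denominator_rule not in (MIN_SET, JACCARD):
            raise ValueError(f"unknown denominator_rule {self.denominator_rule!r}")


@dataclass
class MergedGroup:
    group_id: str
    member_entries: list[ProteinEntry]
    representative: str
    pooled_peptides: frozenset[str]
    pooled_intensities: dict[str, float]

    def total_intensity(self) -> float:
        return float(sum(self.pooled_intensities.values()))


def shared_peptide_fraction(a: frozenset[str], b: frozenset[str], rule: str = MIN_SET) -> float:
    """Fraction of peptides shared between two sets; symmetric in a, b."""
    if not a or not b:
        raise ValueError("shared_peptide_fraction undefined for empty peptide sets")
    inter = len(a & b)
    if rule == MIN_SET:
        return inter / min(len(a), len(b))
    if rule == JACCARD:
        return inter / len(a | b)
    raise ValueError(f"unknown denominator_rule {rule!r}")


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def group_proteins(entries: Sequence[ProteinEntry], cfg: GroupingConfig | None = None) -> list[MergedGroup]:
    """Partition entries into merged groups.

    An edge joins two entries iff their shared-peptide fraction strictly
    exceeds ``share_threshold``; groups are connected components.  Output is
    sorted by descending pooled total iBAQ (ties by representative
    accession) and every entry lands in exactly one group.
    """
    cfg = cfg or GroupingConfig()
    for e in entries:
        if not e.peptide_ids:
            raise ValueError(f"entry {e.representative} has an empty peptide set")

    uf = _UnionFind(len(entries))
    # inverted index: compare only entry pairs that share at least one peptide
    by_peptide: dict[str, list[int]] = {}
    for i, e in enumerate(entries):
        for p in e.peptide_ids:
            by_peptide.setdefault(p, []).append(i)
    candidate_pairs: set[tuple[int, int]] = set()
    for idxs in by_peptide.values():
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                candidate_pairs.add((idxs[a], idxs[b]))
    for i, j in candidate_pairs:
        frac = shared_peptide_fraction(entries[i].peptide_ids, entries[j].peptide_ids, cfg.denominator_rule)
        if frac > cfg.share_threshold:
            uf.union(i, j)

    components: dict[int, list[int]] = {}
    for i in range(len(entries)):
        components.setdefault(uf.find(i), []).append(i)

    groups: list[MergedGroup] = []
    for members_idx in components.values():
        members = [entries[i] for i in members_idx]
        # representative: largest summed iBAQ, ties lexicographic by accession
        rep = min(members, key=lambda e: (-e.total_intensity(), e.representative))
        pooled_pep = frozenset().union(*(e.peptide_ids for e in members))
        samples = {s for e in members for s in e.intensities}
        if cfg.merge_intensities:
            pooled_int = {s: float(sum(e.intensities.get(s, 0.0) for e in members)) for s in samples}
        else:
            pooled_int = {s: float(rep.intensities.get(s, 0.0)) for s in samples}
        groups.append(
            MergedGroup(
                group_id="",  # assigned after sorting
                member_entries=members,
                representative=rep.representative,
                pooled_peptides=pooled_pep,
                pooled_intensities=pooled_int,
            )
        )
    groups.sort(key=lambda g: (-g.total_intensity(), g.representative))
    for k, g in enumerate(groups, start=1):
        g.group_id = f"G{k:05d}"
    return groups


def groups_to_table(groups: Sequence[MergedGroup], sample_ids: Sequence[str]):
    """Tabular view of merged groups (group_id, representative, members, pooled iBAQ)."""
    import pandas as pd

    rows = []
    for g in groups:
        row = {
            "group_id": g.group_id,
            "representative": g.representative,
            "members": ";".join(e.representative for e in g.member_entries),
        }
        for s in sample_ids:
            row[f"iBAQ {s}"] = g.pooled_intensities.get(s, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
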