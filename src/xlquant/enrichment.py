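"""riBAQ normalization, ±UV fold enrichment and interactor classification.

riBAQ (relative iBAQ) is compositional: a group's iBAQ divided by the
summed iBAQ of the groups retained in that sample, so each sample column
sums to 1.  A group counts as *present* in a condition only when it is
detected (iBAQ > 0) in every replicate of that condition — the
both-replicates rule.  Groups present in exactly one condition and absent
from every replicate of the other are *exclusive* to that condition; groups
present in both are *common* and receive a fold enrichment
(mean riBAQ +UV / mean riBAQ −UV) and a two-sided t-test p-value, by
default Student's pooled-variance test on log2 riBAQ (Welch available).  Common groups pass the high-confidence
enrichment call at p ≤ 0.05 and fold change ≥ 2 (both configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grouping import MergedGroup
from .proteingroups import CONDITIONS, MINUS_UV, PLUS_UV, SampleDesign, check_design

EXCLUSIVE_PLUS = "exclusive_plus"
EXCLUSIVE_MINUS = "exclusive_minus"
COMMON_ENRICHED = "common_enriched"
COMMON_DEPLETED = "common_depleted"
COMMON_NS = "common_ns"
CATEGORIES = (EXCLUSIVE_PLUS, EXCLUSIVE_MINUS, COMMON_ENRICHED, COMMON_DEPLETED, COMMON_NS)
COMMON_CATEGORIES = (COMMON_ENRICHED, COMMON_DEPLETED, COMMON_NS)

WELCH = "welch"
STUDENT = "student"


@dataclass(frozen=True)
class EnrichmentConfig:
    p_threshold: float = 0.05
    fc_threshold: float = 2.0
    log_transform: bool = True
    # Student's pooled-variance t by default: with n = 2 replicates per
    # condition the Welch-Satterthwaite df estimate makes the test markedly
    # conservative (empirical size ~0.02 at nominal 0.05), costing power
    test: str = STUDENT
    # Benjamini-Hochberg adjustment of common-group p-values; off by default
    # (the classification rule operates on raw p-values)
    bh_correction: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if self.test not in (WELCH, STUDENT):
            raise ValueError(f"unknown test {self.test!r}")


@dataclass
class RibaqTable:
    """Per-sample riBAQ values for retained groups.

    ``values`` is a (group × sample) DataFrame indexed by group_id;
    ``presence`` records the both-replicates rule per (group_id, condition);
    riBAQ is 0 wherever a group is excluded from a condition.
    """

    values: pd.DataFrame
    presence: dict[tuple[str, str], bool]
    design: list[SampleDesign]

    def samples_of(self, condition: str) -> list[str]:
        return [d.sample_id for d in self.design if d.condition == condition]

    def present(self, group_id: str, condition: str) -> bool:
        return self.presence[(group_id, condition)]


@dataclass
class EnrichmentRecord:
    group_id: str
    representative: str
    mean_ribaq_plus: float
    mean_ribaq_minus: float
    fold_enrichment: float | None
    log2_fc: float | None
    p_value: float | None
    category: str


def compute_ribaq(groups: Sequence[MergedGroup], design: Sequence[SampleDesign]) -> RibaqTable:
    """Normalize pooled iBAQ to riBAQ under the both-replicates presence rule.

    Groups detected in every replicate of a condition are retained for that
    condition; groups present in neither condition are dropped entirely.
    Each sample column is normalized over the groups retained for that
    sample's condition and therefore sums to 1.
    """
    check_design(design, require_replicates=True)
    cond_samples = {c: [d.sample_id for d in design if d.condition == c] for c in CONDITIONS}

    presence: dict[tuple[str, str], bool] = {}
    retained: list[MergedGroup] = []
    for g in groups:
        pres = {
            c: all(g.pooled_intensities.get(s, 0.0) > 0 for s in cond_samples[c])
            for c in CONDITIONS
        }
        if not any(pres.values()):
            continue
        retained.append(g)
        for c in CONDITIONS:
            presence[(g.group_id, c)] = pres[c]

    if not retained:
        raise ValueError("no group is present in either condition")

    index = [g.group_id for g in retained]
    all_samples = [d.sample_id for d in design]
    vals = pd.DataFrame(0.0, index=index, columns=all_samples)
    for c in CONDITIONS:
        members = [g for g in retained if presence[(g.group_id, c)]]
        for s in cond_samples[c]:
            total = sum(g.pooled_intensities.get(s, 0.0) for g in members)
            if members and total <= 0:
                raise ValueError(f"degenerate sample {s!r}: retained-group intensity sum is 0")
            for g in members:
                vals.at[g.group_id, s] = g.pooled_intensities.get(s, 0.0) / total
    return RibaqTable(values=vals, presence=presence, design=list(design))


def condition_means(table: RibaqTable) -> pd.DataFrame:
    """Arithmetic mean riBAQ per group within each condition (0 where excluded)."""
    plus = table.values[table.samples_of(PLUS_UV)].mean(axis=1)
    minus = table.values[table.samples_of(MINUS_UV)].mean(axis=1)
    return pd.DataFrame({"mean_plus": plus, "mean_minus": minus})


def test_enrichment(
    plus_values: Sequence[float],
    minus_values: Sequence[float],
    cfg: EnrichmentConfig | None = None,
) -> tuple[float, float]:
    """Fold enrichment and two-sided t-test p-value for a common group.

    Fold enrichment is mean(plus)/mean(minus) on the linear scale; the test
    runs on log2-transformed riBAQ by default.  Both replicate vectors must
    be all-positive (exclusive groups are routed elsewhere).
    """
    cfg = cfg or EnrichmentConfig()
    plus = np.asarray(plus_values, dtype=float)
    minus = np.asarray(minus_values, dtype=float)
    if plus.size < 2 or minus.size < 2:
        raise ValueError("need >= 2 replicates per condition")
    if (plus <= 0).any() or (minus <= 0).any():
        raise ValueError("test_enrichment requires all-positive riBAQ values")
    fold = float(plus.mean() / minus.mean())
    a, b = (np.log2(plus), np.log2(minus)) if cfg.log_transform else (plus, minus)
    if np.allclose(a, b) and np.ptp(a) == 0 and np.ptp(b) == 0 and a.size == b.size:
        # identical constant vectors: t = 0 by symmetry, p = 1
        return fold, 1.0
    import warnings

    with warnings.catch_warnings():
        # near-constant vectors trigger a scipy precision warning; the
        # resulting nan/indeterminate p is handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=(cfg.test == STUDENT))
    p = float(res.pvalue)
    if math.isnan(p):  # zero pooled variance with unequal means cannot occur on real data
        p = 1.0
    return fold, min(p, 1.0)


def classify(
    groups: Sequence[MergedGroup],
    table: RibaqTable,
    cfg: EnrichmentConfig | None = None,
) -> list[EnrichmentRecord]:
    """Assign each retained group to the exclusive/common partition.

    exclusive_plus: present (both replicates) in +UV with zero iBAQ in every
    −UV replicate; exclusive_minus symmetric.  Groups present in both
    conditions are tested; a group present in one condition whose opposite
    replicates are only partially detected has no defined fold or p-value
    and is reported as common_ns.
    """
    cfg = cfg or EnrichmentConfig()
    by_id = {g.group_id: g for g in groups}
    plus_samples = table.samples_of(PLUS_UV)
    minus_samples = table.samples_of(MINUS_UV)
    means = condition_means(table)

    records: list[EnrichmentRecord] = []
    tested_idx: list[int] = []
    for gid in table.values.index:
        g = by_id[gid]
        pres_plus = table.present(gid, PLUS_UV)
        pres_minus = table.present(gid, MINUS_UV)
        zero_minus = all(g.pooled_intensities.get(s, 0.0) == 0 for s in minus_samples)
        zero_plus = all(g.pooled_intensities.get(s, 0.0) == 0 for s in plus_samples)
        rec = EnrichmentRecord(
            group_id=gid,
            representative=g.representative,
            mean_ribaq_plus=float(means.at[gid, "mean_plus"]),
            mean_ribaq_minus=float(means.at[gid, "mean_minus"]),
            fold_enrichment=None,
            log2_fc=None,
            p_value=None,
            category=COMMON_NS,
        )
        if pres_plus and zero_minus:
            rec.category = EXCLUSIVE_PLUS
        elif pres_minus and zero_plus:
            rec.category = EXCLUSIVE_MINUS
        elif pres_plus and pres_minus:
            fold, p = test_enrichment(
                table.values.loc[gid, plus_samples].to_numpy(),
                table.values.loc[gid, minus_samples].to_numpy(),
                cfg,
            )
            rec.fold_enrichment = fold
            rec.log2_fc = math.log2(fold)
            rec.p_value = p
            tested_idx.append(len(records))
        # else: detected in one condition, partially in the other -> common_ns
        records.append(rec)

    if cfg.bh_correction and tested_idx:
        raw = np.array([records[i].p_value for i in tested_idx])
        adj = _benjamini_hochberg(raw)
        for i, p in zip(tested_idx, adj):
            records[i].p_value = float(p)

    for i in tested_idx:
        rec = records[i]
        if rec.p_value <= cfg.p_threshold and rec.fold_enrichment >= cfg.fc_threshold:
            rec.category = COMMON_ENRICHED
        elif rec.p_value <= cfg.p_threshold and rec.fold_enrichment <= 1.0 / cfg.fc_threshold:
            rec.category = COMMON_DEPLETED
        else:
            rec.category = COMMON_NS
    return records


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def venn_counts(records: Sequence[EnrichmentRecord]) -> dict[str, int]:
    """Counts of the exclusive/common partition (the ±UV Venn summary)."""
    n_plus = sum(1 for r in records if r.category == EXCLUSIVE_PLUS)
    n_minus = sum(1 for r in records if r.category == EXCLUSIVE_MINUS)
    n_common = sum(1 for r in records if r.category in COMMON_CATEGORIES)
    n_enriched = sum(1 for r in records if r.category == COMMON_ENRICHED)
    return {
        "n_exclusive_plus": n_plus,
        "n_exclusive_minus": n_minus,
        "n_common": n_common,
        "n_common_enriched": n_enriched,
    }


def volcano_table(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """log2 fold change vs −log10 p for tested common groups, sorted by p."""
    rows = [
        {
            "group_id": r.group_id,
            "log2_fc": r.log2_fc,
            "neg_log10_p": -math.log10(r.p_value),
            "category": r.category,
        }
        for r in records
        if r.category in COMMON_CATEGORIES and r.p_value is not None
    ]
    df = pd.DataFrame(rows, columns=["group_id", "log2_fc", "neg_log10_p", "category"])
    return df.sort_values("neg_log10_p", ascending=False, kind="stable").reset_index(drop=True)


def records_to_table(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group_id": [r.group_id for r in records],
            "representative": [r.representative for r in records],
            "mean_ribaq_plus": [r.mean_ribaq_plus for r in records],
            "mean_ribaq_minus": [r.mean_ribaq_minus for r in records],
            "fold_enrichment": [r.fold_enrichment for r in records],
            "log2_fc": [r.log2_fc for r in records],
            "p_value": [r.p_value for r in records],
            "category": [r.category for r in records],
        }
    )
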