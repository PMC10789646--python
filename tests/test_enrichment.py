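import math

import numpy as np
import pytest

from xlquant.enrichment import (
    CATEGORIES,
    COMMON_CATEGORIES,
    EnrichmentConfig,
    classify,
    compute_ribaq,
    condition_means,
    venn_counts,
    volcano_table,
)
from xlquant.enrichment import test_enrichment as enrichment_ttest
from xlquant.grouping import group_proteins
from xlquant.proteingroups import filter_entries
from xlquant.simulate import ProteomicsSimConfig, generate_proteomics

from conftest import make_group


def test_ribaq_is_normalization(design4):
    groups = [
        make_group("G1", "A", {"p1": 60, "p2": 60, "m1": 60, "m2": 60}),
        make_group("G2", "B", {"p1": 30, "p2": 30, "m1": 30, "m2": 30}),
        make_group("G3", "C", {"p1": 10, "p2": 10, "m1": 10, "m2": 10}),
    ]
    table = compute_ribaq(groups, design4)
    assert table.values["p1"].tolist() == pytest.approx([0.6, 0.3, 0.1])
    assert table.values.sum(axis=0).tolist() == pytest.approx([1.0] * 4)


def test_presence_rule_excludes_partial_detection(design4):
    # B detected in p1 but not p2: excluded from +UV entirely
    groups = [
        make_group("G1", "A", {"p1": 50, "p2": 50, "m1": 50, "m2": 50}),
        make_group("G2", "B", {"p1": 50, "p2": 0, "m1": 50, "m2": 50}),
    ]
    table = compute_ribaq(groups, design4)
    assert table.values.at["G2", "p1"] == 0.0
    assert table.values.at["G2", "p2"] == 0.0
    assert not table.present("G2", "plusUV")
    assert table.present("G2", "minusUV")
    # A is then the single retained group in +UV columns
    assert table.values.at["G1", "p1"] == pytest.approx(1.0)


def test_group_absent_everywhere_is_dropped(design4):
    groups = [
        make_group("G1", "A", {"p1": 50, "p2": 50, "m1": 50, "m2": 50}),
        make_group("G2", "B", {"p1": 50, "p2": 0, "m1": 0, "m2": 50}),
    ]
    table = compute_ribaq(groups, design4)
    assert list(table.values.index) == ["G1"]


def test_condition_means(design4):
    groups = [
        make_group("G1", "A", {"p1": 2, "p2": 4, "m1": 30, "m2": 30}),
        make_group("G2", "B", {"p1": 98, "p2": 96, "m1": 70, "m2": 70}),
    ]
    table = compute_ribaq(groups, design4)
    means = condition_means(table)
    assert means.at["G1", "mean_plus"] == pytest.approx(0.03)
    assert means.at["G1", "mean_minus"] == pytest.approx(0.3)


def test_ttest_identity_and_arithmetic():
    fold, p = enrichment_ttest([0.02, 0.02], [0.02, 0.02])
    assert fold == pytest.approx(1.0) and p == pytest.approx(1.0)
    fold, p = enrichment_ttest([0.02, 0.02], [0.005, 0.005])
    assert fold == pytest.approx(4.0)
    with pytest.raises(ValueError):
        enrichment_ttest([0.02, 0.0], [0.01, 0.01])
    with pytest.raises(ValueError):
        enrichment_ttest([0.02], [0.01, 0.01])


def test_null_type_i_error_calibrated(rng):
    """Gaussian log-riBAQ with no true effect: empirical size near nominal 0.05."""
    n = 2000
    hits = 0
    for _ in range(n):
        plus = 2.0 ** rng.normal(-10, 0.5, size=2)
        minus = 2.0 ** rng.normal(-10, 0.5, size=2)
        _, p = enrichment_ttest(plus, minus)
        hits += p <= 0.05
    assert 0.03 <= hits / n <= 0.07


def test_classify_categories(design4):
    groups = [
        # detected in both +UV replicates, zero in both −UV: exclusive to +UV
        make_group("G1", "EXC", {"p1": 40, "p2": 40, "m1": 0, "m2": 0}),
        # strong consistent enrichment
        make_group("G2", "ENR", {"p1": 500, "p2": 505, "m1": 50, "m2": 51}),
        # moderate fold but wildly inconsistent replicates: not significant
        make_group("G3", "NSG", {"p1": 300, "p2": 20, "m1": 50, "m2": 49}),
        # stable background filler
        make_group("G4", "BGA", {"p1": 1000, "p2": 1010, "m1": 1000, "m2": 990}),
    ]
    records = {r.representative: r for r in classify(groups, compute_ribaq(groups, design4))}
    assert records["EXC"].category == "exclusive_plus"
    assert records["EXC"].p_value is None and records["EXC"].fold_enrichment is None
    assert records["ENR"].category == "common_enriched"
    assert records["ENR"].p_value <= 0.05 and records["ENR"].fold_enrichment >= 2
    assert records["NSG"].category == "common_ns"
    assert all(r.category in CATEGORIES for r in records.values())


def test_classify_partial_opposite_detection_is_common_ns(design4):
    groups = [
        make_group("G1", "A", {"p1": 40, "p2": 40, "m1": 10, "m2": 0}),
        make_group("G2", "B", {"p1": 60, "p2": 60, "m1": 90, "m2": 100}),
    ]
    records = {r.representative: r for r in classify(groups, compute_ribaq(groups, design4))}
    assert records["A"].category == "common_ns"
    assert records["A"].p_value is None


def test_scale_invariance(design4, rng):
    """Rescaling one sample's iBAQ leaves riBAQ, folds and p-values unchanged."""
    samples = ["p1", "p2", "m1", "m2"]
    groups = [
        make_group(f"G{i}", f"P{i}", {s: float(v) for s, v in zip(samples, row)})
        for i, row in enumerate(rng.lognormal(3, 1, size=(20, 4)))
    ]
    scaled = [
        make_group(g.group_id, g.representative, {**g.pooled_intensities, "p1": g.pooled_intensities["p1"] * 37.5})
        for g in groups
    ]
    rec_a = classify(groups, compute_ribaq(groups, design4))
    rec_b = classify(scaled, compute_ribaq(scaled, design4))
    for a, b in zip(rec_a, rec_b):
        assert a.category == b.category
        if a.p_value is not None:
            assert a.p_value == pytest.approx(b.p_value, rel=1e-9)
            assert a.fold_enrichment == pytest.approx(b.fold_enrichment, rel=1e-9)


def test_venn_counts_partition(design4):
    assert venn_counts([]) == {
        "n_exclusive_plus": 0,
        "n_exclusive_minus": 0,
        "n_common": 0,
        "n_common_enriched": 0,
    }
    cfg = ProteomicsSimConfig(
        n_background=60, n_true_interactors=0, n_exclusive_plus=5,
        n_contaminants=0, n_decoys=0, dropout=False, seed=3,
    )
    entries, design, truth = generate_proteomics(cfg)
    groups = group_proteins(filter_entries(entries)[0])
    records = classify(groups, compute_ribaq(groups, design))
    counts = venn_counts(records)
    # without dropout the exclusive-to-+UV truth is recovered exactly
    assert counts["n_exclusive_plus"] == 5
    assert (
        counts["n_exclusive_plus"] + counts["n_exclusive_minus"] + counts["n_common"]
        == len(records)
    )


def test_volcano_table(design4):
    groups = [
        make_group("G1", "EXC", {"p1": 40, "p2": 40, "m1": 0, "m2": 0}),
        make_group("G2", "A", {"p1": 400, "p2": 404, "m1": 100, "m2": 101}),
        make_group("G3", "B", {"p1": 100, "p2": 101, "m1": 100, "m2": 101}),
    ]
    records = classify(groups, compute_ribaq(groups, design4))
    df = volcano_table(records)
    # exclusive records carry no finite fold/p and are omitted
    assert "G1" not in set(df["group_id"])
    assert len(df) == 2
    # sorted by p ascending == −log10 p descending
    assert df["neg_log10_p"].is_monotonic_decreasing
    row = df[df["group_id"] == "G2"].iloc[0]
    fold_g2 = next(r.fold_enrichment for r in records if r.group_id == "G2")
    assert 2.0 ** row["log2_fc"] == pytest.approx(fold_g2)


def test_volcano_fold_and_p_arithmetic():
    from xlquant.enrichment import EnrichmentRecord

    rec = EnrichmentRecord(
        group_id="G1", representative="A", mean_ribaq_plus=0.4, mean_ribaq_minus=0.1,
        fold_enrichment=4.0, log2_fc=math.log2(4.0), p_value=0.01, category="common_enriched",
    )
    rec_p1 = EnrichmentRecord(
        group_id="G2", representative="B", mean_ribaq_plus=0.1, mean_ribaq_minus=0.1,
        fold_enrichment=1.0, log2_fc=0.0, p_value=1.0, category="common_ns",
    )
    df = volcano_table([rec, rec_p1])
    assert df.iloc[0]["log2_fc"] == pytest.approx(2.0)
    assert df.iloc[0]["neg_log10_p"] == pytest.approx(2.0)
    assert df.iloc[1]["neg_log10_p"] == pytest.approx(0.0)


def test_config_validation():
    with pytest.raises(ValueError):
        EnrichmentConfig(p_threshold=1.5)
    with pytest.raises(ValueError):
        EnrichmentConfig(fc_threshold=0.5)
    with pytest.raises(ValueError):
        EnrichmentConfig(test="wilcoxon")
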