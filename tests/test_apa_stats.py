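import numpy as np
import pandas as pd
import pytest
from scipy import stats

from apashift import apa_stats
from apashift.apa_stats import (
    apa_score,
    bh_fdr,
    binomial_glm_test,
    classify_events,
    median_ratio_size_factors,
    overlap_enrichment,
    segment_fold_changes,
    select_unaffected_controls,
)
from oracles import oracle_bh, oracle_hypergeom_tail


# ---------------------------------------------------------------------------
# size factors


def test_size_factors_identity_and_scaling():
    m = pd.DataFrame({"a": [10, 100, 4], "b": [10, 100, 4]})
    assert np.allclose(median_ratio_size_factors(m), [1.0, 1.0])
    m2 = pd.DataFrame({"a": [10, 100, 4], "b": [20, 200, 8]})
    sf = median_ratio_size_factors(m2)
    assert sf["b"] / sf["a"] == pytest.approx(2.0)


def test_size_factors_hand_computed_example():
    m = pd.DataFrame({"a": [10, 100, 4], "b": [20, 200, 8]})
    sf = median_ratio_size_factors(m)
    assert sf["a"] == pytest.approx(1 / np.sqrt(2))
    assert sf["b"] == pytest.approx(np.sqrt(2))


def test_size_factors_need_an_all_positive_row():
    m = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
    with pytest.raises(ValueError, match="pseudo-count"):
        median_ratio_size_factors(m)


# ---------------------------------------------------------------------------
# fold changes and scores


def _matrix(depths, conditions, lengths=None):
    from apashift.segmentation import SegmentCountMatrix

    depth = pd.DataFrame(depths)
    depth.index = pd.MultiIndex.from_tuples(depth.index, names=["gene_id", "segment_index"])
    counts = (depth * 2).round().astype(int)  # arbitrary consistent integers
    if lengths is None:
        lengths = pd.Series(100, index=depth.index, name="length")
    return SegmentCountMatrix(
        counts=counts, depth=depth, lengths=lengths, conditions=conditions, baseline="wt"
    )


def test_fold_change_mut_over_wt_and_zero_baseline():
    m = _matrix(
        {
            "wt_1": {("g", 0): 10.0, ("h", 0): 0.0},
            "mut_1": {("g", 0): 20.0, ("h", 0): 5.0},
            "mut_2": {("g", 0): 20.0, ("h", 0): 5.0},
        },
        {"wt_1": "wt", "mut_1": "mut", "mut_2": "mut"},
    )
    m.size_factors = pd.Series(1.0, index=m.samples)
    fc = segment_fold_changes(m)
    assert fc[("g", 0)] == pytest.approx(2.0)
    assert np.isnan(fc[("h", 0)])


@pytest.mark.parametrize(
    "wp,wd,mp,md,expected",
    [
        (10, 10, 10, 10, 0.0),
        (10, 20, 20, 10, -2.0),
        (20, 10, 10, 20, 2.0),  # condition swap negates
    ],
)
def test_apa_score_closed_form(wp, wd, mp, md, expected):
    score, _, _ = apa_score(wp, wd, mp, md)
    assert score == pytest.approx(expected, abs=1e-12)


def test_apa_score_zero_segment_gets_pseudocount():
    score, ratio_wt, _ = apa_score(10, 0, 10, 10, pseudocount=0.5)
    assert np.isfinite(score)
    assert ratio_wt == pytest.approx(0.5 / 10.5)


def test_apa_score_antisymmetric_under_condition_swap():
    rng = np.random.default_rng(0)
    for _ in range(50):
        wp, wd, mp, md = rng.uniform(0.1, 50, size=4)
        s1, _, _ = apa_score(wp, wd, mp, md)
        s2, _, _ = apa_score(mp, md, wp, wd)
        assert s1 == pytest.approx(-s2)


# ---------------------------------------------------------------------------
# GLM


def test_glm_null_identity_gives_p_one():
    p, flag = binomial_glm_test(
        proximal=[100, 100], distal=[100, 100], conditions=["wt", "mut"], baseline="wt"
    )
    assert flag == ""
    assert p == pytest.approx(1.0, abs=1e-6)


def test_glm_strong_shift_matches_chi2_order_of_magnitude():
    p, flag = binomial_glm_test(
        proximal=[100, 100, 180, 180],
        distal=[100, 100, 20, 20],
        conditions=["wt", "wt", "mut", "mut"],
        baseline="wt",
    )
    assert flag == ""
    assert p < 1e-10
    chi2_p = stats.chi2_contingency([[200, 200], [360, 40]])[1]
    assert chi2_p < 1e-10  # pooled-table oracle agrees the effect is extreme


def test_glm_separation_falls_back_to_continuity_correction():
    p, flag = binomial_glm_test(
        proximal=[0, 0, 50, 50],
        distal=[50, 50, 0, 0],
        conditions=["wt", "wt", "mut", "mut"],
        baseline="wt",
    )
    assert flag == "continuity_corrected"
    assert 0 <= p < 1e-6


def test_glm_all_zero_gene_reports_missing():
    p, flag = binomial_glm_test([0, 0], [0, 0], ["wt", "mut"], "wt")
    assert flag == "all_zero" and np.isnan(p)


def test_glm_lrt_option_close_to_wald_on_moderate_effect():
    args = dict(
        proximal=[100, 110, 140, 150],
        distal=[100, 95, 70, 60],
        conditions=["wt", "wt", "mut", "mut"],
        baseline="wt",
    )
    p_wald, _ = binomial_glm_test(**args, test="wald")
    p_lrt, _ = binomial_glm_test(**args, test="lrt")
    assert np.isclose(np.log10(p_wald), np.log10(p_lrt), atol=0.5)


def test_glm_invariant_to_library_scaling():
    # proportions are within-sample; doubling one sample's counts moves p
    # only through its (information-bearing) totals, so scale all samples
    p1, _ = binomial_glm_test([50, 50], [60, 30], ["wt", "mut"], "wt")
    p2, _ = binomial_glm_test([100, 100], [120, 60], ["wt", "mut"], "wt")
    # same proportions, doubled information: p2 must be at most p1
    assert p2 <= p1


# ---------------------------------------------------------------------------
# FDR


@pytest.mark.parametrize(
    "p,expected",
    [
        ([0.02], [0.02]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.001, 0.5], [0.002, 0.5]),
    ],
)
def test_bh_fdr_hand_examples(p, expected):
    assert np.allclose(bh_fdr(p), expected)


def test_bh_fdr_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


def test_bh_fdr_propagates_nan_without_counting_it():
    q = bh_fdr([0.01, np.nan, 0.5])
    assert np.isnan(q[1])
    assert np.allclose(q[[0, 2]], bh_fdr([0.01, 0.5]))


def test_bh_fdr_matches_stepup_oracle_on_random_vectors():
    rng = np.random.default_rng(42)
    for _ in range(200):
        p = rng.uniform(size=rng.integers(1, 60))
        assert np.allclose(bh_fdr(p), oracle_bh(p))


# ---------------------------------------------------------------------------
# classification and controls


def test_classification_thresholds():
    df = pd.DataFrame(
        {
            "gene_id": ["a", "b", "c", "d"],
            "apa_score": [-1.5, -1.5, 0.5, 1.2],
            "fdr": [0.001, 0.02, 1e-9, 0.005],
        }
    )
    cls = classify_events(df)
    assert list(cls) == ["proximal", "unchanged", "unchanged", "distal"]


def test_control_selection_ranks_by_absolute_score():
    df = pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3", "g4"],
            "apa_score": [0.01, -0.5, 0.02, 1.8],
            "class": ["unchanged", "unchanged", "unchanged", "distal"],
        }
    )
    assert select_unaffected_controls(df, 2) == ["g1", "g3"]
    assert select_unaffected_controls(df, 0) == []
    assert select_unaffected_controls(df, 3) == ["g1", "g3", "g2"]
    with pytest.raises(ValueError, match="3"):
        select_unaffected_controls(df, 4)


# ---------------------------------------------------------------------------
# overlap enrichment


def test_overlap_enrichment_worked_example():
    universe = [f"u{i}" for i in range(100)]
    a = universe[:20]
    b = universe[10:30]  # overlap of 10
    odds, p = overlap_enrichment(a, b, universe)
    assert odds == pytest.approx(7.0)
    assert p == pytest.approx(oracle_hypergeom_tail(10, 100, 20, 20))
    fisher = stats.fisher_exact([[10, 10], [10, 70]], alternative="greater")
    assert p == pytest.approx(fisher.pvalue)


def test_overlap_at_expected_count_is_not_significant():
    universe = [f"u{i}" for i in range(100)]
    a = universe[:20]
    b = universe[16:41]  # |B|=25, overlap 4 < expected 5, OR < 1
    _, p = overlap_enrichment(a, b, universe)
    assert p > 0.4


def test_overlap_subset_is_maximal():
    universe = [f"u{i}" for i in range(50)]
    a = universe[:10]
    odds, p = overlap_enrichment(a, universe[:20], universe)
    assert odds == np.inf
    assert p == pytest.approx(oracle_hypergeom_tail(10, 50, 10, 20))
    with pytest.raises(ValueError):
        overlap_enrichment(a, ["zz"], universe)


# ---------------------------------------------------------------------------
# orchestrated analysis invariants


def test_analysis_scores_negate_under_condition_swap(small_pipeline):
    matrix = small_pipeline["matrix"]
    res = small_pipeline["results"].set_index("gene_id")
    from apashift.segmentation import SegmentCountMatrix

    flipped = SegmentCountMatrix(
        counts=matrix.counts,
        depth=matrix.depth,
        lengths=matrix.lengths,
        conditions=matrix.conditions,
        baseline=matrix.test_level,  # swap reference level
    )
    res2 = apa_stats.run_apa_analysis(flipped).set_index("gene_id")
    assert np.allclose(res2["apa_score"], -res["apa_score"], atol=1e-9)


def test_analysis_invariant_to_per_sample_scaling(small_pipeline):
    from apashift.segmentation import SegmentCountMatrix

    matrix = small_pipeline["matrix"]
    res = small_pipeline["results"].set_index("gene_id")
    scaled_depth = matrix.depth.copy()
    scaled_counts = matrix.counts.copy()
    scaled_depth["wt_1"] *= 3.0
    scaled_counts["wt_1"] *= 3
    scaled = SegmentCountMatrix(
        counts=scaled_counts,
        depth=scaled_depth,
        lengths=matrix.lengths,
        conditions=matrix.conditions,
        baseline=matrix.baseline,
    )
    res2 = apa_stats.run_apa_analysis(scaled).set_index("gene_id")
    # normalization absorbs the scale: scores identical
    assert np.allclose(res2["apa_score"], res["apa_score"], atol=1e-9)
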