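import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apashift import iolib, segmentation
from apashift.iolib import GeneModel, PASPeak, SampleSheet, ValidationError
from apashift.segmentation import (
    filter_peaks,
    merge_peaks,
    quantify_segments,
    segment_gene,
    segment_genes,
)
from conftest import make_peak
from oracles import oracle_filter, oracle_merge


# ---------------------------------------------------------------------------
# filtering


@pytest.mark.parametrize(
    "counts,kept",
    [
        ([6, 100, 4], [6, 100]),  # 4 fails ">5 reads"; 6/110 = 5.45% passes
        ([5, 95], [95]),  # 5 is not "more than five"
        ([6, 200], [200]),  # 6/206 = 2.9% < 5%
        ([], []),
    ],
)
def test_filter_peaks_applies_both_rules(counts, kept):
    peaks = [make_peak(100 * (i + 1), c) for i, c in enumerate(counts)]
    assert [p.count for p in filter_peaks(peaks)] == kept


# ---------------------------------------------------------------------------
# merging


def test_merge_takes_stronger_position_and_sums_counts():
    merged = merge_peaks([make_peak(100, 10), make_peak(130, 30)])
    assert [(p.site, p.count) for p in merged] == [(130, 40)]
    merged = merge_peaks([make_peak(100, 30), make_peak(130, 10)])
    assert [(p.site, p.count) for p in merged] == [(100, 40)]


def test_merge_chain_uses_closest_pair_then_reiterates():
    # both gaps are 49: lower-coordinate tie-break merges 100+149 first
    merged = merge_peaks([make_peak(100, 20), make_peak(149, 50), make_peak(198, 20)])
    assert [(p.site, p.count) for p in merged] == [(149, 90)]


def test_merge_distance_exactly_50_does_not_merge():
    merged = merge_peaks([make_peak(100, 10), make_peak(150, 10)])
    assert len(merged) == 2


def test_merge_equal_counts_keeps_distal_position():
    plus = merge_peaks([make_peak(100, 10), make_peak(120, 10)])
    assert plus[0].site == 120
    minus = merge_peaks(
        [make_peak(100, 10, strand="-"), make_peak(120, 10, strand="-")]
    )
    assert minus[0].site == 100


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(1, 5000), st.integers(0, 500)), min_size=0, max_size=10
    )
)
def test_filter_and_merge_match_bruteforce_oracle(pairs):
    peaks = [make_peak(s, c) for s, c in pairs]
    got = merge_peaks(filter_peaks(peaks))
    want = oracle_merge(oracle_filter([(s, c) for s, c in pairs]), strand="+")
    assert sorted((p.site, p.count) for p in got) == sorted(want)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(1, 5000), st.integers(0, 500)), min_size=0, max_size=10
    )
)
def test_merge_is_idempotent_and_conserves_counts(pairs):
    peaks = [make_peak(s, c) for s, c in pairs]
    once = merge_peaks(peaks)
    assert merge_peaks(once) == once
    assert sum(p.count for p in once) == sum(p.count for p in peaks)
    sites = sorted(p.site for p in once)
    assert all(b - a >= 50 for a, b in zip(sites, sites[1:]))


# ---------------------------------------------------------------------------
# segmentation


def test_segment_plus_strand_windows():
    gene = GeneModel(gene_id="g", chrom="c", strand="+", start=0, end=1000, biotype="ncRNA")
    seg = segment_gene(gene, [make_peak(400, 50, "g", "c"), make_peak(900, 50, "g", "c")])
    assert seg.segments == [(0, 400), (400, 900)]
    assert seg.eligible
    assert seg.proximal_site == 400 and seg.distal_site == 900


def test_segment_minus_strand_mirrors_proximal_distal():
    gene = GeneModel(gene_id="g", chrom="c", strand="-", start=0, end=1000, biotype="ncRNA")
    seg = segment_gene(
        gene,
        [make_peak(600, 50, "g", "c", "-"), make_peak(100, 50, "g", "c", "-")],
    )
    # proximal segment is the rightmost window, distal the leftmost
    assert seg.segments == [(599, 1000), (99, 599)]
    assert seg.proximal_site == 600 and seg.distal_site == 100


def test_single_peak_gene_is_ineligible():
    gene = GeneModel(gene_id="g", chrom="c", strand="+", start=0, end=1000, biotype="ncRNA")
    seg = segment_gene(gene, [make_peak(400, 50, "g", "c")])
    assert not seg.eligible
    zero = segment_genes([gene], [])
    assert not zero["g"].eligible and zero["g"].segments == []


def test_segment_lengths_partition_tss_to_distal_pas():
    gene = GeneModel(gene_id="g", chrom="c", strand="+", start=10, end=1000, biotype="ncRNA")
    seg = segment_gene(gene, [make_peak(300, 9, "g", "c"), make_peak(900, 9, "g", "c")])
    total = sum(e - s for s, e in seg.segments)
    assert total == 900 - 10  # TSS through the distal PAS base


def test_strand_mirror_preserves_segmentation():
    L = 5000
    gene = GeneModel(gene_id="g", chrom="c", strand="+", start=100, end=2100, biotype="ncRNA")
    sites = [600, 2000]
    seg = segment_gene(gene, [make_peak(s, 10, "g", "c") for s in sites])
    m_gene = GeneModel(
        gene_id="g", chrom="c", strand="-", start=L - 2100, end=L - 100, biotype="ncRNA"
    )
    m_seg = segment_gene(
        m_gene, [make_peak(L - s + 1, 10, "g", "c", "-") for s in sites]
    )
    mirrored = [(L - e, L - s) for s, e in m_seg.segments]
    assert mirrored == seg.segments  # same windows, proximal/distal preserved


# ---------------------------------------------------------------------------
# quantification


def _track(chrom, triples):
    starts = np.array([t[0] for t in triples])
    ends = np.array([t[1] for t in triples])
    vals = np.array([t[2] for t in triples], dtype=float)
    return {chrom: (starts, ends, vals)}


def test_quantify_uniform_depth_mass_and_pseudocount(two_by_two_sheet):
    gene = GeneModel(gene_id="g", chrom="c", strand="+", start=0, end=400, biotype="ncRNA")
    seg = segment_gene(gene, [make_peak(200, 9, "g", "c"), make_peak(400, 9, "g", "c")])
    tracks = {s: _track("c", [(0, 400, 10.0)]) for s in two_by_two_sheet.samples}
    m = quantify_segments({"g": seg}, tracks, two_by_two_sheet, read_length=100)
    # 200-nt segment at uniform depth 10: mass 2000, mean depth 10, count 20
    assert m.depth.loc[("g", 0), "wt_1"] == pytest.approx(10.0)
    assert m.counts.loc[("g", 0), "wt_1"] == 20
    assert m.lengths.loc[("g", 0)] == 200


def test_quantify_partial_coverage_and_zero(two_by_two_sheet):
    gene = GeneModel(gene_id="g", chrom="c", strand="+", start=0, end=400, biotype="ncRNA")
    seg = segment_gene(gene, [make_peak(200, 9, "g", "c"), make_peak(400, 9, "g", "c")])
    # first half of segment 0 at depth 4, everything else uncovered
    tracks = {s: _track("c", [(0, 100, 4.0)]) for s in two_by_two_sheet.samples}
    m = quantify_segments({"g": seg}, tracks, two_by_two_sheet, read_length=100)
    assert m.depth.loc[("g", 0), "wt_1"] == pytest.approx(2.0)
    assert m.depth.loc[("g", 1), "wt_1"] == 0.0
    assert m.counts.loc[("g", 1), "wt_1"] == 0


def test_segment_counts_tsv_roundtrip(tmp_path, two_by_two_sheet, small_pipeline):
    matrix = small_pipeline["matrix"]
    path = tmp_path / "counts.tsv"
    segmentation.write_segment_counts(matrix, path)
    back = segmentation.read_segment_counts(path, small_pipeline["sheet"])
    assert back.counts.equals(matrix.counts)
    assert np.allclose(back.lengths, matrix.lengths)


def test_segment_counts_missing_sample_errors(tmp_path, small_pipeline):
    matrix = small_pipeline["matrix"]
    path = tmp_path / "counts.tsv"
    segmentation.write_segment_counts(matrix, path)
    bad_sheet = SampleSheet(
        conditions={**dict(small_pipeline["sheet"].conditions), "extra": "mut"}
    )
    with pytest.raises(ValidationError, match="extra"):
        segmentation.read_segment_counts(path, bad_sheet)
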