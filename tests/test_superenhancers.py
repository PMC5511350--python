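"""Super-enhancer calling: promoter filter, rank-curve cutoff, overlaps,
opening trace and expression-by-connectivity."""

import numpy as np
import pandas as pd
import pytest

import regulink as rl
from regulink.genome import GenomeLayout, GenomicInterval, IntervalSet, SignalTrack
from regulink import superenhancers as sec


@pytest.fixture()
def layout():
    return GenomeLayout((("chr1", 1_000_000),))


def _single_enhancers(n, spacing=20_000, length=100):
    """n isolated enhancers that never stitch (spacing >> 12.5 kb)."""
    return [
        GenomicInterval("chr1", i * spacing, i * spacing + length, f"e{i}")
        for i in range(n)
    ]


def _tracks_for_scores(enhancers, scores):
    """Treatment track giving each region the requested background-subtracted
    score (input is empty)."""
    runs = [
        (iv.start, iv.end, score / len(iv)) for iv, score in zip(enhancers, scores)
    ]
    return SignalTrack({"chr1": runs}), SignalTrack({"chr1": []})


# ---------------------------------------------------------------------------
# promoter filter
# ---------------------------------------------------------------------------

def test_promoter_filter_removes_padded_hits(layout):
    enh = IntervalSet([GenomicInterval("chr1", 5000, 6000)], layout=layout)
    prom = IntervalSet([GenomicInterval("chr1", 6500, 6600)], layout=layout)
    assert len(sec.filter_promoter_enhancers(enh, prom, layout, pad=1000)) == 0
    assert len(sec.filter_promoter_enhancers(enh, prom, layout, pad=0)) == 1


def test_promoter_filter_matches_bruteforce(layout):
    rng = np.random.default_rng(21)
    enh = IntervalSet(
        [GenomicInterval("chr1", s := int(rng.integers(0, 900_000)),
                         s + int(rng.integers(200, 2000)), f"e{i}")
         for i in range(50)],
        layout=layout,
    )
    prom = IntervalSet(
        [GenomicInterval("chr1", s := int(rng.integers(0, 900_000)), s + 1400)
         for _ in range(20)],
        layout=layout,
    )
    out = sec.filter_promoter_enhancers(enh, prom, layout, pad=1000)
    survivors = {
        iv.label
        for iv in enh
        if not any(
            iv.overlap_bp(GenomicInterval(p.chrom, max(0, p.start - 1000),
                                          p.end + 1000)) >= 1
            for p in prom
        )
    }
    assert {iv.label for iv in out} == survivors


# ---------------------------------------------------------------------------
# rank-curve cutoff
# ---------------------------------------------------------------------------

def _brute_cutoff(scores_ascending):
    s = np.asarray(scores_ascending, float)
    n = len(s)
    x = np.arange(n) / (n - 1)
    rng = s[-1] - s[0]
    y = (s - s[0]) / rng if rng > 0 else np.zeros(n)
    best, best_v = 0, -np.inf
    for i in range(n):
        v = x[i] - y[i]
        if v > best_v:
            best, best_v = i, v
    return best


def test_rank_cutoff_matches_bruteforce_scan():
    rng = np.random.default_rng(17)
    for _ in range(100):
        n = int(rng.integers(3, 200))
        scores = np.sort(rng.gamma(1.0, 100.0, size=n))
        assert sec.rank_cutoff_index(scores) == _brute_cutoff(scores)


def test_single_outlier_region_is_the_only_super(layout):
    enh = _single_enhancers(20)
    scores = [1.0] * 19 + [100.0]
    treat, inp = _tracks_for_scores(enh, scores)
    calls, thr = sec.call_superenhancers(
        IntervalSet(enh, layout=layout), treat, inp
    )
    supers = [c for c in calls if c.is_super]
    assert len(supers) == 1
    assert supers[0].score == pytest.approx(100.0)
    assert supers[0].rank == 1
    assert thr.cutoff_score == pytest.approx(1.0)


def test_constant_scores_yield_no_super_and_order_stability(layout):
    enh = _single_enhancers(10)
    treat, inp = _tracks_for_scores(enh, [5.0] * 10)
    with pytest.warns(UserWarning, match="zero"):
        zero_calls, _ = sec.call_superenhancers(
            IntervalSet(enh, layout=layout),
            SignalTrack({"chr1": []}),  # zero treatment -> all-zero scores
            inp,
        )
    assert not any(c.is_super for c in zero_calls)
    calls, _ = sec.call_superenhancers(IntervalSet(enh, layout=layout), treat, inp)
    assert not any(c.is_super for c in calls)
    # reordering the input does not change the result (canonical sorting)
    calls_rev, _ = sec.call_superenhancers(
        IntervalSet(list(reversed(enh)), layout=layout), treat, inp
    )
    assert [(c.region.start, c.rank, c.is_super) for c in calls] == [
        (c.region.start, c.rank, c.is_super) for c in calls_rev
    ]


def test_tie_break_is_positional(layout):
    enh = _single_enhancers(5)
    treat, inp = _tracks_for_scores(enh, [3.0, 7.0, 3.0, 9.0, 3.0])
    calls, _ = sec.call_superenhancers(IntervalSet(enh, layout=layout), treat, inp)
    by_rank = sorted(calls, key=lambda c: c.rank)
    assert [c.score for c in by_rank] == pytest.approx([9.0, 7.0, 3.0, 3.0, 3.0])
    tied = [c.region.start for c in by_rank[2:]]
    assert tied == sorted(tied)  # earlier position = better rank among ties


def test_fewer_than_three_regions_warns_and_calls_none(layout):
    enh = _single_enhancers(1)
    treat, inp = _tracks_for_scores(enh, [50.0])
    with pytest.warns(UserWarning, match="cutoff is"):
        calls, thr = sec.call_superenhancers(IntervalSet(enh, layout=layout), treat, inp)
    assert not calls[0].is_super
    assert thr.cutoff_index is None


def test_empty_enhancer_set_is_an_error(layout):
    with pytest.raises(ValueError, match="empty"):
        sec.call_superenhancers(
            IntervalSet([], layout=layout), SignalTrack({}), SignalTrack({})
        )


def test_scaling_both_tracks_leaves_partition_unchanged(layout):
    rng = np.random.default_rng(2)
    enh = _single_enhancers(30)
    scores = rng.gamma(1.0, 50.0, size=30)
    treat, _ = _tracks_for_scores(enh, scores)
    inp = SignalTrack({"chr1": [(iv.start, iv.end, 0.05) for iv in enh]})
    base, _ = sec.call_superenhancers(IntervalSet(enh, layout=layout), treat, inp)
    treat_s = SignalTrack({"chr1": [(iv.start, iv.end, scores[i] / len(iv))
                                    for i, iv in enumerate(enh)]}, scale=7.3)
    inp_s = SignalTrack({"chr1": [(iv.start, iv.end, 0.05) for iv in enh]}, scale=7.3)
    scaled, _ = sec.call_superenhancers(IntervalSet(enh, layout=layout), treat_s, inp_s)
    assert [c.is_super for c in base] == [c.is_super for c in scaled]


# ---------------------------------------------------------------------------
# on the synthetic study
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def mk_calls(small_dataset):
    ds = small_dataset
    filtered = sec.filter_promoter_enhancers(
        ds.enhancer_segments["MK"], ds.promoter_segments, ds.layout
    )
    calls, thr = sec.call_superenhancers(
        filtered, ds.h3k27ac["MK"], ds.input_signal["MK"]
    )
    return filtered, calls, thr


def test_constituent_conservation(mk_calls):
    filtered, calls, _ = mk_calls
    n_members = sum(len(c.constituents) for c in calls)
    assert n_members == len(filtered)
    # ranks are a permutation of 1..N and is_super is monotone in score
    ranks = sorted(c.rank for c in calls)
    assert ranks == list(range(1, len(calls) + 1))
    min_super = min((c.score for c in calls if c.is_super), default=np.inf)
    max_other = max((c.score for c in calls if not c.is_super), default=-np.inf)
    assert min_super > max_other


def test_planted_clusters_are_called_super(small_dataset, mk_calls):
    _, calls, _ = mk_calls
    called = {(c.region.chrom, c.region.start, c.region.end)
              for c in calls if c.is_super}
    truth = {
        (t.region.chrom, t.region.start, t.region.end)
        for t in small_dataset.truth.clusters
        if t.cell in ("MK", "shared")
    }
    assert called == truth


def test_se_overlap_length_fraction_rule():
    def mk(start, end):
        return sec.SECall(GenomicInterval("chr1", start, end), (), 1.0, 1, True)

    shared = sec.se_overlap([mk(0, 10_000)], [mk(4000, 20_000)])
    assert shared.shared_a == [0] and shared.shared_b == [0]
    disjointish = sec.se_overlap([mk(0, 10_000)], [mk(9000, 40_000)])
    assert disjointish.a_specific == [0] and disjointish.b_specific == [0]


def test_se_overlap_matches_quadratic_bruteforce():
    rng = np.random.default_rng(8)

    def rand_calls(n):
        out = []
        for i in range(n):
            s = int(rng.integers(0, 500_000))
            out.append(
                sec.SECall(GenomicInterval("chr1", s, s + int(rng.integers(1000, 30_000))),
                           (), 1.0, i + 1, True)
            )
        return out

    a, b = rand_calls(40), rand_calls(40)
    res = sec.se_overlap(a, b, min_frac=0.5)
    brute_pairs = set()
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            ov = x.region.overlap_bp(y.region)
            if ov >= 0.5 * len(x.region) or (ov > 0 and ov >= 0.5 * len(y.region)):
                brute_pairs.add((i, j))
    assert set(res.pairs) == brute_pairs
    assert set(res.shared_a) == {i for i, _ in brute_pairs}
    assert set(res.shared_b) == {j for _, j in brute_pairs}


def test_trace_se_opening_matches_generator_truth(small_dataset, progenitor_sets, mk_calls):
    ds = small_dataset
    _, calls, _ = mk_calls
    supers = [c for c in calls if c.is_super]
    _, se_tbl = sec.trace_se_opening(
        supers, ds.open_chromatin["MK"], progenitor_sets, ds.layout
    )
    truth_by_start = {
        t.region.start: t.fully_open
        for t in ds.truth.clusters
        if t.cell in ("MK", "shared")
    }
    for row in se_tbl.itertuples():
        assert bool(row.fully_open_in_progenitors) == truth_by_start[
            supers[row.se_index].region.start
        ]
    assert se_tbl.fully_open_in_progenitors.any()


def test_constituent_without_open_chromatin_blocks_fully_open(layout):
    cons = (GenomicInterval("chr1", 1000, 2000, "c1"),
            GenomicInterval("chr1", 5000, 6000, "c2"))
    call = sec.SECall(GenomicInterval("chr1", 1000, 6000), cons, 10.0, 1, True)
    term = IntervalSet([GenomicInterval("chr1", 1100, 1900)], layout=layout)
    prog = {c: IntervalSet([GenomicInterval("chr1", 1000, 2000)]) for c in ("HSC", "CMP", "MEP")}
    cons_tbl, se_tbl = sec.trace_se_opening([call], term, prog, layout)
    assert not se_tbl.iloc[0].fully_open_in_progenitors  # c2 has no open peak
    assert cons_tbl.open_in_terminal.tolist() == [True, False]


def test_expression_by_connectivity_buckets_and_medians():
    genes = pd.DataFrame(
        [
            {"gene_id": "A", "chrom": "chr1", "tss": "1", "fpkm": 10.0},
            {"gene_id": "B", "chrom": "chr1", "tss": "1", "fpkm": 30.0},
            {"gene_id": "C", "chrom": "chr1", "tss": "1", "fpkm": 5.0},
            {"gene_id": "D", "chrom": "chr1", "tss": "1", "fpkm": 99.0},
        ]
    )
    links = {
        "A": {"t1", "t2", "t3", "t4", "t5"},
        "B": {"s1"},
        "C": {"s1", "t1"},
    }
    tbl, n_unlinked = sec.expression_by_connectivity(
        genes, links, {"s1", "s2"}, {"t1", "t2", "t3", "t4", "t5"}
    )
    assert n_unlinked == 1  # D has no links
    rows = {(r.n_linked_enhancers, r.composition): r.median_fpkm
            for r in tbl.itertuples()}
    assert rows == {(5, "TE-only"): 10.0, (1, "SE-only"): 30.0, (2, "mixed"): 5.0}


def test_expression_by_connectivity_rejects_unknown_labels():
    genes = pd.DataFrame([{"gene_id": "A", "chrom": "c", "tss": "1", "fpkm": 1.0}])
    with pytest.raises(ValueError, match="unknown enhancer"):
        sec.expression_by_connectivity(genes, {"A": {"zzz"}}, set(), set())
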