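"""Interval algebra: parsing, extension, overlap, stitching, signal sums."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regulink.genome import (
    BedFormatError,
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    SignalTrack,
    extend,
    merge_within,
    overlaps,
    read_bed,
    signal_sum,
    write_bed,
)


@pytest.fixture()
def layout():
    return GenomeLayout((("chr1", 10_000), ("chr2", 400)))


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def test_read_bed_parses_labels_and_sorts(tmp_path, layout):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t500\t600\tb\nchr1\t0\t100\n")
    iset = read_bed(p, layout)
    assert [(iv.chrom, iv.start, iv.end, iv.label) for iv in iset] == [
        ("chr1", 0, 100, None),
        ("chr1", 500, 600, "b"),
    ]


@pytest.mark.parametrize(
    "content,fragment",
    [
        ("chr1\t100\t100\n", ":1"),  # empty interval
        ("chr1\t100\n", ":1"),  # too few columns
        ("chr1\tx\t200\n", ":1"),  # non-integer
    ],
)
def test_read_bed_rejects_malformed_lines_with_line_number(tmp_path, content, fragment):
    p = tmp_path / "bad.bed"
    p.write_text(content)
    with pytest.raises(BedFormatError, match=fragment):
        read_bed(p)


def test_read_bed_rejects_unknown_chromosome_under_layout(tmp_path, layout):
    p = tmp_path / "a.bed"
    p.write_text("chrX\t0\t10\n")
    with pytest.raises(BedFormatError, match="chrX"):
        read_bed(p, layout)


def test_bed_round_trip_is_bit_exact(tmp_path, layout):
    rng = np.random.default_rng(0)
    ivs = []
    for i in range(200):
        s = int(rng.integers(0, 9000))
        ivs.append(
            GenomicInterval("chr1", s, s + int(rng.integers(1, 500)),
                            f"x{i}" if i % 3 else None)
        )
    iset = IntervalSet(ivs, layout=layout)
    p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
    write_bed(iset, p1)
    write_bed(read_bed(p1, layout), p2)
    assert p1.read_bytes() == p2.read_bytes()


# ---------------------------------------------------------------------------
# extend
# ---------------------------------------------------------------------------

def test_extend_clamps_to_chromosome_bounds(layout):
    iset = IntervalSet([GenomicInterval("chr2", 100, 200)], layout=layout)
    (out,) = extend(iset, 500, layout)
    assert (out.start, out.end) == (0, 400)


def test_extend_zero_pad_is_identity(layout):
    iset = IntervalSet([GenomicInterval("chr1", 1000, 2000)], layout=layout)
    assert extend(iset, 0, layout) == iset


def test_extend_plain_arithmetic(layout):
    iset = IntervalSet([GenomicInterval("chr1", 1000, 2000)], layout=layout)
    (out,) = extend(iset, 500, layout)
    assert (out.start, out.end) == (500, 2500)


# ---------------------------------------------------------------------------
# overlaps
# ---------------------------------------------------------------------------

def test_overlaps_single_base_hits_and_half_open_misses(layout):
    a = IntervalSet([GenomicInterval("chr1", 0, 10)], layout=layout)
    assert overlaps(a, IntervalSet([GenomicInterval("chr1", 9, 20)])).flags[0]
    assert not overlaps(a, IntervalSet([GenomicInterval("chr1", 10, 20)])).flags[0]


def _random_intervals(rng, n, chroms=("chr1", "chr2"), span=5000):
    return [
        GenomicInterval(
            str(rng.choice(chroms)), s := int(rng.integers(0, span)),
            s + int(rng.integers(1, 300)),
        )
        for _ in range(n)
    ]


def test_overlaps_matches_quadratic_bruteforce_and_is_symmetric():
    rng = np.random.default_rng(42)
    a = IntervalSet(_random_intervals(rng, 100))
    b = IntervalSet(_random_intervals(rng, 100))
    for min_bp in (1, 5, 50):
        res = overlaps(a, b, min_bp=min_bp)
        brute = {
            (i, j)
            for i, x in enumerate(a)
            for j, y in enumerate(b)
            if x.overlap_bp(y) >= min_bp
        }
        assert set(res.pairs) == brute
        assert list(res.flags) == [any(i == p[0] for p in brute) for i in range(len(a))]
        # symmetry of hit existence
        rev = overlaps(b, a, min_bp=min_bp)
        assert {(j, i) for (i, j) in res.pairs} == set(rev.pairs)


# ---------------------------------------------------------------------------
# merge_within
# ---------------------------------------------------------------------------

def test_merge_within_stitches_by_gap_rule():
    iset = IntervalSet(
        [GenomicInterval("chr1", 0, 1000), GenomicInterval("chr1", 5000, 6000),
         GenomicInterval("chr1", 20_000, 21_000)]
    )
    out = merge_within(iset, 12_500)
    assert [(o.start, o.end, len(o.members)) for o in out] == [
        (0, 6000, 2), (20_000, 21_000, 1)
    ]


def test_merge_within_gap_zero_joins_touching_intervals():
    iset = IntervalSet([GenomicInterval("chr1", 0, 5), GenomicInterval("chr1", 5, 9)])
    out = merge_within(iset, 0)
    assert [(o.start, o.end) for o in out] == [(0, 9)]


def _closure_clusters(intervals, max_gap):
    """Brute-force transitive closure of pairwise proximity (union-find)."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            if a.chrom != b.chrom:
                continue
            gap = max(a.start, b.start) - min(a.end, b.end)
            if gap <= max_gap:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return {
        frozenset((intervals[i].chrom, intervals[i].start, intervals[i].end)
                  for i in g)
        for g in groups.values()
    }


def test_merge_within_equals_transitive_closure_on_random_intervals():
    rng = np.random.default_rng(7)
    iset = IntervalSet(_random_intervals(rng, 1000, span=100_000))
    for gap in (0, 50, 500):
        out = merge_within(iset, gap)
        got = {
            frozenset((m.chrom, m.start, m.end) for m in o.members) for o in out
        }
        assert got == _closure_clusters(list(iset), gap)


def test_merge_within_is_idempotent():
    rng = np.random.default_rng(3)
    iset = IntervalSet(_random_intervals(rng, 300, span=20_000))
    once = merge_within(iset, 100)
    spans = IntervalSet([o.interval for o in once])
    twice = merge_within(spans, 100)
    assert [(o.chrom, o.start, o.end) for o in once] == [
        (o.chrom, o.start, o.end) for o in twice
    ]


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(
        st.tuples(st.integers(0, 500), st.integers(1, 60)), min_size=1, max_size=30
    ),
    st.integers(0, 40),
)
def test_merge_within_members_conserve_input(pairs, gap):
    ivs = [GenomicInterval("chr1", s, s + ln) for s, ln in pairs]
    out = merge_within(IntervalSet(ivs), gap)
    members = [m for o in out for m in o.members]
    assert sorted((m.start, m.end) for m in members) == sorted(
        (i.start, i.end) for i in ivs
    )


# ---------------------------------------------------------------------------
# signal_sum
# ---------------------------------------------------------------------------

def test_signal_sum_uniform_and_full_exclusion():
    track = SignalTrack({"chr1": [(0, 100, 2.0)]})
    region = GenomicInterval("chr1", 10, 60)
    assert signal_sum(track, region) == pytest.approx(100.0)
    excl = IntervalSet([GenomicInterval("chr1", 10, 60)])
    assert signal_sum(track, region, excl) == 0.0


def test_signal_sum_matches_per_base_bruteforce():
    rng = np.random.default_rng(11)
    runs, pos = [], 0
    dense = np.zeros(5000)
    while pos < 4500:
        ln = int(rng.integers(10, 200))
        gap = int(rng.integers(0, 100))
        v = float(rng.uniform(0, 5))
        runs.append((pos, min(pos + ln, 5000), v))
        dense[pos : min(pos + ln, 5000)] = v
        pos += ln + gap
    track = SignalTrack({"chr1": runs}, scale=1.7)
    excl_ivs = [GenomicInterval("chr1", 100, 300), GenomicInterval("chr1", 900, 950)]
    mask = np.ones(5000, bool)
    for e in excl_ivs:
        mask[e.start : e.end] = False
    for _ in range(10):
        s = int(rng.integers(0, 4000))
        e = s + int(rng.integers(1, 900))
        region = GenomicInterval("chr1", s, e)
        expected = 1.7 * float((dense[s:e] * mask[s:e]).sum())
        assert abs(signal_sum(track, region, IntervalSet(excl_ivs)) - expected) < 1e-9


def test_signal_sum_additive_over_partition():
    track = SignalTrack({"chr1": [(0, 50, 1.0), (60, 200, 3.5), (250, 400, 0.7)]})
    whole = signal_sum(track, GenomicInterval("chr1", 10, 390))
    parts = sum(
        signal_sum(track, GenomicInterval("chr1", a, b))
        for a, b in [(10, 100), (100, 222), (222, 390)]
    )
    assert whole == pytest.approx(parts, rel=1e-12)


def test_signal_track_rejects_overlapping_runs():
    with pytest.raises(ValueError, match="overlap"):
        SignalTrack({"chr1": [(0, 100, 1.0), (50, 150, 1.0)]})
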