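"""Genomic interval algebra, genome layout, signal tracks and flat-file I/O.

All coordinates are 0-based half-open (BED convention) internally.  Variant
positions arrive 1-based from TSV input and are converted on load by the
modules that read them.  The chromosome order of a :class:`GenomeLayout` is
canonical: it is the concatenation order used by the circular permutation
test, never lexicographic.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomeLayout",
    "GenomicInterval",
    "IntervalSet",
    "StitchedRegion",
    "SignalTrack",
    "OverlapResult",
    "read_bed",
    "write_bed",
    "extend",
    "overlaps",
    "merge_within",
    "signal_sum",
    "subtract_intervals",
]


class BedFormatError(ValueError):
    """A malformed line in a BED/bedGraph/chrom-sizes file."""


# ---------------------------------------------------------------------------
# Layout and intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths.

    The declared order is the circularization order for the permutation
    test and the canonical sort order for every :class:`IntervalSet`.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    @property
    def lengths(self) -> Mapping[str, int]:
        return dict(self.chromosomes)

    def rank(self, chrom: str) -> int:
        try:
            return self.names.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def length(self, chrom: str) -> int:
        for name, ln in self.chromosomes:
            if name == chrom:
                return ln
        raise KeyError(f"unknown chromosome {chrom!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "GenomeLayout":
        chroms: list[tuple[str, int]] = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise BedFormatError(f"{path}:{lineno}: expected 'name<TAB>length'")
            try:
                chroms.append((parts[0], int(parts[1])))
            except ValueError:
                raise BedFormatError(f"{path}:{lineno}: bad length {parts[1]!r}") from None
        return cls(tuple(chroms))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{name}\t{length}\n" for name, length in self.chromosomes)
        )


@dataclass(frozen=True, order=False)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def _sort_key(layout: GenomeLayout | None):
    if layout is None:
        return lambda iv: (iv.chrom, iv.start, iv.end, iv.label or "")
    ranks = {name: i for i, name in enumerate(layout.names)}
    return lambda iv: (ranks[iv.chrom], iv.start, iv.end, iv.label or "")


class IntervalSet:
    """A canonically sorted collection of :class:`GenomicInterval`.

    Sorted by (chromosome order, start, end); the chromosome order is taken
    from the layout when supplied, lexicographic otherwise.  Duplicates are
    permitted.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        layout: GenomeLayout | None = None,
    ) -> None:
        ivs = list(intervals)
        if layout is not None:
            lengths = layout.lengths
            for iv in ivs:
                if iv.chrom not in lengths:
                    raise KeyError(f"interval on unknown chromosome {iv.chrom!r}")
                if iv.end > lengths[iv.chrom]:
                    raise ValueError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                        f"chromosome length {lengths[iv.chrom]}"
                    )
        ivs.sort(key=_sort_key(layout))
        self.intervals: tuple[GenomicInterval, ...] = tuple(ivs)
        self.layout = layout
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet({len(self.intervals)} intervals)"

    def by_chrom(self) -> Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """chrom -> (starts, ends, indices-into-self), each sorted by start."""
        if self._by_chrom is None:
            grouped: dict[str, list[int]] = {}
            for i, iv in enumerate(self.intervals):
                grouped.setdefault(iv.chrom, []).append(i)
            self._by_chrom = {
                chrom: (
                    np.array([self.intervals[i].start for i in idx], dtype=np.int64),
                    np.array([self.intervals[i].end for i in idx], dtype=np.int64),
                    np.array(idx, dtype=np.int64),
                )
                for chrom, idx in grouped.items()
            }
        return self._by_chrom

    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, layout: GenomeLayout | None = None) -> IntervalSet:
    """Read a BED3+ file (optional 4th label column) into an IntervalSet."""
    intervals: list[GenomicInterval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise BedFormatError(f"{path}:{lineno}: expected at least 3 columns")
        chrom = parts[0]
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            raise BedFormatError(f"{path}:{lineno}: non-integer coordinates") from None
        if start >= end:
            raise BedFormatError(
                f"{path}:{lineno}: empty or inverted interval {start}-{end}"
            )
        label = parts[3] if len(parts) > 3 and parts[3] != "" else None
        try:
            intervals.append(GenomicInterval(chrom, start, end, label))
        except ValueError as exc:
            raise BedFormatError(f"{path}:{lineno}: {exc}") from None
    try:
        return IntervalSet(intervals, layout=layout)
    except (KeyError, ValueError) as exc:
        raise BedFormatError(f"{path}: {exc}") from None


def write_bed(intervals: IntervalSet | Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.label is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


# ---------------------------------------------------------------------------
# Interval operations
# ---------------------------------------------------------------------------

def extend(intervals: IntervalSet, pad: int, layout: GenomeLayout) -> IntervalSet:
    """Grow every interval by ``pad`` bp on both sides, clamped to the chromosome."""
    if pad < 0:
        raise ValueError("pad must be >= 0")
    lengths = layout.lengths
    out = [
        GenomicInterval(
            iv.chrom,
            max(0, iv.start - pad),
            min(lengths[iv.chrom], iv.end + pad),
            iv.label,
        )
        for iv in intervals
    ]
    return IntervalSet(out, layout=layout)


@dataclass
class OverlapResult:
    """Per-interval-of-a hit flags plus all matched (a, b) index pairs."""

    flags: np.ndarray
    pairs: list[tuple[int, int]]


def overlaps(a: IntervalSet, b: IntervalSet, min_bp: int = 1) -> OverlapResult:
    """Mark each interval of ``a`` that shares >= ``min_bp`` bases with some
    interval of ``b``; list all such pairs (indices into the canonical orders)."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    flags = np.zeros(len(a), dtype=bool)
    pairs: list[tuple[int, int]] = []
    b_chrom = b.by_chrom()
    for chrom, (a_starts, a_ends, a_idx) in a.by_chrom().items():
        if chrom not in b_chrom:
            continue
        bs, be, b_idx = b_chrom[chrom]
        for s, e, ia in zip(a_starts, a_ends, a_idx):
            hi = int(np.searchsorted(bs, e, side="left"))
            if hi == 0:
                continue
            ov = np.minimum(be[:hi], e) - np.maximum(bs[:hi], s)
            hit = np.nonzero(ov >= min_bp)[0]
            if hit.size:
                flags[ia] = True
                pairs.extend((int(ia), int(b_idx[j])) for j in hit)
    pairs.sort()
    return OverlapResult(flags=flags, pairs=pairs)


@dataclass(frozen=True)
class StitchedRegion:
    """A cluster of intervals stitched together, with its members recorded."""

    chrom: str
    start: int
    end: int
    members: tuple[GenomicInterval, ...]

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start


def merge_within(intervals: IntervalSet, max_gap: int) -> list[StitchedRegion]:
    """Single-linkage stitch: consecutive sorted intervals join one cluster iff
    ``start_next - end_prev <= max_gap``.  Returns clusters in canonical order."""
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out: list[StitchedRegion] = []
    cur: list[GenomicInterval] = []
    cur_end = None
    cur_chrom = None

    def flush() -> None:
        if cur:
            out.append(
                StitchedRegion(
                    cur_chrom,
                    min(iv.start for iv in cur),
                    max(iv.end for iv in cur),
                    tuple(cur),
                )
            )

    for iv in intervals:
        if cur and iv.chrom == cur_chrom and iv.start - cur_end <= max_gap:
            cur.append(iv)
            cur_end = max(cur_end, iv.end)
        else:
            flush()
            cur = [iv]
            cur_chrom = iv.chrom
            cur_end = iv.end
    flush()
    return out


def subtract_intervals(
    interval: GenomicInterval, exclude: Iterable[GenomicInterval]
) -> list[tuple[int, int]]:
    """Coordinates of ``interval`` minus any bases covered by ``exclude``."""
    blocks = sorted(
        (max(interval.start, iv.start), min(interval.end, iv.end))
        for iv in exclude
        if iv.chrom == interval.chrom and iv.start < interval.end and iv.end > interval.start
    )
    pieces: list[tuple[int, int]] = []
    pos = interval.start
    for s, e in blocks:
        if s > pos:
            pieces.append((pos, s))
        pos = max(pos, e)
    if pos < interval.end:
        pieces.append((pos, interval.end))
    return pieces


# ---------------------------------------------------------------------------
# Signal tracks
# ---------------------------------------------------------------------------

class SignalTrack:
    """Per-chromosome runs of (start, end, value) signal density per bp.

    Runs must be non-overlapping within a chromosome; uncovered bases have
    value 0.  ``scale`` is a library-size scale factor applied at summation
    time so that treatment and input tracks are comparable.
    """

    def __init__(
        self,
        runs: Mapping[str, Sequence[tuple[int, int, float]]],
        scale: float = 1.0,
    ) -> None:
        if not np.isfinite(scale) or scale <= 0:
            raise ValueError("scale must be finite and > 0")
        self.scale = float(scale)
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, rs in runs.items():
            rs = sorted(rs)
            starts = np.array([r[0] for r in rs], dtype=np.int64)
            ends = np.array([r[1] for r in rs], dtype=np.int64)
            values = np.array([r[2] for r in rs], dtype=np.float64)
            if np.any(ends <= starts):
                raise ValueError(f"empty run on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping runs on {chrom}")
            if not np.all(np.isfinite(values)) or np.any(values < 0):
                raise ValueError(f"non-finite or negative signal value on {chrom}")
            self._runs[chrom] = (starts, ends, values)

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self._runs)

    def runs(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._runs.get(
            chrom,
            (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.float64)),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        if self.scale != other.scale or set(self._runs) != set(other._runs):
            return False
        return all(
            all(np.array_equal(x, y) for x, y in zip(self._runs[c], other._runs[c]))
            for c in self._runs
        )

    @classmethod
    def from_bedgraph(cls, path: str | Path, scale: float = 1.0) -> "SignalTrack":
        runs: dict[str, list[tuple[int, int, float]]] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise BedFormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                runs.setdefault(parts[0], []).append(
                    (int(parts[1]), int(parts[2]), float(parts[3]))
                )
            except ValueError:
                raise BedFormatError(f"{path}:{lineno}: bad bedGraph record") from None
        return cls(runs, scale=scale)

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self._runs:
                starts, ends, values = self._runs[chrom]
                for s, e, v in zip(starts, ends, values):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.17g}\n")


def signal_sum(
    track: SignalTrack,
    interval: GenomicInterval,
    exclude: IntervalSet | Iterable[GenomicInterval] | None = None,
) -> float:
    """Sum of value x covered-bp over ``interval`` minus excluded bases,
    multiplied by the track's scale factor."""
    pieces = (
        [(interval.start, interval.end)]
        if exclude is None
        else subtract_intervals(interval, exclude)
    )
    starts, ends, values = track.runs(interval.chrom)
    total = 0.0
    for s, e in pieces:
        lo = int(np.searchsorted(ends, s, side="right"))
        hi = int(np.searchsorted(starts, e, side="left"))
        if hi > lo:
            ov = np.minimum(ends[lo:hi], e) - np.maximum(starts[lo:hi], s)
            total += float(np.dot(np.clip(ov, 0, None), values[lo:hi]))
    return total * track.scale
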