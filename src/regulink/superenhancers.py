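"""Super-enhancer calling by H3K27ac stitching and rank-curve thresholding.

Enhancer-state segments are first cleared of anything touching promoter
states (±1 kb), then stitched when within 12.5 kb of each other.  Each
stitched (or single) region is scored by its background-subtracted H3K27ac
signal, scores are ranked, and the super/typical split is made by the
classical rank-curve geometric rule: on the ascending curve with ranks and
scores both scaled to [0, 1], the cutoff is the point where a unit-slope
tangent touches the curve, i.e. the index maximising (x - y).  Regions
scoring strictly above the cutoff score are super enhancers (SEs); their
member segments are SE constituents, everything else is an "other
enhancer" whose members are typical enhancers (TEs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import (
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    SignalTrack,
    StitchedRegion,
    extend,
    merge_within,
    overlaps,
    signal_sum,
)

__all__ = [
    "SECall",
    "SEThreshold",
    "SEOverlap",
    "filter_promoter_enhancers",
    "rank_cutoff_index",
    "call_superenhancers",
    "se_overlap",
    "trace_se_opening",
    "expression_by_connectivity",
]


@dataclass
class SECall:
    """A stitched enhancer region with its score, rank and super flag."""

    region: GenomicInterval
    constituents: tuple[GenomicInterval, ...]
    score: float
    rank: int  # 1 = highest score
    is_super: bool


@dataclass
class SEThreshold:
    """Cutoff location on the ascending scaled rank curve."""

    cutoff_index: int | None  # index into the ascending score vector
    cutoff_score: float | None


def filter_promoter_enhancers(
    enhancers: IntervalSet,
    promoter_states: IntervalSet,
    layout: GenomeLayout,
    pad: int = 1000,
) -> IntervalSet:
    """Remove enhancers overlapping (promoter states extended by ``pad``) by
    >=1 bp, to avoid confounding enhancer and promoter acetylation."""
    padded = extend(promoter_states, pad, layout) if pad else promoter_states
    hit = overlaps(enhancers, padded, min_bp=1).flags
    return IntervalSet(
        [iv for iv, h in zip(enhancers, hit) if not h], layout=layout
    )


def rank_cutoff_index(scores_ascending: np.ndarray) -> int:
    """Index maximising (x - y) on the ascending curve scaled to [0, 1]^2.

    This is where a slope-1 tangent touches the scaled curve.  With a flat
    curve (zero score range) the last index is returned, so nothing scores
    strictly above the cutoff.
    """
    s = np.asarray(scores_ascending, dtype=float)
    n = len(s)
    if n < 2:
        return n - 1
    x = np.arange(n) / (n - 1)
    rng = s[-1] - s[0]
    y = (s - s[0]) / rng if rng > 0 else np.zeros(n)
    return int(np.argmax(x - y))


def call_superenhancers(
    enhancers: IntervalSet,
    h3k27ac: SignalTrack,
    input_signal: SignalTrack,
    exclude: IntervalSet | None = None,
    max_gap: int = 12_500,
) -> tuple[list[SECall], SEThreshold]:
    """Stitch promoter-filtered enhancers, score, rank, and split SE vs TE.

    Scores are ``max(0, treatment - input)`` summed over each stitched
    region (bases inside ``exclude`` are ignored).  Ties in score are broken
    by genomic position (earlier = better rank).  With fewer than 3 regions
    or an all-zero signal no SE is called and a warning is emitted.
    """
    if len(enhancers) == 0:
        raise ValueError("cannot call super enhancers from an empty enhancer set")
    stitched = merge_within(enhancers, max_gap)
    scores = np.array(
        [
            max(
                0.0,
                signal_sum(h3k27ac, st.interval, exclude)
                - signal_sum(input_signal, st.interval, exclude),
            )
            for st in stitched
        ]
    )

    # descending rank with positional tie-break; stitched is in canonical order
    order_desc = sorted(range(len(stitched)), key=lambda i: (-scores[i], i))
    ranks = np.empty(len(stitched), dtype=int)
    for r, i in enumerate(order_desc, start=1):
        ranks[i] = r

    degenerate = len(stitched) < 3
    if degenerate:
        warnings.warn(
            f"only {len(stitched)} stitched region(s): rank-curve cutoff is "
            "undefined, no super enhancer called",
            stacklevel=2,
        )
        threshold = SEThreshold(cutoff_index=None, cutoff_score=None)
        cutoff_score = np.inf
    else:
        asc = np.sort(scores)
        idx = rank_cutoff_index(asc)
        cutoff_score = float(asc[idx])
        threshold = SEThreshold(cutoff_index=idx, cutoff_score=cutoff_score)
        if scores.max() == 0.0:
            warnings.warn("all region scores are zero; no super enhancer called",
                          stacklevel=2)

    calls = [
        SECall(
            region=st.interval,
            constituents=st.members,
            score=float(scores[i]),
            rank=int(ranks[i]),
            is_super=bool(scores[i] > cutoff_score),
        )
        for i, st in enumerate(stitched)
    ]
    return calls, threshold


@dataclass
class SEOverlap:
    """Shared / cell-type-specific partition of two SE sets."""

    shared_a: list[int]
    shared_b: list[int]
    a_specific: list[int]
    b_specific: list[int]
    pairs: list[tuple[int, int]]


def se_overlap(
    se_a: list[SECall], se_b: list[SECall], min_frac: float = 0.5
) -> SEOverlap:
    """Mark an SE as shared iff some SE of the other set overlaps it by at
    least ``min_frac`` of either SE's length (inclusive symmetric rule)."""
    shared_a: set[int] = set()
    shared_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for i, a in enumerate(se_a):
        for j, b in enumerate(se_b):
            ov = a.region.overlap_bp(b.region)
            if ov == 0:
                continue
            if ov >= min_frac * len(a.region) or ov >= min_frac * len(b.region):
                shared_a.add(i)
                shared_b.add(j)
                pairs.append((i, j))
    return SEOverlap(
        shared_a=sorted(shared_a),
        shared_b=sorted(shared_b),
        a_specific=[i for i in range(len(se_a)) if i not in shared_a],
        b_specific=[j for j in range(len(se_b)) if j not in shared_b],
        pairs=pairs,
    )


def trace_se_opening(
    se_calls: list[SECall],
    terminal_open_chromatin: IntervalSet,
    progenitor_peaks: dict[str, IntervalSet],
    layout: GenomeLayout,
    pad: int = 500,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trace SE constituents back through differentiation.

    Each constituent (±``pad``) is overlapped with the terminal cell's open
    chromatin; each overlapped peak's own progenitor presence (>=1 bp,
    unpadded) gives the constituent its (HSC, CMP, MEP) pattern.  An SE is
    "fully open in progenitors" iff every constituent overlaps some open
    region present in HSC, CMP and MEP.

    Returns (per-constituent table, per-SE table).
    """
    peak_presence = {
        cell: overlaps(terminal_open_chromatin, progenitor_peaks[cell], min_bp=1).flags
        for cell in ("HSC", "CMP", "MEP")
    }
    cons_rows = []
    se_rows = []
    for s_idx, call in enumerate(se_calls):
        all_full = True
        for c in call.constituents:
            cset = IntervalSet([c], layout=layout)
            padded = extend(cset, pad, layout)
            res = overlaps(padded, terminal_open_chromatin, min_bp=1)
            peak_js = [j for (_, j) in res.pairs]
            bits = {
                cell: bool(any(peak_presence[cell][j] for j in peak_js))
                for cell in ("HSC", "CMP", "MEP")
            }
            full = any(
                peak_presence["HSC"][j]
                and peak_presence["CMP"][j]
                and peak_presence["MEP"][j]
                for j in peak_js
            )
            all_full = all_full and full
            cons_rows.append(
                {
                    "se_index": s_idx,
                    "constituent": c.label or f"{c.chrom}:{c.start}-{c.end}",
                    "open_in_terminal": bool(peak_js),
                    "hsc": bits["HSC"],
                    "cmp": bits["CMP"],
                    "mep": bits["MEP"],
                    "fully_open": full,
                }
            )
        se_rows.append(
            {
                "se_index": s_idx,
                "region": f"{call.region.chrom}:{call.region.start}-{call.region.end}",
                "is_super": call.is_super,
                "n_constituents": len(call.constituents),
                "fully_open_in_progenitors": bool(all_full and call.constituents),
            }
        )
    return pd.DataFrame(cons_rows), pd.DataFrame(se_rows)


def expression_by_connectivity(
    genes: pd.DataFrame,
    gene_links: dict[str, set[str]],
    se_constituent_labels: set[str],
    typical_enhancer_labels: set[str],
) -> tuple[pd.DataFrame, int]:
    """Median expression by (number of linked enhancers, SE/TE composition).

    ``gene_links`` maps gene id -> labels of linked enhancer segments.
    Genes without links are excluded from the buckets and returned as an
    "unlinked" tally.
    """
    fpkm = dict(zip(genes.gene_id, genes.fpkm))
    buckets: dict[tuple[int, str], list[float]] = {}
    n_unlinked = 0
    for gid in genes.gene_id:
        links = gene_links.get(gid, set())
        if not links:
            n_unlinked += 1
            continue
        n_se = sum(1 for l in links if l in se_constituent_labels)
        n_te = sum(1 for l in links if l in typical_enhancer_labels)
        unknown = links - se_constituent_labels - typical_enhancer_labels
        if unknown:
            raise ValueError(f"unknown enhancer label(s) linked to {gid}: {sorted(unknown)[:3]}")
        comp = "SE-only" if n_te == 0 else ("TE-only" if n_se == 0 else "mixed")
        buckets.setdefault((len(links), comp), []).append(float(fpkm[gid]))
    rows = [
        {
            "n_linked_enhancers": n,
            "composition": comp,
            "n_genes": len(vals),
            "median_fpkm": float(np.median(vals)),
        }
        for (n, comp), vals in sorted(buckets.items())
    ]
    return pd.DataFrame(rows), n_unlinked
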