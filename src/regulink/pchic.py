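"""Promoter-capture Hi-C model: fragments, baits, scored interactions and
region -> gene lookup.

Fragments tile each chromosome without overlap (a HindIII-like grid).  A
bait is a fragment annotated with the genes whose transcription start sites
it overlaps.  Interactions are stored directed (bait -> other end) with a
continuous confidence score; an interaction is "called" at score >= 5
(inclusive), and bait-bait pairs may appear once in either direction - both
directions are honoured at query time.

Query semantics for a region of interest: take every fragment it overlaps
(>=1 bp); a fragment on the prey side of a called interaction contributes
the genes of the interacting bait; if the fragment is itself a bait, called
bait-bait interactions in either direction contribute the other bait's
genes; interactions where the fragment is the bait and the partner is a
non-bait prey contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genome import GenomicInterval, IntervalSet

__all__ = [
    "FragmentIndex",
    "build_baits",
    "map_to_fragments",
    "interacting_genes",
    "interacting_genes_bulk",
    "interaction_gene_lookup",
    "fragment_feature_table",
    "read_interactions",
    "write_interactions",
]

INTERACTION_COLUMNS = [
    "bait_chr", "bait_start", "bait_end", "bait_id", "bait_genes",
    "oe_chr", "oe_start", "oe_end", "oe_id", "score",
]


class FragmentIndex:
    """Restriction fragments with unique ids, indexed per chromosome."""

    def __init__(self, fragments: IntervalSet) -> None:
        seen: set[str] = set()
        for iv in fragments:
            if not iv.label:
                raise ValueError("every fragment needs an id (BED4 label)")
            if iv.label in seen:
                raise ValueError(f"duplicate fragment id {iv.label!r}")
            seen.add(iv.label)
        for chrom, (starts, ends, _) in fragments.by_chrom().items():
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"fragments overlap on {chrom}")
        self.intervals = fragments
        self.by_id: dict[str, GenomicInterval] = {iv.label: iv for iv in fragments}

    def __len__(self) -> int:
        return len(self.intervals)

    def overlapping(self, region: GenomicInterval) -> list[GenomicInterval]:
        chroms = self.intervals.by_chrom()
        if region.chrom not in chroms:
            raise KeyError(f"region on unknown chromosome {region.chrom!r}")
        starts, ends, idx = chroms[region.chrom]
        lo = int(np.searchsorted(ends, region.start, side="right"))
        hi = int(np.searchsorted(starts, region.end, side="left"))
        return [self.intervals[int(i)] for i in idx[lo:hi]]


def map_to_fragments(region: GenomicInterval, fragments: FragmentIndex) -> list[str]:
    """Ids of all fragments overlapping the region by >=1 bp, in genomic order."""
    return [iv.label for iv in fragments.overlapping(region)]


def build_baits(
    fragments: FragmentIndex, genes: pd.DataFrame
) -> dict[str, tuple[str, ...]]:
    """fragment id -> genes whose TSSs the fragment overlaps (from a gene
    table with ';'-separated TSS positions)."""
    baits: dict[str, list[str]] = {}
    for r in genes.itertuples():
        for t in str(r.tss).split(";"):
            pos = int(t)
            for fr in fragments.overlapping(GenomicInterval(r.chrom, pos, pos + 1)):
                lst = baits.setdefault(fr.label, [])
                if r.gene_id not in lst:
                    lst.append(r.gene_id)
    return {k: tuple(v) for k, v in baits.items()}


def interacting_genes(
    region: GenomicInterval,
    fragments: FragmentIndex,
    baits: Mapping[str, tuple[str, ...]],
    interactions: pd.DataFrame,
    score_min: float = 5.0,
) -> set[str]:
    """Genes whose promoters contact the region through called interactions."""
    if score_min < 0:
        raise ValueError("score_min must be >= 0")
    frags = set(map_to_fragments(region, fragments))
    if not frags:
        return set()
    called = interactions[interactions.score >= score_min]
    genes: set[str] = set()
    for r in called.itertuples():
        if r.oe_id in frags:
            genes.update(baits.get(r.bait_id, ()))
        # bait-bait interaction recorded with our fragment on the bait side:
        # honour the reverse direction iff the other end is itself a bait
        if r.bait_id in frags and r.oe_id in baits:
            genes.update(baits[r.oe_id])
    return genes


def interaction_gene_lookup(
    baits: Mapping[str, tuple[str, ...]],
    interactions: pd.DataFrame,
    score_min: float = 5.0,
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Precomputed lookups for bulk queries: fragment-as-prey -> bait genes,
    and fragment-as-bait -> partner-bait genes (bait-bait pairs only)."""
    called = interactions[interactions.score >= score_min]
    prey_to: dict[str, set[str]] = {}
    bait_to: dict[str, set[str]] = {}
    for r in called.itertuples():
        prey_to.setdefault(r.oe_id, set()).update(baits.get(r.bait_id, ()))
        if r.oe_id in baits:
            bait_to.setdefault(r.bait_id, set()).update(baits[r.oe_id])
    return prey_to, bait_to


def interacting_genes_bulk(
    regions: Iterable[GenomicInterval],
    fragments: FragmentIndex,
    baits: Mapping[str, tuple[str, ...]],
    interactions: pd.DataFrame,
    score_min: float = 5.0,
) -> list[set[str]]:
    """Vector form of :func:`interacting_genes` over many regions."""
    prey_to, bait_to = interaction_gene_lookup(baits, interactions, score_min)
    out = []
    for region in regions:
        genes: set[str] = set()
        for fid in map_to_fragments(region, fragments):
            genes |= prey_to.get(fid, set())
            genes |= bait_to.get(fid, set())
        out.append(genes)
    return out


def fragment_feature_table(
    fragments: FragmentIndex,
    interactions: pd.DataFrame,
    feature_sets: Mapping[str, IntervalSet],
    score_min: float = 5.0,
) -> pd.DataFrame:
    """Per-fragment export: length, called-interaction degree, and the number
    of intervals of each feature set overlapping the fragment.  No model is
    fitted; the table is the deliverable."""
    called = interactions[interactions.score >= score_min]
    partners: dict[str, set[str]] = {iv.label: set() for iv in fragments.intervals}
    for r in called.itertuples():
        if r.bait_id in partners:
            partners[r.bait_id].add(r.oe_id)
        if r.oe_id in partners:
            partners[r.oe_id].add(r.bait_id)
    rows = []
    feature_hits: dict[str, dict[str, int]] = {}
    for name, iset in feature_sets.items():
        counts: dict[str, int] = {}
        chroms = iset.by_chrom()
        for iv in fragments.intervals:
            if iv.chrom in chroms:
                starts, ends, _ = chroms[iv.chrom]
                lo = int(np.searchsorted(ends, iv.start, side="right"))
                hi = int(np.searchsorted(starts, iv.end, side="left"))
                counts[iv.label] = max(0, hi - lo)
            else:
                counts[iv.label] = 0
        feature_hits[name] = counts
    for iv in fragments.intervals:
        row = {
            "fragment_id": iv.label,
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
            "length": len(iv),
            "degree": len(partners[iv.label]),
        }
        for name in feature_sets:
            row[f"n_{name}"] = feature_hits[name][iv.label]
        rows.append(row)
    return pd.DataFrame(rows)


def read_interactions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, float_precision="round_trip")
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing interaction column(s) {missing}")
    return df[INTERACTION_COLUMNS]


def write_interactions(df: pd.DataFrame, path: str | Path) -> None:
    df[INTERACTION_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.17g")
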