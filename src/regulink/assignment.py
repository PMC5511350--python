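"""Tiered assignment of GWAS sentinel variants to genes.

The decision tree mirrors the multi-step promoter-capture Hi-C annotation:

1. coding — an exonic/splice variant keeps its VEP gene, provided the gene
   is expressed (FPKM >= 1) and the variant is not inside an enhancer
   segment;
2. promoter — the variant lies in a promoter-state segment ±1 kb that
   contains an annotated TSS; the genes of those TSSs are assigned;
3. enhancer_plus_bait — an expressed exonic variant inside an enhancer
   keeps its gene and additionally gains the genes of the interacting
   PCHi-C bait(s);
4. fragment_interaction — the variant's restriction fragment(s) contact
   bait(s) at interaction score >= 5; the baits' genes are assigned.

Variants still unassigned enter the LD cascade: their proxies at r² = 1,
then >= 0.9, then >= 0.8 are pushed through steps 2/4 and the union of gene
sets at the first successful level is used.  Finally, variants with no
assignable proxy are checked against PCHi-C baits ±10 kb (short-range
interactions are systematically under-detected by the capture design).
Unassignable variants are reported with tier ``unassigned``, never dropped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeLayout, GenomicInterval, IntervalSet, extend
from .pchic import FragmentIndex, interacting_genes
from .simulate import overlapping_any

__all__ = [
    "TIERS",
    "AssignmentResources",
    "AssignmentResult",
    "EnrichmentResult",
    "assign_variant",
    "assign_all",
    "se_te_variant_enrichment",
]

TIERS = (
    "coding",
    "promoter",
    "enhancer_plus_bait",
    "fragment_interaction",
    "ld_r2_1",
    "ld_r2_09",
    "ld_r2_08",
    "bait_10kb",
    "unassigned",
)

LD_LEVELS = (("ld_r2_1", 1.0), ("ld_r2_09", 0.9), ("ld_r2_08", 0.8))


@dataclass
class AssignmentResources:
    """Everything the decision tree consults."""

    genes: pd.DataFrame  # gene_id, chrom, tss (";"-separated), fpkm
    promoter_segments: IntervalSet
    enhancer_segments: IntervalSet
    fragments: FragmentIndex
    baits: Mapping[str, tuple[str, ...]]
    interactions: pd.DataFrame
    ld: pd.DataFrame  # sentinel_id, proxy_id, proxy_chrom, proxy_pos0, r2
    layout: GenomeLayout
    score_min: float = 5.0
    promoter_pad: int = 1000
    bait_pad: int = 10_000

    def __post_init__(self) -> None:
        self._fpkm = dict(zip(self.genes.gene_id, self.genes.fpkm.astype(float)))
        self._tss: list[tuple[str, int, str]] = []  # (chrom, pos, gene)
        self._mean_tss: dict[str, tuple[str, float]] = {}
        for r in self.genes.itertuples():
            tsses = [int(t) for t in str(r.tss).split(";")]
            for t in tsses:
                self._tss.append((r.chrom, t, r.gene_id))
            self._mean_tss[r.gene_id] = (r.chrom, sum(tsses) / len(tsses))
        self._padded_promoters = extend(
            self.promoter_segments, self.promoter_pad, self.layout
        )
        self._padded_baits = {
            fid: GenomicInterval(
                iv.chrom,
                max(0, iv.start - self.bait_pad),
                min(self.layout.length(iv.chrom), iv.end + self.bait_pad),
            )
            for fid, iv in self.fragments.by_id.items()
            if fid in self.baits
        }

    def fpkm(self, gene_id: str) -> float | None:
        return self._fpkm.get(gene_id)

    def mean_tss(self, gene_id: str) -> tuple[str, float]:
        return self._mean_tss[gene_id]

    def promoter_genes_at(self, chrom: str, pos: int) -> set[str]:
        genes: set[str] = set()
        for seg in self._padded_promoters:
            if seg.chrom == chrom and seg.start <= pos < seg.end:
                genes.update(
                    g for (c, t, g) in self._tss
                    if c == seg.chrom and seg.start <= t < seg.end
                )
        return genes

    def nearest_gene(self, chrom: str, pos: int) -> str | None:
        best, best_d = None, math.inf
        for gid, (gchrom, mt) in self._mean_tss.items():
            if gchrom != chrom:
                continue
            d = abs(pos - mt)
            if d < best_d or (d == best_d and (best is None or gid < best)):
                best, best_d = gid, d
        return best


@dataclass
class AssignmentResult:
    sentinel_id: str
    genes: tuple[str, ...]
    tier: str
    proxy_ids: tuple[str, ...] = ()
    distances: dict[str, float] = field(default_factory=dict)  # gene -> bp to mean TSS

    @property
    def assigned(self) -> bool:
        return self.tier != "unassigned"


def _steps_1_to_4(
    res: AssignmentResources,
    chrom: str,
    pos: int,
    consequence: str,
    vep_gene: str,
) -> tuple[set[str], str | None]:
    """One pass of the in-place decision tree (no LD, no bait fallback)."""
    point = GenomicInterval(chrom, pos, pos + 1)
    if consequence == "exonic_or_splice" and vep_gene:
        fpkm = res.fpkm(vep_gene)
        if fpkm is None:
            warnings.warn(
                f"no FPKM for VEP gene {vep_gene!r}; treating as not expressed",
                stacklevel=2,
            )
            fpkm = 0.0
        expressed = fpkm >= 1.0
        in_enhancer = overlapping_any(res.enhancer_segments, point)
        if expressed and not in_enhancer:
            return {vep_gene}, "coding"
        if expressed and in_enhancer:
            bait_genes = interacting_genes(
                point, res.fragments, res.baits, res.interactions, res.score_min
            )
            return {vep_gene} | bait_genes, "enhancer_plus_bait"
        # unexpressed exonic falls through to the non-coding logic
    genes = res.promoter_genes_at(chrom, pos)
    if genes:
        return genes, "promoter"
    genes = interacting_genes(
        point, res.fragments, res.baits, res.interactions, res.score_min
    )
    if genes:
        return genes, "fragment_interaction"
    return set(), None


def assign_variant(variant, res: AssignmentResources) -> AssignmentResult:
    """Assign one sentinel variant (a row with id/chrom/pos0/consequence/
    vep_gene attributes) to its most probable target gene(s)."""
    chrom, pos = variant.chrom, int(variant.pos0)
    if chrom not in res.layout.names or not 0 <= pos < res.layout.length(chrom):
        raise ValueError(f"variant {variant.id} at {chrom}:{pos} is off the layout")

    genes, tier = _steps_1_to_4(
        res, chrom, pos, str(variant.consequence), str(variant.vep_gene or "")
    )
    proxy_ids: tuple[str, ...] = ()

    if not genes:
        prox = res.ld[res.ld.sentinel_id == variant.id]
        for level, thr in LD_LEVELS:
            level_genes: set[str] = set()
            level_proxies: list[str] = []
            for p in prox[prox.r2 >= thr].itertuples():
                g, _ = _steps_1_to_4(
                    res, p.proxy_chrom, int(p.proxy_pos0), "intronic_or_intergenic", ""
                )
                if g:
                    level_genes |= g
                    level_proxies.append(p.proxy_id)
            if level_genes:
                genes, tier, proxy_ids = level_genes, level, tuple(level_proxies)
                break

    if not genes:
        point = GenomicInterval(chrom, pos, pos + 1)
        hit = {
            g
            for fid, padded in res._padded_baits.items()
            if padded.overlap_bp(point) > 0
            for g in res.baits[fid]
        }
        if hit:
            genes, tier = hit, "bait_10kb"

    if not genes:
        return AssignmentResult(variant.id, (), "unassigned")

    distances = {}
    for g in sorted(genes):
        gchrom, mt = res.mean_tss(g)
        distances[g] = abs(pos - mt) if gchrom == chrom else math.nan
    return AssignmentResult(variant.id, tuple(sorted(genes)), tier, proxy_ids, distances)


def assign_all(
    variants: pd.DataFrame, res: AssignmentResources
) -> tuple[list[AssignmentResult], dict]:
    """Assign every variant; summarise tiers, nearest-gene classification and
    the variant -> assigned-TSS distance distribution."""
    results = [assign_variant(v, res) for v in variants.itertuples()]
    tier_counts = {t: 0 for t in TIERS}
    classes = {"nearest_only": 0, "nearest_plus_distal": 0, "distal_only": 0}
    dist_assigned: list[float] = []
    dist_nearest: list[float] = []
    pos_by_id = {r.id: (r.chrom, int(r.pos0)) for r in variants.itertuples()}
    for r in results:
        tier_counts[r.tier] += 1
        if not r.assigned:
            continue
        chrom, pos = pos_by_id[r.sentinel_id]
        nearest = res.nearest_gene(chrom, pos)
        if nearest is not None:
            _, mt = res.mean_tss(nearest)
            dist_nearest.append(abs(pos - mt))
            if set(r.genes) == {nearest}:
                classes["nearest_only"] += 1
            elif nearest in r.genes:
                classes["nearest_plus_distal"] += 1
            else:
                classes["distal_only"] += 1
        dist_assigned.extend(d for d in r.distances.values() if not math.isnan(d))
    n_assigned = sum(1 for r in results if r.assigned)
    summary = {
        "n_variants": len(results),
        "n_assigned": n_assigned,
        "fraction_assigned": n_assigned / len(results) if results else 0.0,
        "tier_counts": tier_counts,
        **classes,
        "median_distance_assigned_bp": float(np.median(dist_assigned)) if dist_assigned else math.nan,
        "median_distance_nearest_bp": float(np.median(dist_nearest)) if dist_nearest else math.nan,
    }
    return results, summary


@dataclass
class EnrichmentResult:
    table: np.ndarray  # [[a, b], [c, d]]
    odds_ratio: float | None  # ad/bc; None when a margin is zero
    p_value: float  # two-sided exact hypergeometric P
    mode: str


def se_te_variant_enrichment(
    variants: pd.DataFrame,
    se_constituents: IntervalSet,
    typical_enhancers: IntervalSet,
    mode: str = "elements",
) -> EnrichmentResult:
    """Fisher 2x2 enrichment of variants in SE constituents versus TEs.

    ``elements`` (primary): rows are SE constituents / TEs, columns are
    bearing >= 1 variant / none.  ``bp``: rows are SE / TE, columns are
    variant count / remaining base pairs.
    """
    points = [
        GenomicInterval(r.chrom, int(r.pos0), int(r.pos0) + 1)
        for r in variants.itertuples()
    ]

    def n_with_variant(iset: IntervalSet) -> int:
        return sum(
            1 for iv in iset if any(iv.overlap_bp(p) > 0 for p in points)
        )

    def n_variants_in(iset: IntervalSet) -> int:
        return sum(1 for p in points if overlapping_any(iset, p))

    if mode == "elements":
        a = n_with_variant(se_constituents)
        b = len(se_constituents) - a
        c = n_with_variant(typical_enhancers)
        d = len(typical_enhancers) - c
    elif mode == "bp":
        a = n_variants_in(se_constituents)
        b = se_constituents.total_bp() - a
        c = n_variants_in(typical_enhancers)
        d = typical_enhancers.total_bp() - c
    else:
        raise ValueError(f"unknown mode {mode!r}")

    table = np.array([[a, b], [c, d]], dtype=np.int64)
    if min(a + b, c + d, a + c, b + d) == 0:
        return EnrichmentResult(table, None, 1.0, mode)
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return EnrichmentResult(table, odds, p, mode)
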