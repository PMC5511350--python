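"""Deterministic generator of a complete toy regulatory-genomics study.

The generator emulates the data structures of a megakaryocyte/erythroblast
(MK/EB) regulatory landscape: a small genome, open-chromatin peak sets for
five cell types (HSC, CMP, MEP, MK, EB) with planted differentiation
patterns, enhancer segments with clustered high-H3K27ac super-enhancer (SE)
regions and dispersed typical enhancers, a HindIII-like restriction fragment
grid, promoter-anchored interactions with designated target genes, a gene
table with expression (FPKM), and GWAS-like sentinel variants with block LD
proxies and a configurable planted enrichment of significant P-values inside
the MK-specific SE constituents.

One seed governs all randomness; sub-streams are derived per component by
fixed offsets, so identical config+seed yields bit-identical serialized
output.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genome import (
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    SignalTrack,
    read_bed,
    write_bed,
)

__all__ = ["SimulationConfig", "SyntheticDataset", "ClusterTruth", "Truth",
           "SimulationError", "generate", "write_dataset", "read_dataset"]

PROGENITORS = ("HSC", "CMP", "MEP")
CELLS = ("HSC", "CMP", "MEP", "MK", "EB")

#: presence pattern (HSC, CMP, MEP, EB) implied by each named opening category
CATEGORY_PATTERNS = {
    "I": (1, 1, 1, 1),
    "II": (1, 1, 1, 0),
    "III": (0, 0, 0, 0),
    "IV": (0, 0, 0, 1),
}
_UNCAT_PATTERNS = [
    p
    for p in [(a, b, c, d) for a in (0, 1) for b in (0, 1) for c in (0, 1) for d in (0, 1)]
    if p not in CATEGORY_PATTERNS.values()
]


class SimulationError(RuntimeError):
    """Raised when a configuration cannot be realised (features do not fit)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the toy study.

    The defaults describe the study conditions the pipeline is exercised
    under: a 32 Mb four-chromosome genome, ~4 kb HindIII-like fragments,
    SE clusters whose stitched H3K27ac scores exceed dispersed enhancers by
    well over an order of magnitude, and a planted significance enrichment
    with odds multiplier ``theta`` (default 5, analogous to the reported
    fivefold SE-vs-TE enrichment) for platelet-trait variants lying inside
    MK-specific SE constituents.
    """

    seed: int = 0
    n_chromosomes: int = 4
    chromosome_length: int = 8_000_000
    n_genes: int = 240
    fragment_mean_bp: int = 4_000
    # enhancers per cell type
    n_se_clusters: int = 16
    se_constituents_min: int = 4
    se_constituents_max: int = 9
    shared_cluster_fraction: float = 0.3
    n_dispersed_enhancers: int = 160
    n_promoter_decoy_enhancers: int = 20
    # open chromatin
    n_reference_peaks: int = 600
    n_spurious_progenitor_peaks: int = 30
    category_fractions: tuple[float, float, float, float] = (0.40, 0.10, 0.20, 0.18)
    fully_open_se_fraction: float = 0.15
    # variants
    n_sentinels_platelet: int = 110
    n_sentinels_redcell: int = 110
    pleiotropic_fraction: float = 0.04
    exonic_fraction: float = 0.16
    fraction_in_enriched_set: float = 0.25
    fraction_in_te_set: float = 0.10
    theta: float = 5.0
    enriched_trait: str = "platelet"
    baseline_sig_odds: float = 0.5
    sig_pvalue_magnitude: float = 1e-10
    sig_threshold: float = 5e-8
    # LD
    proxies_per_sentinel: int = 3
    proxy_window_bp: int = 50_000
    ld_exact_fraction: float = 0.15

    def __post_init__(self) -> None:
        if sum(self.category_fractions) > 1.0 + 1e-12:
            raise ValueError("category fractions must sum to <= 1")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if not 0 < self.sig_threshold < 1:
            raise ValueError("sig_threshold must lie in (0,1)")
        for name in (
            "n_chromosomes", "chromosome_length", "n_genes", "fragment_mean_bp",
            "n_se_clusters", "n_dispersed_enhancers", "n_reference_peaks",
            "n_sentinels_platelet", "n_sentinels_redcell", "proxies_per_sentinel",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def small(self) -> "SimulationConfig":
        """A reduced configuration for replicate-heavy statistical checks."""
        return replace(
            self,
            n_chromosomes=2,
            chromosome_length=4_000_000,
            n_genes=60,
            n_se_clusters=6,
            n_dispersed_enhancers=40,
            n_promoter_decoy_enhancers=8,
            n_reference_peaks=150,
            n_spurious_progenitor_peaks=15,
            n_sentinels_platelet=100,
            n_sentinels_redcell=100,
        )


@dataclass(frozen=True)
class ClusterTruth:
    """Planted SE cluster: where it is, its constituents and its targets."""

    cluster_id: str
    cell: str  # "MK", "EB" or "shared"
    region: GenomicInterval
    constituent_labels: tuple[str, ...]
    target_genes: tuple[str, ...]  # MK-side PCHi-C targets; empty for EB-only
    fully_open: bool  # every constituent traces to HSC+CMP+MEP-open chromatin


@dataclass
class Truth:
    """Ground truth planted by the generator, for downstream assertions."""

    peaks: pd.DataFrame  # peak_id, chrom, start, end, hsc, cmp, mep, eb, category
    clusters: list[ClusterTruth]
    enriched_set: IntervalSet  # MK-specific SE constituents
    te_set: IntervalSet  # dispersed MK enhancers (future typical enhancers)
    variants: pd.DataFrame  # id, significant, in_enriched


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    layout: GenomeLayout
    open_chromatin: dict[str, IntervalSet]  # per cell type
    ctcf: dict[str, IntervalSet]  # MK, EB
    enhancer_segments: dict[str, IntervalSet]  # MK, EB (BED4 labels)
    promoter_segments: IntervalSet
    h3k27ac: dict[str, SignalTrack]
    input_signal: dict[str, SignalTrack]
    fragments: IntervalSet  # BED4, label = fragment id
    interactions: pd.DataFrame  # ibed-style dialect (MK PCHi-C)
    genes: pd.DataFrame  # gene_id, chrom, tss (";"-joined), fpkm
    variants: pd.DataFrame  # id, chrom, pos0, trait, pval, consequence, vep_gene
    ld: pd.DataFrame  # sentinel_id, proxy_id, proxy_chrom, proxy_pos0, r2
    truth: Truth

    def __eq__(self, other: object) -> bool:  # full structural equality
        if not isinstance(other, SyntheticDataset):
            return NotImplemented
        return (
            self.layout == other.layout
            and self.open_chromatin == other.open_chromatin
            and self.ctcf == other.ctcf
            and self.enhancer_segments == other.enhancer_segments
            and self.promoter_segments == other.promoter_segments
            and self.h3k27ac == other.h3k27ac
            and self.input_signal == other.input_signal
            and self.fragments == other.fragments
            and self.interactions.equals(other.interactions)
            and self.genes.equals(other.genes)
            and self.variants.equals(other.variants)
            and self.ld.equals(other.ld)
        )


# ---------------------------------------------------------------------------
# placement machinery
# ---------------------------------------------------------------------------

class _Occupancy:
    """Disjoint blocked intervals per chromosome, for rejection placement."""

    def __init__(self, layout: GenomeLayout) -> None:
        self._blocks: dict[str, list[tuple[int, int]]] = {c: [] for c in layout.names}
        self._lengths = layout.lengths
        self._names = layout.names

    def _free(self, chrom: str, start: int, end: int, margin: int) -> bool:
        lo, hi = start - margin, end + margin
        blocks = self._blocks[chrom]
        i = bisect.bisect_left(blocks, (lo, -1))
        if i > 0 and blocks[i - 1][1] > lo:
            return False
        return not (i < len(blocks) and blocks[i][0] < hi)

    def add(self, chrom: str, start: int, end: int) -> None:
        bisect.insort(self._blocks[chrom], (start, end))

    def place(
        self,
        rng: np.random.Generator,
        length: int,
        margin: int,
        max_tries: int = 2000,
    ) -> tuple[str, int]:
        lens = np.array([self._lengths[c] for c in self._names], dtype=float)
        probs = lens / lens.sum()
        for _ in range(max_tries):
            chrom = self._names[int(rng.choice(len(self._names), p=probs))]
            start = int(rng.integers(margin, self._lengths[chrom] - length - margin))
            if self._free(chrom, start, start + length, margin):
                self.add(chrom, start, start + length)
                return chrom, start
        raise SimulationError(
            f"could not place a feature of {length} bp with margin {margin}: "
            "configuration infeasible (too many features for the genome size)"
        )


def _rng(cfg: SimulationConfig, component: int) -> np.random.Generator:
    # fixed per-component offsets off one seed: reproducible sub-streams
    return np.random.default_rng([component, cfg.seed])


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _make_fragments(cfg: SimulationConfig, layout: GenomeLayout) -> IntervalSet:
    rng = _rng(cfg, 0)
    frags: list[GenomicInterval] = []
    fid = 0
    for chrom, length in layout.chromosomes:
        pos = 0
        mean_extra = max(1, cfg.fragment_mean_bp - 500)
        while pos < length:
            ln = 500 + int(rng.geometric(1.0 / mean_extra))
            end = min(pos + ln, length)
            fid += 1
            frags.append(GenomicInterval(chrom, pos, end, f"F{fid:06d}"))
            pos = end
    return IntervalSet(frags, layout=layout)


def _make_genes(
    cfg: SimulationConfig, layout: GenomeLayout, occ: _Occupancy
) -> pd.DataFrame:
    rng = _rng(cfg, 1)
    rows = []
    for i in range(cfg.n_genes):
        chrom, start = occ.place(rng, 4000, margin=1000)
        tss = start + 2000
        tss_list = [tss]
        if rng.random() < 0.10:
            tss_list.append(tss + int(rng.integers(800, 1900)))
        if rng.random() < 0.20:
            fpkm = round(float(rng.uniform(0.0, 0.95)), 3)
        else:
            fpkm = round(1.0 + float(rng.lognormal(1.5, 1.0)), 3)
        rows.append(
            {
                "gene_id": f"G{i + 1:04d}",
                "chrom": chrom,
                "tss": ";".join(str(t) for t in tss_list),
                "fpkm": fpkm,
            }
        )
    return pd.DataFrame(rows)


def _gene_tss_map(genes: pd.DataFrame) -> dict[str, tuple[str, tuple[int, ...]]]:
    return {
        r.gene_id: (r.chrom, tuple(int(t) for t in str(r.tss).split(";")))
        for r in genes.itertuples()
    }


@dataclass
class _Cluster:
    cluster_id: str
    cell: str
    chrom: str
    start: int
    end: int
    constituents: list[GenomicInterval]


def _make_clusters(
    cfg: SimulationConfig, occ: _Occupancy, rng: np.random.Generator
) -> list[_Cluster]:
    n_shared = int(round(cfg.n_se_clusters * cfg.shared_cluster_fraction))
    n_specific = cfg.n_se_clusters - n_shared
    plan = (
        [("shared", i) for i in range(n_shared)]
        + [("MK", i) for i in range(n_specific)]
        + [("EB", i) for i in range(n_specific)]
    )
    clusters: list[_Cluster] = []
    for cell, i in plan:
        k = int(rng.integers(cfg.se_constituents_min, cfg.se_constituents_max + 1))
        lens = rng.integers(800, 1500, size=k)
        gaps = rng.integers(1200, 9000, size=max(0, k - 1))
        span = int(lens.sum() + gaps.sum())
        chrom, start = occ.place(rng, span, margin=30_000)
        tag = {"shared": "SH", "MK": "MK", "EB": "EB"}[cell]
        cid = f"{tag}_SE{i + 1:02d}"
        cons = []
        pos = start
        for t in range(k):
            cons.append(
                GenomicInterval(chrom, pos, pos + int(lens[t]), f"{cid}_c{t + 1}")
            )
            pos += int(lens[t]) + (int(gaps[t]) if t < k - 1 else 0)
        clusters.append(_Cluster(cid, cell, chrom, start, start + span, cons))
    return clusters


def generate(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full toy study for one configuration."""
    cfg = config
    layout = GenomeLayout(
        tuple((f"chr{i + 1}", cfg.chromosome_length) for i in range(cfg.n_chromosomes))
    )
    occ = _Occupancy(layout)

    fragments = _make_fragments(cfg, layout)
    genes = _make_genes(cfg, layout, occ)
    tss_map = _gene_tss_map(genes)

    # promoter-state segments around every TSS
    promoters = IntervalSet(
        [
            GenomicInterval(chrom, t - 700, t + 700, gid)
            for gid, (chrom, tsses) in tss_map.items()
            for t in tsses
        ],
        layout=layout,
    )

    # --- enhancer landscape -------------------------------------------------
    rng_enh = _rng(cfg, 2)
    clusters = _make_clusters(cfg, occ, rng_enh)

    dispersed: dict[str, list[GenomicInterval]] = {"MK": [], "EB": []}
    for cell in ("MK", "EB"):
        for j in range(cfg.n_dispersed_enhancers):
            ln = int(rng_enh.integers(600, 1200))
            chrom, start = occ.place(rng_enh, ln, margin=13_000)
            dispersed[cell].append(
                GenomicInterval(chrom, start, start + ln, f"{cell}_TE{j + 1:03d}")
            )

    gene_ids = list(genes.gene_id)
    decoys: dict[str, list[GenomicInterval]] = {"MK": [], "EB": []}
    nd = min(cfg.n_promoter_decoy_enhancers, len(gene_ids) // 2)
    for cell, offset in (("MK", 0), ("EB", nd)):
        for gid in gene_ids[offset : offset + nd]:
            chrom, tsses = tss_map[gid]
            t = tsses[0]
            decoys[cell].append(
                GenomicInterval(chrom, t + 800, t + 1600, f"{cell}_decoy_{gid}")
            )

    enhancer_segments = {}
    for cell in ("MK", "EB"):
        segs = [
            c
            for cl in clusters
            if cl.cell in (cell, "shared")
            for c in cl.constituents
        ]
        enhancer_segments[cell] = IntervalSet(
            segs + dispersed[cell] + decoys[cell], layout=layout
        )

    # --- H3K27ac signal -----------------------------------------------------
    rng_sig = _rng(cfg, 3)
    h3k27ac: dict[str, SignalTrack] = {}
    input_signal: dict[str, SignalTrack] = {}
    for cell in ("MK", "EB"):
        treat: dict[str, list[tuple[int, int, float]]] = {}
        inp: dict[str, list[tuple[int, int, float]]] = {}
        for iv in enhancer_segments[cell]:
            is_constituent = "_SE" in (iv.label or "")
            if is_constituent:
                value = max(8.0, float(rng_sig.normal(12.0, 1.5)))
            else:
                value = max(0.5, float(rng_sig.normal(1.0, 0.15)))
            treat.setdefault(iv.chrom, []).append((iv.start, iv.end, round(value, 4)))
            inp.setdefault(iv.chrom, []).append((iv.start, iv.end, 0.2))
        h3k27ac[cell] = SignalTrack(treat)
        input_signal[cell] = SignalTrack(inp)

    # --- open chromatin with planted opening patterns -----------------------
    rng_peak = _rng(cfg, 4)
    mk_clusters = [cl for cl in clusters if cl.cell in ("MK", "shared")]
    n_forced_open = math.ceil(cfg.fully_open_se_fraction * len(mk_clusters))
    forced_open_ids = {cl.cluster_id for cl in mk_clusters[:n_forced_open]}

    peak_rows = []
    mk_peaks: list[GenomicInterval] = []
    progenitor_peaks: dict[str, list[GenomicInterval]] = {c: [] for c in PROGENITORS}
    eb_peaks: list[GenomicInterval] = []

    fractions = np.array(list(cfg.category_fractions) + [1.0 - sum(cfg.category_fractions)])
    cat_names = ["I", "II", "III", "IV", "UNCAT"]

    def draw_category(forced: str | None = None) -> tuple[str, tuple[int, int, int, int]]:
        if forced is not None:
            return forced, CATEGORY_PATTERNS[forced]
        cat = cat_names[int(rng_peak.choice(5, p=fractions))]
        if cat == "UNCAT":
            return cat, _UNCAT_PATTERNS[int(rng_peak.integers(len(_UNCAT_PATTERNS)))]
        return cat, CATEGORY_PATTERNS[cat]

    def add_peak(base: GenomicInterval, forced: str | None) -> None:
        pid = f"P{len(peak_rows) + 1:05d}"
        u, v = int(rng_peak.integers(0, 300)), int(rng_peak.integers(0, 300))
        peak = GenomicInterval(
            base.chrom,
            max(0, base.start - u),
            min(layout.length(base.chrom), base.end + v),
            pid,
        )
        cat, pattern = draw_category(forced)
        mk_peaks.append(peak)
        for bit, cell in zip(pattern[:3], PROGENITORS):
            if bit:
                uu, vv = int(rng_peak.integers(0, 300)), int(rng_peak.integers(0, 300))
                progenitor_peaks[cell].append(
                    GenomicInterval(
                        peak.chrom,
                        max(0, peak.start - uu),
                        min(layout.length(peak.chrom), peak.end + vv),
                    )
                )
        if pattern[3]:
            uu, vv = int(rng_peak.integers(0, 300)), int(rng_peak.integers(0, 300))
            eb_peaks.append(
                GenomicInterval(
                    peak.chrom,
                    max(0, peak.start - uu),
                    min(layout.length(peak.chrom), peak.end + vv),
                )
            )
        peak_rows.append(
            {
                "peak_id": pid,
                "chrom": peak.chrom,
                "start": peak.start,
                "end": peak.end,
                "hsc": pattern[0],
                "cmp": pattern[1],
                "mep": pattern[2],
                "eb": pattern[3],
                "category": cat,
            }
        )

    # every MK-side SE constituent carries an MK open-chromatin peak
    for cl in mk_clusters:
        forced = "I" if cl.cluster_id in forced_open_ids else None
        for c in cl.constituents:
            add_peak(c, forced)
    n_extra = max(0, cfg.n_reference_peaks - len(peak_rows))
    for _ in range(n_extra):
        ln = int(rng_peak.integers(300, 800))
        chrom, start = occ.place(rng_peak, ln, margin=3_000)
        add_peak(GenomicInterval(chrom, start, start + ln), None)

    # EB-specific SE constituents appear in EB open chromatin only
    for cl in clusters:
        if cl.cell == "EB":
            for c in cl.constituents:
                u, v = int(rng_peak.integers(0, 300)), int(rng_peak.integers(0, 300))
                eb_peaks.append(
                    GenomicInterval(c.chrom, max(0, c.start - u), c.end + v)
                )

    for _ in range(cfg.n_spurious_progenitor_peaks):
        ln = int(rng_peak.integers(400, 800))
        chrom, start = occ.place(rng_peak, ln, margin=3_000)
        cell = PROGENITORS[int(rng_peak.integers(3))]
        progenitor_peaks[cell].append(GenomicInterval(chrom, start, start + ln))

    open_chromatin = {
        "MK": IntervalSet(mk_peaks, layout=layout),
        "EB": IntervalSet(eb_peaks, layout=layout),
        **{c: IntervalSet(progenitor_peaks[c], layout=layout) for c in PROGENITORS},
    }

    # --- CTCF ---------------------------------------------------------------
    rng_ctcf = _rng(cfg, 5)
    ctcf: dict[str, IntervalSet] = {}
    for cell, peaks in (("MK", mk_peaks), ("EB", eb_peaks)):
        sites = []
        for iv in peaks:
            if rng_ctcf.random() < 0.30:
                q = len(iv) // 4
                if len(iv) - 2 * q >= 50:
                    sites.append(GenomicInterval(iv.chrom, iv.start + q, iv.end - q))
                else:
                    sites.append(GenomicInterval(iv.chrom, iv.start, iv.end))
        for _ in range(30):
            ln = int(rng_ctcf.integers(200, 500))
            chrom, start = occ.place(rng_ctcf, ln, margin=3_000)
            sites.append(GenomicInterval(chrom, start, start + ln))
        ctcf[cell] = IntervalSet(sites, layout=layout)

    # --- PCHi-C interactions (MK) -------------------------------------------
    rng_int = _rng(cfg, 6)
    frag_by_chrom = fragments.by_chrom()

    def frags_overlapping(iv: GenomicInterval) -> list[GenomicInterval]:
        starts, ends, idx = frag_by_chrom[iv.chrom]
        lo = int(np.searchsorted(ends, iv.start, side="right"))
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        return [fragments[int(i)] for i in idx[lo:hi]]

    # baits: fragments containing >=1 TSS
    baits: dict[str, list[str]] = {}
    for gid, (chrom, tsses) in tss_map.items():
        for t in tsses:
            for fr in frags_overlapping(GenomicInterval(chrom, t, t + 1)):
                baits.setdefault(fr.label, [])
                if gid not in baits[fr.label]:
                    baits[fr.label].append(gid)
    bait_frag_of_gene = {}
    for fid, gids in baits.items():
        for gid in gids:
            bait_frag_of_gene.setdefault(gid, fid)

    frag_lookup = {iv.label: iv for iv in fragments}
    cluster_frag_ids: dict[str, list[str]] = {}
    all_cluster_frags: set[str] = set()
    for cl in mk_clusters:
        fids = sorted(
            {fr.label for c in cl.constituents for fr in frags_overlapping(c)}
        )
        cluster_frag_ids[cl.cluster_id] = fids
        all_cluster_frags.update(fids)

    expressed = [
        g for g in gene_ids if float(genes.loc[genes.gene_id == g, "fpkm"].iloc[0]) >= 1.0
    ]
    candidate_targets = [
        g for g in expressed
        if g in bait_frag_of_gene and bait_frag_of_gene[g] not in all_cluster_frags
    ]
    if not candidate_targets:
        raise SimulationError("no expressed gene with a usable bait fragment")

    inter_rows: list[dict] = []

    def add_interaction(bait_id: str, oe_id: str, score: float) -> None:
        b, o = frag_lookup[bait_id], frag_lookup[oe_id]
        inter_rows.append(
            {
                "bait_chr": b.chrom, "bait_start": b.start, "bait_end": b.end,
                "bait_id": bait_id, "bait_genes": ";".join(baits[bait_id]),
                "oe_chr": o.chrom, "oe_start": o.start, "oe_end": o.end,
                "oe_id": oe_id, "score": round(score, 3),
            }
        )

    cluster_targets: dict[str, tuple[str, ...]] = {}
    for cl in mk_clusters:
        n_t = int(rng_int.integers(1, 3))
        chosen = [
            candidate_targets[int(i)]
            for i in rng_int.choice(len(candidate_targets), size=n_t, replace=False)
        ]
        target_baits = sorted({bait_frag_of_gene[g] for g in chosen})
        # truth targets = union of the chosen baits' full gene lists
        cluster_targets[cl.cluster_id] = tuple(
            sorted({g for fb in target_baits for g in baits[fb]})
        )
        for fid in cluster_frag_ids[cl.cluster_id]:
            for fb in target_baits:
                add_interaction(fb, fid, float(rng_int.uniform(5.0, 15.0)))
        # sub-threshold decoy interactions into the cluster
        decoy_baits = [b for b in baits if b not in all_cluster_frags]
        for _ in range(2):
            db = decoy_baits[int(rng_int.integers(len(decoy_baits)))]
            fid = cluster_frag_ids[cl.cluster_id][
                int(rng_int.integers(len(cluster_frag_ids[cl.cluster_id])))
            ]
            add_interaction(db, fid, float(rng_int.uniform(0.5, 4.5)))

    usable_baits = sorted(b for b in baits if b not in all_cluster_frags)
    frag_ids_all = [iv.label for iv in fragments]
    n_background = 20 * max(1, len(usable_baits) // 10)
    for _ in range(min(300, n_background)):
        b = usable_baits[int(rng_int.integers(len(usable_baits)))]
        if rng_int.random() < 0.08:  # bait-bait pair
            o = usable_baits[int(rng_int.integers(len(usable_baits)))]
            if o == b:
                continue
        else:
            o = frag_ids_all[int(rng_int.integers(len(frag_ids_all)))]
            if o in all_cluster_frags or o == b:
                continue
        add_interaction(b, o, float(rng_int.gamma(2.0, 1.5)))
    interactions = pd.DataFrame(inter_rows).sort_values(
        ["bait_id", "oe_id", "score"], kind="mergesort", ignore_index=True
    )

    # --- variants with planted enrichment -----------------------------------
    rng_var = _rng(cfg, 7)
    enriched_ivs = [
        c for cl in clusters if cl.cell == "MK" for c in cl.constituents
    ]
    enriched_set = IntervalSet(enriched_ivs, layout=layout)
    te_set = IntervalSet(dispersed["MK"], layout=layout)

    n_other = int(round(cfg.pleiotropic_fraction
                        * (cfg.n_sentinels_platelet + cfg.n_sentinels_redcell)))
    groups = (
        [("platelet", cfg.n_sentinels_platelet),
         ("red-cell", cfg.n_sentinels_redcell),
         ("other", n_other)]
    )
    chrom_lengths = np.array([layout.length(c) for c in layout.names], dtype=float)
    chrom_probs = chrom_lengths / chrom_lengths.sum()
    enr_lens = np.array([len(iv) for iv in enriched_ivs], dtype=float)
    enr_probs = enr_lens / enr_lens.sum() if len(enr_lens) else None

    te_ivs = list(dispersed["MK"])
    te_lens = np.array([len(iv) for iv in te_ivs], dtype=float)
    te_probs = te_lens / te_lens.sum() if len(te_lens) else None

    var_rows = []
    truth_var_rows = []
    vid = 0
    for trait, n in groups:
        k_in = int(round(cfg.fraction_in_enriched_set * n)) if enr_probs is not None else 0
        k_te = int(round(cfg.fraction_in_te_set * n)) if te_probs is not None else 0
        for j in range(n):
            vid += 1
            v_id = f"rs{vid:06d}"
            if j < k_in:
                iv = enriched_ivs[int(rng_var.choice(len(enriched_ivs), p=enr_probs))]
                chrom = iv.chrom
                pos = int(rng_var.integers(iv.start, iv.end))
            elif j < k_in + k_te:
                iv = te_ivs[int(rng_var.choice(len(te_ivs), p=te_probs))]
                chrom = iv.chrom
                pos = int(rng_var.integers(iv.start, iv.end))
            else:
                chrom = layout.names[int(rng_var.choice(len(layout.names), p=chrom_probs))]
                pos = int(rng_var.integers(0, layout.length(chrom)))
            point = GenomicInterval(chrom, pos, pos + 1)
            in_set = any(
                iv.overlap_bp(point) > 0
                for iv in enriched_ivs
                if iv.chrom == chrom
            )
            odds = cfg.baseline_sig_odds * (
                cfg.theta if (trait == cfg.enriched_trait and in_set) else 1.0
            )
            sig = bool(rng_var.random() < odds / (1.0 + odds))
            if sig:
                mag = math.log10(cfg.sig_pvalue_magnitude)
                pval = float(10 ** rng_var.uniform(mag - 2, mag + 2))
            else:
                pval = float(rng_var.uniform(0.0, 1.0))
            # consequence class
            in_promoter = bool(
                overlapping_any(promoters, point)
            )
            if in_promoter:
                consequence, vep_gene = "promoter_overlap_candidate", ""
            elif rng_var.random() < cfg.exonic_fraction:
                consequence = "exonic_or_splice"
                vep_gene = _nearest_gene(tss_map, chrom, pos) or ""
            else:
                consequence, vep_gene = "intronic_or_intergenic", ""
            var_rows.append(
                {
                    "id": v_id, "chrom": chrom, "pos0": pos, "trait": trait,
                    "pval": pval, "consequence": consequence, "vep_gene": vep_gene,
                }
            )
            truth_var_rows.append(
                {"id": v_id, "significant": int(sig), "in_enriched": int(in_set)}
            )
    variants = pd.DataFrame(
        var_rows,
        columns=["id", "chrom", "pos0", "trait", "pval", "consequence", "vep_gene"],
    )
    truth_variants = pd.DataFrame(
        truth_var_rows, columns=["id", "significant", "in_enriched"]
    )

    # --- LD proxies ----------------------------------------------------------
    rng_ld = _rng(cfg, 8)
    ld_rows = []
    for r in variants.itertuples():
        if rng_ld.random() < 0.10:  # some sentinels have no proxies
            continue
        for k in range(cfg.proxies_per_sentinel):
            off = 0
            while off == 0:
                off = int(rng_ld.integers(-cfg.proxy_window_bp, cfg.proxy_window_bp + 1))
            pos = min(max(0, r.pos0 + off), layout.length(r.chrom) - 1)
            if rng_ld.random() < cfg.ld_exact_fraction:
                r2 = 1.0
            else:
                r2 = round(float(rng_ld.uniform(0.8, 1.0)), 4)
            ld_rows.append(
                {
                    "sentinel_id": r.id, "proxy_id": f"{r.id}p{k + 1}",
                    "proxy_chrom": r.chrom, "proxy_pos0": pos, "r2": r2,
                }
            )
    ld = pd.DataFrame(
        ld_rows, columns=["sentinel_id", "proxy_id", "proxy_chrom", "proxy_pos0", "r2"]
    )

    # --- truth record ---------------------------------------------------------
    peaks_df = pd.DataFrame(peak_rows)
    pattern_by_label: dict[str, tuple[int, int, int]] = {}
    for row, peak in zip(peak_rows, mk_peaks):
        pattern_by_label[row["peak_id"]] = (row["hsc"], row["cmp"], row["mep"])
    # constituent peaks were added in cluster order, so recover per-cluster flags
    cluster_truths: list[ClusterTruth] = []
    i_peak = 0
    for cl in mk_clusters:
        k = len(cl.constituents)
        fully = all(
            peak_rows[i_peak + t]["hsc"]
            and peak_rows[i_peak + t]["cmp"]
            and peak_rows[i_peak + t]["mep"]
            for t in range(k)
        )
        cluster_truths.append(
            ClusterTruth(
                cl.cluster_id,
                cl.cell,
                GenomicInterval(cl.chrom, cl.start, cl.end),
                tuple(c.label for c in cl.constituents),
                cluster_targets[cl.cluster_id],
                fully,
            )
        )
        i_peak += k
    for cl in clusters:
        if cl.cell == "EB":
            cluster_truths.append(
                ClusterTruth(
                    cl.cluster_id, "EB",
                    GenomicInterval(cl.chrom, cl.start, cl.end),
                    tuple(c.label for c in cl.constituents),
                    (), False,
                )
            )

    truth = Truth(
        peaks=peaks_df,
        clusters=cluster_truths,
        enriched_set=enriched_set,
        te_set=te_set,
        variants=truth_variants,
    )
    return SyntheticDataset(
        config=cfg,
        layout=layout,
        open_chromatin=open_chromatin,
        ctcf=ctcf,
        enhancer_segments=enhancer_segments,
        promoter_segments=promoters,
        h3k27ac=h3k27ac,
        input_signal=input_signal,
        fragments=fragments,
        interactions=interactions,
        genes=genes,
        variants=variants,
        ld=ld,
        truth=truth,
    )


def overlapping_any(iset: IntervalSet, iv: GenomicInterval) -> bool:
    """True iff any interval of the set shares >=1 bp with ``iv``."""
    chroms = iset.by_chrom()
    if iv.chrom not in chroms:
        return False
    starts, ends, _ = chroms[iv.chrom]
    hi = int(np.searchsorted(starts, iv.end, side="left"))
    return bool(hi > 0 and np.any(ends[:hi] > iv.start))


def _nearest_gene(
    tss_map: Mapping[str, tuple[str, tuple[int, ...]]], chrom: str, pos: int
) -> str | None:
    best, best_d = None, None
    for gid, (gchrom, tsses) in tss_map.items():
        if gchrom != chrom:
            continue
        d = abs(pos - sum(tsses) / len(tsses))
        if best_d is None or d < best_d or (d == best_d and gid < best):
            best, best_d = gid, d
    return best


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_FILES = {
    "chrom.sizes": "genome layout",
    "open_HSC.bed": "open chromatin HSC",
    "open_CMP.bed": "open chromatin CMP",
    "open_MEP.bed": "open chromatin MEP",
    "open_MK.bed": "open chromatin MK (reference, BED4 peak ids)",
    "open_EB.bed": "open chromatin EB",
    "ctcf_MK.bed": "CTCF peaks MK",
    "ctcf_EB.bed": "CTCF peaks EB",
    "enhancers_MK.bed": "enhancer-state segments MK (BED4)",
    "enhancers_EB.bed": "enhancer-state segments EB (BED4)",
    "promoters.bed": "promoter-state segments (BED4 gene id)",
    "h3k27ac_MK.bedgraph": "H3K27ac treatment signal MK",
    "h3k27ac_EB.bedgraph": "H3K27ac treatment signal EB",
    "input_MK.bedgraph": "ChIP input signal MK",
    "input_EB.bedgraph": "ChIP input signal EB",
    "fragments.bed": "restriction fragment grid (BED4 ids)",
    "interactions.tsv": "PCHi-C interactions MK (ibed-style)",
    "genes.tsv": "gene table (TSS list, FPKM)",
    "variants.tsv": "GWAS sentinel variants (1-based POS)",
    "ld.tsv": "LD proxy table (1-based POS)",
    "truth_peaks.tsv": "truth: planted peak patterns and categories",
    "truth_clusters.tsv": "truth: planted SE clusters and targets",
    "truth_variants.tsv": "truth: planted significance and membership",
}


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> dict[str, str]:
    """Write every component to ``directory``; returns a file -> role manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    ds = dataset
    ds.layout.to_file(d / "chrom.sizes")
    for cell in CELLS:
        write_bed(ds.open_chromatin[cell], d / f"open_{cell}.bed")
    for cell in ("MK", "EB"):
        write_bed(ds.ctcf[cell], d / f"ctcf_{cell}.bed")
        write_bed(ds.enhancer_segments[cell], d / f"enhancers_{cell}.bed")
        ds.h3k27ac[cell].to_bedgraph(d / f"h3k27ac_{cell}.bedgraph")
        ds.input_signal[cell].to_bedgraph(d / f"input_{cell}.bedgraph")
    write_bed(ds.promoter_segments, d / "promoters.bed")
    write_bed(ds.fragments, d / "fragments.bed")
    ds.interactions.to_csv(d / "interactions.tsv", sep="\t", index=False,
                           float_format="%.17g")
    ds.genes.to_csv(d / "genes.tsv", sep="\t", index=False, float_format="%.17g")
    v = ds.variants.copy()
    v.insert(2, "pos", v.pop("pos0") + 1)
    v.to_csv(d / "variants.tsv", sep="\t", index=False, float_format="%.17g")
    ld = ds.ld.copy()
    ld["proxy_pos"] = ld.pop("proxy_pos0") + 1
    ld = ld[["sentinel_id", "proxy_id", "proxy_chrom", "proxy_pos", "r2"]]
    ld.to_csv(d / "ld.tsv", sep="\t", index=False, float_format="%.17g")
    ds.truth.peaks.to_csv(d / "truth_peaks.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id, "cell": c.cell,
                "chrom": c.region.chrom, "start": c.region.start, "end": c.region.end,
                "constituents": ";".join(c.constituent_labels),
                "target_genes": ";".join(c.target_genes),
                "fully_open": int(c.fully_open),
            }
            for c in ds.truth.clusters
        ]
    ).to_csv(d / "truth_clusters.tsv", sep="\t", index=False)
    ds.truth.variants.to_csv(d / "truth_variants.tsv", sep="\t", index=False)
    manifest = dict(_FILES)
    with open(d / "MANIFEST.tsv", "w") as fh:
        fh.write("file\trole\n")
        for name, role in manifest.items():
            fh.write(f"{name}\t{role}\n")
    return manifest


def read_dataset(directory: str | Path, config: SimulationConfig | None = None) -> SyntheticDataset:
    """Re-read a written dataset through the package's own format readers."""
    d = Path(directory)
    layout = GenomeLayout.from_file(d / "chrom.sizes")
    open_chromatin = {c: read_bed(d / f"open_{c}.bed", layout) for c in CELLS}
    ctcf = {c: read_bed(d / f"ctcf_{c}.bed", layout) for c in ("MK", "EB")}
    enhancers = {c: read_bed(d / f"enhancers_{c}.bed", layout) for c in ("MK", "EB")}
    h3k27ac = {
        c: SignalTrack.from_bedgraph(d / f"h3k27ac_{c}.bedgraph") for c in ("MK", "EB")
    }
    inp = {c: SignalTrack.from_bedgraph(d / f"input_{c}.bedgraph") for c in ("MK", "EB")}
    promoters = read_bed(d / "promoters.bed", layout)
    fragments = read_bed(d / "fragments.bed", layout)
    interactions = pd.read_csv(d / "interactions.tsv", sep="\t",
                               keep_default_na=False, float_precision="round_trip")
    genes = pd.read_csv(d / "genes.tsv", sep="\t", dtype={"tss": str}, float_precision="round_trip")
    variants = pd.read_csv(d / "variants.tsv", sep="\t", keep_default_na=False, float_precision="round_trip")
    variants["pos0"] = variants.pop("pos") - 1
    variants = variants[
        ["id", "chrom", "pos0", "trait", "pval", "consequence", "vep_gene"]
    ]
    ld = pd.read_csv(d / "ld.tsv", sep="\t", keep_default_na=False, float_precision="round_trip")
    if len(ld):
        ld["proxy_pos0"] = ld.pop("proxy_pos") - 1
    else:
        ld["proxy_pos0"] = pd.Series(dtype=int)
        ld = ld.drop(columns=["proxy_pos"], errors="ignore")
    ld = ld[["sentinel_id", "proxy_id", "proxy_chrom", "proxy_pos0", "r2"]]
    truth_peaks = pd.read_csv(d / "truth_peaks.tsv", sep="\t")
    tc = pd.read_csv(d / "truth_clusters.tsv", sep="\t", keep_default_na=False, float_precision="round_trip")
    clusters = [
        ClusterTruth(
            r.cluster_id, r.cell, GenomicInterval(r.chrom, r.start, r.end),
            tuple(str(r.constituents).split(";")) if r.constituents else (),
            tuple(str(r.target_genes).split(";")) if r.target_genes else (),
            bool(r.fully_open),
        )
        for r in tc.itertuples()
    ]
    label_lookup = {
        iv.label: iv for cell in ("MK", "EB") for iv in enhancers[cell] if iv.label
    }
    enriched = IntervalSet(
        [label_lookup[l] for c in clusters if c.cell == "MK"
         for l in c.constituent_labels],
        layout=layout,
    )
    te_set = IntervalSet(
        [iv for iv in enhancers["MK"] if iv.label and iv.label.startswith("MK_TE")],
        layout=layout,
    )
    truth = Truth(
        peaks=truth_peaks,
        clusters=clusters,
        enriched_set=enriched,
        te_set=te_set,
        variants=pd.read_csv(d / "truth_variants.tsv", sep="\t"),
    )
    return SyntheticDataset(
        config=config if config is not None else SimulationConfig(),
        layout=layout,
        open_chromatin=open_chromatin,
        ctcf=ctcf,
        enhancer_segments=enhancers,
        promoter_segments=promoters,
        h3k27ac=h3k27ac,
        input_signal=inp,
        fragments=fragments,
        interactions=interactions,
        genes=genes,
        variants=variants,
        ld=ld,
        truth=truth,
    )
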