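"""Shared fixtures: a small synthetic study and a hand-built assignment
fixture exercising every tier of the variant-to-gene decision tree."""

from __future__ import annotations

import pandas as pd
import pytest

import regulink as rl
from regulink.genome import GenomeLayout, GenomicInterval, IntervalSet
from regulink.pchic import FragmentIndex
from regulink.assignment import AssignmentResources


@pytest.fixture(scope="session")
def small_dataset() -> rl.SyntheticDataset:
    return rl.generate(rl.SimulationConfig(seed=7).small())


@pytest.fixture(scope="session")
def progenitor_sets(small_dataset):
    return {c: small_dataset.open_chromatin[c] for c in ("HSC", "CMP", "MEP")}


@pytest.fixture()
def toy_layout() -> GenomeLayout:
    return GenomeLayout((("chr1", 100_000), ("chr2", 50_000)))


def _interaction_row(frag_by_id, bait_id, oe_id, score, baits):
    b, o = frag_by_id[bait_id], frag_by_id[oe_id]
    return {
        "bait_chr": b.chrom, "bait_start": b.start, "bait_end": b.end,
        "bait_id": bait_id, "bait_genes": ";".join(baits.get(bait_id, ())),
        "oe_chr": o.chrom, "oe_start": o.start, "oe_end": o.end,
        "oe_id": oe_id, "score": float(score),
    }


@pytest.fixture(scope="session")
def tiny_resources() -> AssignmentResources:
    """A 100 kb single-chromosome world with one gene/bait per tier.

    Fragments F01..F20 tile chr1 in 5 kb steps.  Genes: G1 (TSS 12,000,
    expressed), G2 (22,000, expressed), G3 (32,000, expressed), G4 (42,000,
    FPKM 0.5, not expressed), G5 (52,500, expressed).  One enhancer segment
    at [60,000, 61,000).  Interactions: G1's bait -> F13 and F15 (called),
    G2's bait -> F13 (called), G1's bait -> F05 (called bait-bait).
    """
    layout = GenomeLayout((("chr1", 100_000),))
    frags = IntervalSet(
        [GenomicInterval("chr1", i * 5000, (i + 1) * 5000, f"F{i + 1:02d}")
         for i in range(20)],
        layout=layout,
    )
    genes = pd.DataFrame(
        [
            {"gene_id": "G1", "chrom": "chr1", "tss": "12000", "fpkm": 10.0},
            {"gene_id": "G2", "chrom": "chr1", "tss": "22000", "fpkm": 10.0},
            {"gene_id": "G3", "chrom": "chr1", "tss": "32000", "fpkm": 10.0},
            {"gene_id": "G4", "chrom": "chr1", "tss": "42000", "fpkm": 0.5},
            {"gene_id": "G5", "chrom": "chr1", "tss": "52500", "fpkm": 2.0},
        ]
    )
    promoters = IntervalSet(
        [GenomicInterval("chr1", t - 700, t + 700, g)
         for g, t in [("G1", 12000), ("G2", 22000), ("G3", 32000),
                      ("G4", 42000), ("G5", 52500)]],
        layout=layout,
    )
    enhancers = IntervalSet([GenomicInterval("chr1", 60_000, 61_000, "enhE")],
                            layout=layout)
    frag_index = FragmentIndex(frags)
    baits = {"F03": ("G1",), "F05": ("G2",), "F07": ("G3",),
             "F09": ("G4",), "F11": ("G5",)}
    frag_by_id = frag_index.by_id
    interactions = pd.DataFrame(
        [
            _interaction_row(frag_by_id, "F03", "F13", 6.0, baits),
            _interaction_row(frag_by_id, "F05", "F13", 7.0, baits),
            _interaction_row(frag_by_id, "F03", "F15", 8.0, baits),
            _interaction_row(frag_by_id, "F03", "F05", 9.0, baits),  # bait-bait
            _interaction_row(frag_by_id, "F07", "F17", 3.0, baits),  # sub-threshold
        ]
    )
    ld = pd.DataFrame(
        [
            # tier ld_r2_1: only the r2=1 proxy is consulted
            {"sentinel_id": "v_ld1", "proxy_id": "v_ld1_p1", "proxy_chrom": "chr1",
             "proxy_pos0": 22_100, "r2": 1.0},
            {"sentinel_id": "v_ld1", "proxy_id": "v_ld1_p2", "proxy_chrom": "chr1",
             "proxy_pos0": 32_100, "r2": 0.85},
            # tier ld_r2_09
            {"sentinel_id": "v_ld09", "proxy_id": "v_ld09_p1", "proxy_chrom": "chr1",
             "proxy_pos0": 22_100, "r2": 0.92},
            # tier ld_r2_08
            {"sentinel_id": "v_ld08", "proxy_id": "v_ld08_p1", "proxy_chrom": "chr1",
             "proxy_pos0": 32_100, "r2": 0.81},
        ]
    )
    return AssignmentResources(
        genes=genes,
        promoter_segments=promoters,
        enhancer_segments=enhancers,
        fragments=frag_index,
        baits=baits,
        interactions=interactions,
        ld=ld,
        layout=layout,
    )


def make_variant(vid, pos, consequence="intronic_or_intergenic", vep_gene="",
                 chrom="chr1", trait="platelet", pval=0.5):
    """A one-row variant record with itertuples-compatible attributes."""
    return pd.DataFrame(
        [{"id": vid, "chrom": chrom, "pos0": pos, "trait": trait, "pval": pval,
          "consequence": consequence, "vep_gene": vep_gene}]
    ).itertuples().__next__()


#: (variant kwargs, expected genes, expected tier) — one case per tier
TIER_CASES = [
    (dict(vid="v_coding", pos=80_500, consequence="exonic_or_splice",
          vep_gene="G1"), ("G1",), "coding"),
    (dict(vid="v_prom", pos=22_300), ("G2",), "promoter"),
    (dict(vid="v_enh", pos=60_500, consequence="exonic_or_splice",
          vep_gene="G3"), ("G1", "G2", "G3"), "enhancer_plus_bait"),
    (dict(vid="v_frag", pos=72_000), ("G1",), "fragment_interaction"),
    (dict(vid="v_ld1", pos=95_000), ("G2",), "ld_r2_1"),
    (dict(vid="v_ld09", pos=96_000), ("G2",), "ld_r2_09"),
    (dict(vid="v_ld08", pos=97_000), ("G3",), "ld_r2_08"),
    (dict(vid="v_bait10", pos=48_000), ("G4", "G5"), "bait_10kb"),
    (dict(vid="v_none", pos=67_000), (), "unassigned"),
]
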