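"""End-to-end orchestration of the variant-to-gene pipeline.

Stages run in order: simulate (or load) -> open-chromatin dynamics ->
super-enhancer calling (MK and EB) -> enhancer-to-gene mapping ->
variant assignment -> enrichment tests.  Every effective parameter is
echoed into the manifest together with a SHA-256 hash of each artifact, so
a rerun with the same configuration and seed reproduces identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assignment as asg
from . import dynamics as dyn
from . import pchic
from . import permutation as perm
from . import superenhancers as sec
from .genome import GenomicInterval, IntervalSet, write_bed
from .simulate import SimulationConfig, generate, read_dataset, write_dataset

logger = logging.getLogger("regulink")

__all__ = ["PipelineConfig", "run_all"]

_REQUIRED_DATA_FILES = (
    "chrom.sizes", "open_MK.bed", "open_HSC.bed", "open_CMP.bed", "open_MEP.bed",
    "open_EB.bed", "enhancers_MK.bed", "enhancers_EB.bed", "promoters.bed",
    "h3k27ac_MK.bedgraph", "input_MK.bedgraph", "h3k27ac_EB.bedgraph",
    "input_EB.bedgraph", "fragments.bed", "interactions.tsv", "genes.tsv",
    "variants.tsv", "ld.tsv",
)


@dataclass
class PipelineConfig:
    """All stage parameters, with defaults matching the published procedure:
    ±500 bp dynamics pad, ±1 kb promoter pad, 12.5 kb stitching gap,
    interaction score >= 5, LD cascade r² 1 / 0.9 / 0.8, bait ±10 kb,
    999,999 shifts."""

    simulate: bool = True
    data_dir: str = ""  # read an existing dataset directory instead of simulating
    outdir: str = "regulink_out"
    seed: int = 0
    dynamics_pad: int = 500
    promoter_pad: int = 1000
    stitch_gap: int = 12_500
    score_min: float = 5.0
    sig_threshold: float = 5e-8
    n_shifts: int = 999_999
    mode: str = "trait_contrast"
    min_frac: float = 0.5
    bait_pad: int = 10_000
    foreground_trait: str = "platelet"
    background_trait: str = "red-cell"

    @classmethod
    def from_file(cls, path: str | Path, overrides: dict | None = None) -> "PipelineConfig":
        """Parse a flat ``key = value`` configuration file."""
        values: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            k, v = (s.strip() for s in line.split("=", 1))
            values[k] = v
        values.update(overrides or {})
        return cls.from_mapping(values)

    @classmethod
    def from_mapping(cls, values: dict) -> "PipelineConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in values.items():
            if k not in fields:
                raise ValueError(f"unknown configuration key {k!r}")
            ftype = fields[k].type
            if isinstance(v, str):
                if ftype == "bool":
                    v = v.lower() in ("1", "true", "yes")
                elif ftype == "int":
                    v = int(v)
                elif ftype == "float":
                    v = float(v)
            kwargs[k] = v
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr),
                    logging.FileHandler(outdir / "run.log")):
        handler.setFormatter(fmt)
        logger.addHandler(handler)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (artifact -> sha256 + params)."""
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    logger.info("pipeline start, seed=%d", cfg.seed)
    artifacts: dict[str, str] = {}

    def emit(name: str) -> None:
        artifacts[name] = _sha256(outdir / name)

    # ---- stage: simulate or load ------------------------------------------
    data_dir = outdir / "data"
    if cfg.simulate:
        dataset = generate(SimulationConfig(seed=cfg.seed))
        write_dataset(dataset, data_dir)
        logger.info("simulated dataset written to %s", data_dir)
    else:
        src = Path(cfg.data_dir)
        for name in _REQUIRED_DATA_FILES:
            if not (src / name).exists():
                raise FileNotFoundError(
                    f"stage 'load': missing required input {src / name}"
                )
        dataset = read_dataset(src)
        write_dataset(dataset, data_dir)
        logger.info("dataset loaded from %s", src)
    for name in sorted(p.name for p in data_dir.iterdir()):
        artifacts[f"data/{name}"] = _sha256(data_dir / name)
    ds = dataset
    layout = ds.layout

    # ---- stage: open-chromatin dynamics -----------------------------------
    progenitors = {c: ds.open_chromatin[c] for c in ("HSC", "CMP", "MEP")}
    patterns = dyn.presence_patterns(ds.open_chromatin["MK"], progenitors,
                                     ds.open_chromatin["EB"])
    # toy stand-in for progenitor acetylation: high-signal H3K27ac footprints
    acet = []
    for chrom in layout.names:
        starts, ends, values = ds.h3k27ac["MK"].runs(chrom)
        acet.extend(
            GenomicInterval(chrom, int(s), int(e))
            for s, e, v in zip(starts, ends, values) if v >= 2.0
        )
    labels = dyn.annotate_labels(
        ds.open_chromatin["MK"], ds.ctcf["MK"], ds.enhancer_segments["MK"],
        IntervalSet(acet, layout=layout), layout, pad=cfg.dynamics_pad,
    )
    dynamics_table = patterns.merge(labels, on="peak_id")
    dynamics_table.to_csv(outdir / "dynamics.tsv", sep="\t", index=False)
    dyn.category_summary(patterns).to_csv(
        outdir / "dynamics_summary.tsv", sep="\t", index=False
    )
    emit("dynamics.tsv")
    emit("dynamics_summary.tsv")
    frac_cat = float((patterns.category != "UNCATEGORIZED").mean())
    logger.info("dynamics: %d peaks, %.1f%% categorized", len(patterns),
                100 * frac_cat)

    # ---- stage: super-enhancer calling ------------------------------------
    se_calls: dict[str, list[sec.SECall]] = {}
    for cell in ("MK", "EB"):
        filtered = sec.filter_promoter_enhancers(
            ds.enhancer_segments[cell], ds.promoter_segments, layout,
            pad=cfg.promoter_pad,
        )
        calls, thr = sec.call_superenhancers(
            filtered, ds.h3k27ac[cell], ds.input_signal[cell],
            max_gap=cfg.stitch_gap,
        )
        se_calls[cell] = calls
        supers = [c for c in calls if c.is_super]
        others = [c for c in calls if not c.is_super]
        write_bed(
            IntervalSet(
                [dataclasses.replace(c.region, label=f"{cell}_SE_rank{c.rank}")
                 for c in supers], layout=layout),
            outdir / f"se_{cell}.bed",
        )
        write_bed(
            IntervalSet(
                [dataclasses.replace(c.region, label=f"{cell}_other_rank{c.rank}")
                 for c in others], layout=layout),
            outdir / f"other_enhancers_{cell}.bed",
        )
        pd.DataFrame(
            [
                {
                    "chrom": c.region.chrom, "start": c.region.start,
                    "end": c.region.end, "score": c.score, "rank": c.rank,
                    "is_super": c.is_super, "n_constituents": len(c.constituents),
                }
                for c in calls
            ]
        ).to_csv(outdir / f"secalls_{cell}.tsv", sep="\t", index=False,
                 float_format="%.17g")
        pd.DataFrame(
            [
                {"se_rank": c.rank, "is_super": c.is_super,
                 "constituent": m.label or f"{m.chrom}:{m.start}-{m.end}",
                 "chrom": m.chrom, "start": m.start, "end": m.end}
                for c in calls for m in c.constituents
            ]
        ).to_csv(outdir / f"constituents_{cell}.tsv", sep="\t", index=False)
        for name in (f"se_{cell}.bed", f"other_enhancers_{cell}.bed",
                     f"secalls_{cell}.tsv", f"constituents_{cell}.tsv"):
            emit(name)
        logger.info("%s: %d SEs / %d other enhancers (cutoff %s)",
                    cell, len(supers), len(others),
                    f"{thr.cutoff_score:.1f}" if thr.cutoff_score else "n/a")

    mk_super = [c for c in se_calls["MK"] if c.is_super]
    eb_super = [c for c in se_calls["EB"] if c.is_super]
    ov = sec.se_overlap(mk_super, eb_super, min_frac=cfg.min_frac)

    cons_tbl, se_tbl = sec.trace_se_opening(
        mk_super, ds.open_chromatin["MK"], progenitors, layout,
        pad=cfg.dynamics_pad,
    )
    cons_tbl.to_csv(outdir / "se_opening_MK.tsv", sep="\t", index=False)
    emit("se_opening_MK.tsv")

    # ---- stage: enhancer-to-gene mapping ----------------------------------
    frag_index = pchic.FragmentIndex(ds.fragments)
    baits = pchic.build_baits(frag_index, ds.genes)
    mk_constituents = [m for c in mk_super for m in c.constituents]
    mk_typical = [m for c in se_calls["MK"] if not c.is_super for m in c.constituents]
    all_enh = mk_constituents + mk_typical
    gene_sets = pchic.interacting_genes_bulk(
        all_enh, frag_index, baits, ds.interactions, cfg.score_min
    )
    gene_links: dict[str, set[str]] = {}
    link_rows = []
    for iv, genes in zip(all_enh, gene_sets):
        lab = iv.label or f"{iv.chrom}:{iv.start}-{iv.end}"
        for g in sorted(genes):
            gene_links.setdefault(g, set()).add(lab)
            link_rows.append({"enhancer": lab, "gene": g})
    pd.DataFrame(link_rows, columns=["enhancer", "gene"]).to_csv(
        outdir / "enhancer_gene_links.tsv", sep="\t", index=False
    )
    emit("enhancer_gene_links.tsv")
    expr_tbl, n_unlinked = sec.expression_by_connectivity(
        ds.genes, gene_links,
        {iv.label for iv in mk_constituents},
        {iv.label for iv in mk_typical},
    )
    expr_tbl.to_csv(outdir / "expression_by_connectivity.tsv", sep="\t",
                    index=False, float_format="%.17g")
    emit("expression_by_connectivity.tsv")

    feature_tbl = pchic.fragment_feature_table(
        frag_index, ds.interactions,
        {"ctcf": ds.ctcf["MK"], "open_chromatin": ds.open_chromatin["MK"]},
        score_min=cfg.score_min,
    )
    feature_tbl.to_csv(outdir / "fragment_features.tsv", sep="\t", index=False)
    emit("fragment_features.tsv")

    # ---- stage: variant assignment ----------------------------------------
    resources = asg.AssignmentResources(
        genes=ds.genes,
        promoter_segments=ds.promoter_segments,
        enhancer_segments=ds.enhancer_segments["MK"],
        fragments=frag_index,
        baits=baits,
        interactions=ds.interactions,
        ld=ds.ld,
        layout=layout,
        score_min=cfg.score_min,
        promoter_pad=cfg.promoter_pad,
        bait_pad=cfg.bait_pad,
    )
    results, assign_summary = asg.assign_all(ds.variants, resources)
    pd.DataFrame(
        [
            {
                "sentinel_id": r.sentinel_id,
                "tier": r.tier,
                "genes": ";".join(r.genes),
                "proxies": ";".join(r.proxy_ids),
            }
            for r in results
        ]
    ).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    emit("assignments.tsv")
    logger.info("assignment: %d/%d variants assigned",
                assign_summary["n_assigned"], assign_summary["n_variants"])

    mk_constituent_set = IntervalSet(mk_constituents, layout=layout)
    mk_typical_set = IntervalSet(mk_typical, layout=layout)
    fisher = asg.se_te_variant_enrichment(
        ds.variants, mk_constituent_set, mk_typical_set
    )

    # ---- stage: permutation enrichment ------------------------------------
    mk_specific_constituents = IntervalSet(
        [m for i in ov.a_specific for m in mk_super[i].constituents],
        layout=layout,
    )
    enr_rows = []
    for name, regions in (
        ("MK_specific_SE_constituents", mk_specific_constituents),
        ("MK_typical_enhancers", mk_typical_set),
    ):
        result = perm.test_region_enrichment(
            ds.variants, regions, layout,
            mode=cfg.mode, sig_threshold=cfg.sig_threshold,
            n_shifts=cfg.n_shifts, seed=cfg.seed,
            foreground=cfg.foreground_trait, background=cfg.background_trait,
        )
        enr_rows.append(
            {
                "region_set": name, "mode": result.mode,
                "observed": result.observed, "rank": result.rank,
                "empirical_p": result.pvalue, "n_shifts": result.n_shifts,
            }
        )
        logger.info("enrichment %s: empirical P = %.3g", name, result.pvalue)
    pd.DataFrame(enr_rows).to_csv(outdir / "enrichment.tsv", sep="\t",
                                  index=False, float_format="%.17g")
    emit("enrichment.tsv")

    summary = {
        "n_peaks": len(patterns),
        "fraction_categorized": frac_cat,
        "n_se": {c: sum(1 for x in se_calls[c] if x.is_super) for c in ("MK", "EB")},
        "n_shared_se": len(ov.shared_a),
        "n_se_fully_open_mk": int(se_tbl.fully_open_in_progenitors.sum()),
        "n_unlinked_genes": n_unlinked,
        "assignment": assign_summary,
        "se_te_fisher": {
            "table": fisher.table.tolist(),
            "odds_ratio": fisher.odds_ratio,
            "p_value": fisher.p_value,
        },
        "enrichment": enr_rows,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    emit("summary.json")

    manifest = {
        "parameters": {
            f.name: getattr(cfg, f.name) for f in dataclasses.fields(cfg)
        },
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d artifacts", len(artifacts))
    return manifest
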