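# regulink

**regulink** links non-coding GWAS variants for blood-cell traits to the genes
they most probably regulate, using the regulatory landscape of the relevant
cell types — megakaryocytes (MK, the platelet precursor) and erythroblasts
(EB, the red-cell precursor). Most trait-associated variants are intronic or
intergenic; assigning them to the *nearest* gene is often wrong because
enhancers act over long ranges through chromatin loops. The package
implements the computational core of an integrative annotation strategy for
such variants, exercised end to end on a deterministic synthetic study so
that every stage is testable without any controlled-access data.

## What it computes

1. **Open-chromatin opening dynamics** (`regulink.dynamics`). A reference
   cell type's open-chromatin peaks are classified by their presence
   (minimum 1 bp overlap) in the progenitor compartments HSC → CMP → MEP and
   in the other terminal cell type: category I `(1,1,1,1)` open throughout;
   II `(1,1,1,0)` open throughout but closed in the other terminal cell;
   III `(0,0,0,0)` opened only at the final stage in the reference cell;
   IV `(0,0,0,1)` opened at the final stage in both terminal cells. All
   other patterns are reported as UNCATEGORIZED.

2. **Super-enhancer (SE) calling** (`regulink.superenhancers`). Enhancer
   segments are cleared of promoter states ±1 kb, stitched when within
   12.5 kb, and scored by background-subtracted H3K27ac signal
   `max(0, Σ treatment − Σ input)`. On the ascending rank curve scaled to
   the unit square, the SE cutoff is the point where a slope-1 tangent
   touches the curve, i.e. `argmax(xᵢ − yᵢ)`; regions scoring strictly above
   the cutoff are SEs, their members SE constituents, the rest typical
   enhancers (TEs). SE sets of two cell types are compared by requiring
   ≥ 50 % of either SE's length to overlap.

3. **Promoter-capture Hi-C gene mapping** (`regulink.pchic`). Restriction
   fragments (HindIII-like) tile the genome; baits are fragments containing
   gene TSSs. A region is assigned to a gene when an interaction with score
   ≥ 5 connects one of its fragments to that gene's bait (bait–bait
   interactions count in both directions; bait→prey contributes nothing to
   a region on the bait side).

4. **Tiered variant→gene assignment** (`regulink.assignment`). Exonic
   variants keep their VEP gene if it is expressed (FPKM ≥ 1) and the
   variant is outside enhancers; variants in promoter states ±1 kb take the
   genes of the contained TSSs; expressed exonic variants inside enhancers
   additionally gain interacting bait genes; the rest are mapped through
   fragment interactions. Unassigned variants cascade through LD proxies at
   r² = 1, ≥ 0.9, ≥ 0.8, and finally against baits ±10 kb.

5. **Circular genomic permutation enrichment** (`regulink.permutation`).
   Variants are ordered around a circular genome (the first chromosome
   follows the last); their P-value vector is rotated by random offsets
   (default 999,999 shifts) while positions, traits and region memberships
   stay fixed. The per-dataset statistic (significant-in-region count, its
   hypergeometric tail, or a one-sided exact platelet-vs-red-cell contrast)
   is recomputed per rotation, and the empirical P is
   `rank / (n_shifts + 1)` under the add-one rule — never zero, and
   preserving the local correlation of nearby variants.

A deterministic generator (`regulink.simulate`) produces a complete toy
study — genome, five cell types' peaks with planted opening categories,
SE-like H3K27ac clusters, fragment grid, promoter-anchored interactions
with designated target genes, variants with block LD and a configurable
planted enrichment odds ratio θ — together with a truth record that the
test suite checks against exactly.

## Worked example

```bash
regulink run-all --seed 1 --out out/
```

runs simulate → dynamics → se-call → map-genes → assign → enrich and logs:

```
dynamics: 600 peaks, 88.5% categorized
MK: 16 SEs / 160 other enhancers (cutoff 1219.1)
EB: 16 SEs / 160 other enhancers (cutoff 1272.6)
assignment: 117/229 variants assigned
enrichment MK_specific_SE_constituents: empirical P = 0.00436
enrichment MK_typical_enhancers: empirical P = 1
```

Reading: 88.5 % of the 600 MK open-chromatin peaks fall into the four
differentiation categories; the SE caller recovers exactly the 16 planted
H3K27ac clusters per cell type above the tangent cutoff; about half the
sentinel variants reach a gene through the tiered decision tree; and under
the planted θ = 5 enrichment, platelet-trait variants are significantly
concentrated in MK-specific SE constituents (empirical P ≈ 0.004 over
999,999 rotations) but not in typical enhancers. `out/summary.json` and
`out/manifest.json` hold the full stage summaries, the effective
parameters, and a SHA-256 hash per artifact; rerunning with the same seed
reproduces the hashes bit for bit.

Every stage is also a subcommand over explicit files, e.g.

```bash
regulink se-call --enhancers enh.bed --promoters prom.bed \
    --treatment h3k27ac.bedgraph --input input.bedgraph \
    --chrom-sizes chrom.sizes --gap 12500 --promoter-pad 1000 \
    --out-prefix mk
```

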