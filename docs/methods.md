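# Methods

## Scope and model

regulink reimplements, as a reusable pipeline, the computational chain that
connects blood-trait GWAS variants to target genes through the regulatory
landscape of megakaryocytes (MK) and erythroblasts (EB): open-chromatin
opening dynamics across the HSC → CMP → MEP → MK/EB differentiation
hierarchy, super-enhancer (SE) calling from H3K27ac signal, promoter-capture
Hi-C (PCHi-C) based region→gene mapping, a tiered variant→gene decision
tree with an LD fallback, and a circular genomic permutation test for
enrichment of significant variants in region sets. Upstream data production
(alignment, peak calling, genome segmentation, interaction scoring,
expression quantification, consequence prediction) is out of scope: peaks,
enhancer/promoter state segments, signal densities, scored interactions,
FPKM values and consequence classes are consumed as inputs.

Coordinates are 0-based half-open (BED) internally; variant and proxy
positions are 1-based in TSV files and converted on load. The chromosome
order declared in the chrom-sizes file is canonical — it fixes interval-set
sort order and the circularization order of the permutation test.

## Opening dynamics

Presence of a reference peak in another cell type means ≥ 1 bp overlap with
that cell type's peak set. The four named categories are exactly the
patterns (HSC, CMP, MEP, other-terminal) = (1,1,1,1), (1,1,1,0), (0,0,0,0)
and (0,0,0,1); the remaining 12 patterns are reported as UNCATEGORIZED with
their pattern retained, so the uncategorized remainder stays auditable.
CTCF labels use unpadded peak coordinates; enhancer-state and
progenitor-acetylation labels use peaks extended by ±500 bp, the pad
accounting for the spatial offset between an accessibility summit and the
flanking acetylation signal. The terminal-cell column likewise uses
unpadded 1 bp overlap. In the pipeline's synthetic run the
"progenitor acetylation" annotation is stood in for by the high-signal
(≥ 2 per bp) H3K27ac footprints of the simulated track, since the toy study
does not simulate an external progenitor ChIP-seq compendium.

## Super-enhancer calling

Enhancer segments overlapping promoter, weak-promoter or bivalent-promoter
states extended by ±1 kb are removed entirely before stitching, to avoid
promoter acetylation contaminating enhancer scores. Stitching joins sorted
segments whose gap (start_next − end_prev) is ≤ 12,500 bp; "touching"
counts as gap 0. Each stitched or single region is scored as
max(0, Σ treatment − Σ input) over the region, with optional excluded
intervals (e.g. a blacklist) subtracted base-wise; both tracks carry a
library-size scale factor applied at summation time, so multiplying both
tracks by a common constant cannot change the SE/TE partition. Total
signal (not per-bp density) is ranked, following the classical stitched-
enhancer convention; a density mode was considered and rejected to keep a
single documented behaviour.

The cutoff uses the geometric rank-curve rule: sort scores ascending, scale
ranks x and scores y to [0, 1], and take the cutoff index
i\* = argmax(xᵢ − yᵢ), the point where a unit-slope tangent touches the
curve; regions scoring strictly **above** y[i\*] (unscaled) are SEs. Ties
in rank are broken by genomic position (earlier = better), making the
ranking a strict total order. Degenerate inputs: an empty enhancer set is
an error; fewer than 3 stitched regions or an all-zero score vector yield
no SE and a warning, because the tangent construction is undefined on flat
or two-point curves.

Two SE sets are compared symmetrically: a pair is "shared" when the overlap
is at least `min_frac` (default 0.5) of **either** SE's length. The
either-length reading is the most inclusive symmetric interpretation of a
50 %-of-length rule; `min_frac` is exposed for sensitivity analysis.

## PCHi-C gene mapping

Fragments tile each chromosome without overlap; baits are fragments
overlapping ≥ 1 TSS and carry all such genes. Interactions are stored
directed (bait → other end) with a continuous confidence score and are
"called" at score ≥ 5 (inclusive, applied uniformly to bait–bait pairs). A
query region takes the union over all fragments it overlaps of the genes of
every called interacting bait; a fragment that is itself a bait honours
bait–bait interactions in both directions; bait→non-bait-prey interactions
contribute nothing to a region sitting on the bait. The per-fragment
feature table (length, called-interaction degree, per-feature overlap
counts) is exported as-is; no regression is fitted on it.

## Variant assignment

Tier order: coding → promoter → enhancer_plus_bait → fragment_interaction →
ld_r2_1 → ld_r2_09 → ld_r2_08 → bait_10kb → unassigned; the first tier
producing a non-empty gene set is recorded, and unassignable variants are
emitted with tier `unassigned`, never dropped. "Not expressed" is
FPKM < 1; a VEP gene missing from the expression table is treated as not
expressed with a warning. Promoter resolution assigns the gene(s) whose TSS
lies inside the ±1 kb-padded promoter segment containing the variant — not
the nearest gene. An expressed exonic variant inside an enhancer segment
keeps its VEP gene and adds the interacting bait genes; an exonic variant
whose gene is not expressed falls through to the promoter/interaction
logic. Within one LD level all qualifying proxies' gene sets are unioned
and the level succeeds if the union is non-empty; levels are r² = 1,
≥ 0.9, ≥ 0.8 in that order. The final fallback assigns the genes of baits
whose fragment ±10 kb covers the variant, reflecting the capture design's
insensitivity to short-range interactions.

For summaries, a gene's position is the mean of its TSSs. Each assigned
variant is classified nearest-only / nearest-plus-distal / distal-only
against the nearest-TSS gene on its chromosome, and the median
variant→assigned-TSS distance is reported next to the nearest-gene median
as the coordinate-based comparator.

The SE-vs-TE enrichment table counts elements by default: SE constituents
(rows) bearing ≥ 1 variant versus not, against TEs. The odds ratio is the
cross-product ad/bc (undefined and reported as such when a margin is zero,
with P = 1), and the P-value is the two-sided exact hypergeometric test. A
bp-normalised table (variant counts against remaining base pairs) is
available behind `mode="bp"`; element counting is primary because it does
not let a few very long elements dominate.

## Circular permutation test

Variants are sorted by (declared chromosome order, position, id); the
P-value vector is rotated so that position i receives the value originally
at (i − offset) mod n. Offsets are drawn uniformly with replacement from
1..n−1 (duplicates allowed), or enumerated exactly once each in exhaustive
mode. Because only n−1 distinct rotations exist, the per-dataset statistic
is evaluated once per distinct offset and sampled offsets index into those
values — identical to per-shift recomputation and verified against an
independent brute-force oracle.

Three statistics are provided because the appropriate contrast depends on
the question: `count` (significant foreground-trait variants inside the
region set, larger = more extreme), `hypergeom_tail` (upper tail
probability of that count given the rotated number of significant
foreground variants), and the default `trait_contrast` (one-sided exact P
on significant foreground vs background variants inside vs outside the
region set — platelet versus red-cell in the pipeline). Variants of
neither trait class (e.g. pleiotropic ones) stay in the circle, so their
P-values rotate, but are excluded from both count groups. The empirical P
uses the add-one rule, rank/(n_shifts + 1), counting ties as at least as
extreme: with 999,999 shifts the observed rank is divided by 1,000,000 and
the empirical P can never be 0. Rotation preserves the multiset of
P-values and the run structure of significant flags, so local LD-induced
clustering of significant variants is retained under the null.

## Synthetic study

The generator emulates the statistical structure the pipeline assumes, not
nucleotides or reads. Defaults (the study conditions): 4 chromosomes ×
8 Mb; ~4 kb fragments (500 bp minimum plus a geometric tail); 240 genes
(~20 % not expressed, FPKM < 1); per cell type 16 SE clusters of 4–9
constituents with gaps of 1.2–9 kb (all below the 12.5 kb stitch gap) of
which ~30 % are shared between MK and EB, plus 160 dispersed enhancers
placed ≥ 13 kb from anything so they stitch with nothing, plus 20 decoy
enhancers inside promoter zones that the promoter filter must remove;
constituent H3K27ac density ~12 per bp against ~1 for dispersed enhancers
and a flat 0.2 input, making cluster scores ≳ 50× dispersed scores so the
planted clusters are exactly the called SEs; 600 MK reference peaks with
opening-category fractions (I, II, III, IV) = (0.40, 0.10, 0.20, 0.18),
leaving 12 % uncategorized, and guaranteed-overlap jitter (≤ 300 bp) with
inter-peak margins large enough that presence patterns are exact by
construction; 110 platelet and 110 red-cell sentinels plus ~4 %
"other"-trait (pleiotropic stand-in) variants; 3 LD proxies per sentinel
within ±50 kb, r² uniform on [0.8, 1] with 15 % exactly 1; baseline
significance odds 0.5 (about one third of variants significant, so the
permutation statistic has enough resolution to be calibrated at toy scale).

Planted enrichment: 25 % of each trait's variants are placed inside the
designated set (MK-specific SE constituents) and 10 % inside typical
enhancers — GWAS variants concentrate in regulatory elements, and without
the TE share the SE-vs-TE table has an empty margin at toy scale. A
variant's odds of being "significant" are baseline × θ when it is a
variant of the enriched trait (platelet by default) lying in the
designated set; θ defaults to 5, analogous to a fivefold SE-vs-TE
enrichment, θ = 1 gives the no-enrichment null and θ = 0 annihilates
significance there. Significant variants draw P log-uniformly in
[10⁻¹², 10⁻⁸] (below the 5 × 10⁻⁸ threshold); all others draw P uniformly
on (0, 1). One seed drives everything through fixed per-component
sub-streams; identical config + seed reproduces byte-identical files, and
placement failure after bounded rejection sampling raises an "infeasible
configuration" error rather than degrading silently.

What the toy does **not** model: sequence, read sampling and mapping noise,
realistic coalescent LD (proxies are positional jitter with assigned r²),
inter-chromosomal interactions, distance-decay of interaction scores, and
copy-number or blacklist artefacts. Passing tests therefore demonstrate
correctness of the algorithms under the planted statistical structure, not
robustness to real-data noise.

## Numerical and testing choices

Exact tests are delegated to scipy (`fisher_exact`, `hypergeom`); the test
suite checks them against full enumeration with rational arithmetic
(agreement within 10⁻¹², including the standard 1 + 10⁻⁷ minimum-likelihood
gate for the two-sided P). Interval primitives are checked against
quadratic brute force and union-find transitive closure on 1,000 random
intervals; the SE cutoff against a brute-force scan of the scaled curve;
the permutation machinery against independent enumeration of all rotations
for n ≤ 12. Statistical acceptance checks run the generator at reduced
size (2 chromosomes × 4 Mb, 200 sentinels): 500 replicates at θ = 1 must
keep the rejection rate at α = 0.05 within [0.03, 0.07], and at θ = 5 the
SE foreground must beat the TE background in ≥ 90 % of 100 replicates —
both pass with margin. Problem sizes were chosen so the full suite and the
end-to-end run stay interactive on a single CPU.

The pipeline (`run_all`) echoes every effective parameter into
`manifest.json` with a SHA-256 hash per artifact; defaults equal the
procedure's stated values (±500 bp, ±1 kb, 12.5 kb, score ≥ 5, r² cascade
1/0.9/0.8, ±10 kb, 999,999 shifts). Logs (timestamps, seed) go to stderr
and `run.log`, which is deliberately outside the hashed manifest.

## Known limitations

- `interacting_genes` scans the interaction table per query; the bulk
  variant of the same semantics (`interacting_genes_bulk`) should be used
  for thousands of regions.
- The LD cascade re-annotates proxies as plain non-coding positions;
  proxies' own consequence classes are not modelled.
- The either-length shared-SE rule and the element-counting enrichment
  table are documented choices among defensible alternatives; both expose
  parameters (`min_frac`, `mode`) for sensitivity analysis.
- The permutation test assumes a single genome-wide variant panel;
  stratified or trait-conditional rotation schemes are not implemented.
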