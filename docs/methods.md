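# Methods

This note documents the models and numerical choices behind `scdepth`:
what the synthetic generator simulates (and deliberately does not), how
each pipeline stage is defined, and where the design was genuinely open.

## Synthetic data generator

The generator (`scdepth.datagen`) emulates a droplet scRNA-seq
experiment on sorted CD4+ T cells with these components:

**Expression structure.** Per-gene relative expression shares are drawn
from a Gamma(0.4, 1) and normalised; a configurable fraction of genes
(default 1%) carries the mitochondrial `MT-` prefix and holds a fixed
share (default 5%) of expression. Canonical marker symbols (CD4,
CD3D/E/G, CCR7, CCR4, CCR6, FOXP3, IL2, CD69, CD40LG, SELL) are always
present; the CD4/CD3 lineage markers are pinned to a solidly detectable
baseline (85th percentile weight) so that expressing fractions can
discriminate T cells from contaminants.

**Subtypes.** Five populations by default — naïve 42%, memory 20%, Th17
14%, cytotoxic 12%, Treg 10% — each with 50 disjoint marker genes whose
means are multiplied by `de_factor` (default 4) in that subtype.
Markers are drawn from the *below-median* expression band
(`marker_expression_band = (0, 0.5)`): subtype-defining transcripts
(chemokine receptors, transcription factors) are low-abundance in real
UMI data, and this is what makes the simulated subtypes as
transcriptionally similar as real CD4+ subsets rather than trivially
separable blocks. With these defaults the full-depth pipeline recovers
the truth at ARI ≈ 0.95 — high but not saturated, leaving room for
subsampling to degrade it. A 2% contaminant population has CD4/CD3
means set to zero.

**Conditions.** A stimulated sample multiplies all means by a global
activation factor (default 1.3; TCR stimulation raises transcription
broadly, which is what lifts genes- and UMIs-per-cell), boosts a 10%
gene subset 3-fold (always including IL2 and CD69) and suppresses a
disjoint 5% subset to 0.4×. Two configs differing only in `condition`
share all gene-level structure (separate seed streams for parameters vs
sampling), which is what makes paired samples integrable.

**Counts and reads.** Library sizes are log-normal (default median
2,500 UMIs, sdlog 0.35). Latent molecule counts are gamma-Poisson
(negative binomial) with dispersion 0.4. Sequencing is modelled at the
molecule level: each molecule receives NB(mean r, shape 1/0.5) reads,
with r set so the realized total equals `mean_reads_per_cell` (default
120,000) in expectation, and a molecule is *observed* as a UMI only if
it receives ≥ 1 read. Consequently UMIs and detected genes per cell
rise monotonically with depth, and saturation (1 − UMIs/reads) traces
the familiar curve, ~87% at 20k reads/cell rising to ~98% at full
depth.

**What is not simulated:** raw reads, barcode errors, doublet kinetics,
ambient RNA, batch effects beyond the condition shift, and
mapping-rate terms (our saturation therefore lacks the unmapped-read
component of the upstream pipeline's definition). Passing tests show
the *framework* behaves correctly on data with the assumed statistical
shape; absolute accuracies on real tissue will differ.

**Default sizes.** 2,000 genes × 3,000 cells at 120k reads/cell is the
package's default scenario for tests and the acceptance script; it is a
desk-scale rendering of a high-depth 10x experiment (real references:
~20k genes, ~5k cells, 260–333k reads/cell) chosen so the full grid
runs in minutes on one CPU while preserving every qualitative regime
(saturation plateau, marginal subtype separability, QC removal rates).

## Quality control

Order matters and is fixed: (1) drop cells expressing < 200 genes;
(2) drop genes expressed in < 3 cells; (3) recompute metrics; (4) drop
cells outside 3 MADs (scaled by 1.4826, the normal-consistency
constant) on any of %mito (high side only — low mitochondrial content
is not a defect), detected genes (both sides), total UMIs (both sides),
as a *union* of flags in a single pass. Zero-MAD metrics flag any value
off the median; zero-count cells are always removed. Removing all cells
raises an explicit error rather than returning an empty object. The
union-of-flags choice (vs sequential re-estimation) keeps the filter a
one-shot classification; a second pass removes ≤ 5% more cells on
default data (tested).

## Normalisation, HVGs, scaling, PCA

Log-normalisation is ln(1 + 10⁴·x/total). HVG statistics follow the
mean–dispersion convention: per gene, mean = ln(mean(exp(x) − 1) + 1)
and dispersion = ln(var/mean) of the back-transformed values,
z-scored within 20 equal-frequency mean bins; selection requires
0.0125 < mean < 8 and scaled dispersion > 0.5. Zero-variance genes get
−∞ dispersion (a relative tolerance of 1e−12 on the variance guards
against cancellation error declaring a constant gene variable).
Scaling regresses each gene on raw UMI count and %mito (raw rather
than log counts — the era's default; the alternative is one config
change away), standardises residuals and clips at ±10. PCA keeps 20
components (fixed by configuration; the manual inspection step of
interactive workflows is intentionally not reproduced). When fewer
HVGs pass the cutoffs than PCA needs (deep subsampling), the pipeline
falls back to the top genes by scaled dispersion and logs it.

## Clustering

SNN graph: k = 30 nearest neighbours in PC space (neighbour sets
include the cell itself), Jaccard edge weights, edges below 1/15
pruned. Louvain modularity optimisation at resolution 1 with a seeded
RNG; communities are relabelled by decreasing size so labels are
deterministic. Cluster pairs separated by fewer than 10 DE genes
(Wilcoxon, Bonferroni-adjusted p < 0.05, |ln FC| ≥ 0.25) are merged
iteratively, fewest-DE pair first — a quantified stand-in for the
"minimal differences" merge judgement, with the threshold configurable
and every merge logged. Clusters whose cells show *no* CD4 expression
and < 25% expressing fractions for each CD3 chain are excluded as
non-T-cell contaminants before any accuracy evaluation.

The marker test is a two-sided Wilcoxon rank-sum (normal approximation
with tie correction) on genes passing min.pct 0.1 and |ln FC| ≥ 0.25
prefilters. Bonferroni correction uses the **full gene axis** as the
denominator, not the tested subset: the prefilter selects extreme
genes, and adjusting only over survivors is anti-conservative (the
permutation null then produces false positives in ~15% of runs instead
of the nominal ≤ 5%).

## Subsampling

Read thinning keeps each read i.i.d. Bernoulli(f). Since only per-entry
read totals are stored, an entry's reads are first distributed over its
UMIs — one guaranteed read each plus a multinomial split of the excess
(realised by sequential conditional binomials, vectorised over
entries) — then each UMI's reads are thinned binomially and the UMI
survives if any read does. When every UMI has exactly one read this is
exactly binomial thinning of the counts. The thinning fraction for a
target depth is target / realised mean reads per cell. Cell
subsampling draws a uniform barcode subset from the post-QC cells and
re-runs QC on the subset (losses are not topped up). Replicate seeds
derive deterministically from the grid's base seed.

## Benchmark grid

The read-depth arm compares each thinned dataset's independent
clustering against the full-depth reference; the cell-number arm uses,
as reference, the clustering of *all* cells at the relevant depth.
Ground truth per cell is its cluster in the reference, matched by
barcode; cells absent from either side's post-QC/post-exclusion set are
not evaluated (the only well-defined handling of QC-discordant cells).
Classifier features are log-normalised (not scaled/regressed) HVG
expression — normalised space avoids leaking subsample-specific
scaling — with missing genes zero-filled and 500 trees, √p features per
split. Majority-vote ties break toward the reference cluster with more
predicted cells overall, then the lowest id, and are flagged.
Many-to-one mappings are allowed: a reference identity can go
unclaimed, in which case its sensitivity is 0. Grid-point failures are
logged and skipped, not fatal. The "full cell count" tile is a
cell-arm point at n = all post-QC cells, so every tile (including the
top one) goes through the identical subsample-recluster-evaluate path.

## Integration

Diagonal CCA: both samples restricted to the union of per-sample
top-2000 HVGs (ranked by scaled dispersion), gene rows standardised,
and the cells×cells cross-product decomposed by truncated SVD; the
singular vectors are the per-cell canonical embeddings. Reported
canonical correlations are the gene-space correlations of paired
canonical variates, sorted non-increasing. The CCA-vs-PCA filter
removes cells whose standardised profile is explained > 2× better by
their own sample's PCA basis than by the shared CCA basis (squared
projection norms over total sum of squares). Alignment warps each
canonical component of the smaller dataset onto the larger dataset's
empirical quantiles — exactly rank-preserving, exactly
distribution-matching at equal sizes; this realises the subspace-
alignment contract without the original implementation's metagene
dynamic-time-warping internals, which are not recoverable from its
description. Joint clustering reuses the SNN/Louvain machinery on the
aligned components; condition DE reuses the marker test on pooled
log-normalised values without further batch terms.

A note on the unaligned/aligned contrast: the "standard merged
analysis" that clusters by condition computes HVGs on the *merged*
data (where the stimulation response dominates variability); the CCA
path computes HVGs per sample, as its definition requires. Using the
per-sample union for the unaligned arm would hide the condition axis
and manufacture a mixed result.

## Determinism

Every stochastic step (generation, thinning, subsampling, PCA solver,
Louvain, random forest, tSNE) takes an explicit seed; `RunConfig`
fans a single global seed out to all of them and writes the resolved
configuration next to its outputs. Two runs with the same config
produce byte-identical TSVs (tested).

## Known limitations

- Accuracy values are properties of the simulated regime; the package
  reproduces the benchmark's *design* and directional conclusions, not
  any particular dataset's percentages.
- The merge rule and the CCA/PCA variance-ratio filter are quantified
  stand-ins for judgements that interactive workflows make by
  inspection; both are configurable and logged.
- Clustering defaults to Louvain (the era-appropriate algorithm);
  Leiden is available via ``cluster_method="leiden"``.
- `condition_de` pools samples without a per-gene batch model; with
  only two samples, condition and batch are confounded by design.
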