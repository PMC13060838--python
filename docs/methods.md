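# Methods

This note records the models, defaults, numerical choices and known
limitations behind `crecascade`. Nothing here states an empirical result the
test suite does not itself compute.

## Synthetic world

The generator (`crecascade.synth`) emits a ground-truth regulatory world and
observed screens against it. The world is a stated set of conditions, not a
tuning surface; its defaults are:

**Gene annotation.** Genes are placed without overlap on a small genome
(default 300 genes, 4 × 30 Mb chromosomes; the bundled pipeline config uses
2,000 genes). Baseline expression is lognormal (σ_log = 1.2, heavy-tailed,
TPM-like role) and per-cell NB dispersion lognormal around α ≈ 0.5 — the
typical overdispersion of UMI data. TSS = body start on `+`, body end − 1 on
`-`.

**CREs and true links.** A configurable fraction of CREs (default 15%) sit on
a TSS and act as promoters with strong negative effects (log2FC in
−[1, 3]); the rest are enhancer-class elements placed at log-uniform
distances (80% within 100 kb, the rest out to 2 Mb) from an anchor gene.
Anchors are drawn from the expressed half of the annotation
(weight ∝ √baseline) because targeted screens select candidate genes with
detectable expression. Active enhancer CREs carry 1 + Poisson(0.6) target
links (≈1.6 on average); 27% of links are silencers (positive log2FC under
CRISPRi), matching the up/down split such screens report. Link magnitude is
drawn from the weak regime |log2FC| ∈ [0.05, 0.3] and multiplied by a mild
distance-decay factor `(1 + d/10 kb)^-0.15`, so planted strength, like
chromatin signal, declines with distance. A 25% fraction of enhancer CREs is
inactive (no links).

**Evidence layers.** Chromatin signals are class-conditional lognormals
(promoter-like: H3K4me3-high; enhancer-like: H3K27ac/H3K4me1-high,
H3K4me3-low; inactive: low everything), scaled by a distance-decay factor
with exponent 0.25. TADs tile each chromosome with lognormal sizes (median
500 kb). Hi-C contact for a pair at distance d is
`1e4 · (d + 5 kb)^-0.8`, ×3 within a TAD, ×2 for a true link, with lognormal
noise (σ_log = 0.5). eQTL catalogs flag true links at a per-catalog rate
(0.5 / 0.35 / 0.08 for the T-cell-like, blood-like and unrelated-tissue
defaults) plus background pairs at 2–4%. Prediction sources comprise two
deterministic strategies (all genes within 100 kb; nearest up/downstream
gene) and three sampled ones with set recall and precision (GRN-like
0.40/0.15, model-prediction-like 0.45/0.32, eQTL-like 0.20/0.35). The tested
("candidate") universe is the union of all sources — a recall-oriented panel.

**Counts.** `count(cell i, gene g) ~ NB(s_i · d(donor_i, g) · b_g · 2^eff,
α_g)` with lognormal library sizes (CV default 0.5, mean umi/cell 5,000),
gene-wise lognormal donor multipliers (σ = 0.1 across 3 donors), and `eff`
the summed log2 effects of the cell's perturbation. ~80% of cells carry
exactly one identified gRNA; the remainder split between zero and two. A
targeted (CRE-mode) screen zeroes genes outside the cell's panel, emulating
panel-restricted readout. Trans propagation is off by default (so DE power
and calibration are interpretable against direct effects only); with
`propagate_trans=True` one multiplicative hop of the gene–gene network is
applied — used for cascade and mediation-decoy experiments. NB sampling is
gamma–Poisson, chunked at ~2M matrix entries per block.

What the generator does **not** emulate: ambient RNA, doublets, read-level
error, gRNA efficacy gradients within a target (guides are active/inactive),
and trans effects attenuated by knockdown depth. A green test therefore
establishes correctness of the analysis under the NB-with-covariates model,
not robustness to those artifacts.

## Differential expression engine

DESeq2-style pseudobulk testing, re-implemented:

* **Pseudobulk**: exact count sums per (perturbation, panel, donor) group;
  groups under `min_cells_per_group` (default 10) are dropped with a warning.
* **Size factors**: median-of-ratios over genes positive in every column,
  rescaled to geometric mean 1; library-size ratio fallback when no such gene
  exists.
* **Dispersion**: a pseudobulk column summing `n` iid NB(m, α) cells is
  treated as NB(n·m, α/n). The per-cell α_g is estimated once on the full
  (group + donor) design by method of moments on GLM residuals with a hat-value
  (leverage) correction — `E[(y−μ̂)²] ≈ (1−h)·var` — iterated once under NB
  weights, then shrunk 50/50 toward an `a0 + a1/mean` trend fitted across
  genes. The leverage correction matters: the full design uses ~1/3 of the
  residual degrees of freedom, and the uncorrected estimator is biased low
  enough to break type-I calibration. When more than 24 groups exist the
  estimation design is capped at the largest 24 (cost is quadratic in
  coefficients; dispersion is shared across contrasts). Note α̂ absorbs every
  variance source acting like extra-Poisson noise at the column level
  (including residual library-size variability), which is what calibration
  requires.
* **Wald test**: per perturbation, a 4-ish-parameter GLM (intercept,
  condition, donor dummies) on that perturbation's columns plus in-panel
  controls, fitted by batched IRLS (stacked 4×4 solves across all genes at
  once). p = 2Φ(−|β/se|); BH within perturbation; non-converged or boundary
  fits (|β| ≥ 25 nats) and all-zero genes get p = NA and leave the BH
  denominator.
* **Response universe**: CRE mode tests the TAP panel genes of the
  perturbation's library-panel pair (controls pooled within pair, all-pool
  fallback); promoter mode tests the top-N variable genes (N default 8,001
  capped at the panel size), ranked by median/MAD-standardized normalized
  dispersion within ≤20 mean bins.

## Link calling and classification

Coordinates are uniformly 0-based half-open; GTF-like inputs are converted at
the I/O boundary. CRE context precedence is promoter (overlap any
TSS ± 1,500 bp) > intragenic (CRE center inside a gene body) > intergenic.
Distance is unsigned, CRE center to the gene's nearest TSS; position is
proximal below 1,500 bp. Context × position yields five classes —
intergenic-proximal cannot occur because proximity to a TSS forces promoter
context — and the classes partition every same-chromosome link (asserted at
run time). Significance is adj_p < FDR (default 0.1) with an optional
|log2FC| gate (default 0, since link calling reports no gate; the cascade
gates are separate). Control-promoter and cross-chromosome associations are
excluded before any downstream analysis but preserved in an audit table.

## Enhancer prioritization

A distal link is high-confidence iff it is significant, its CRE has **no**
significant proximal link anywhere (mediation filter — the conservative
answer to indirect effects, CRISPRi spreading and dCas9 roadblocking),
and its distance is ≤ 1 Mb (beyond which distal CREs are indistinguishable
from non-significant elements in chromatin and contact features; the cut is
configurable off). Labels follow sign: enhancer if log2FC < 0 under CRISPRi,
silencer otherwise. Hi-C comparison matches on distance-bin identity
(deterministic, mirrors binned reporting) rather than nearest-neighbor
matching. Same-TAD means no TAD boundary strictly between CRE center and
target TSS. Chromatin signals are carried descriptively and summarized per
bin; they are not hard filters (an open design point — the threshold filters
can be added in config).

## Enrichment statistics

All 2×2 tests report the sample cross-ratio OR with Haldane–Anscombe +0.5
correction when a cell is zero (flagged); the exact p always uses the
uncorrected table (scipy's conditional hypergeometric; tests verify it
against full enumeration for every table with N ≤ 30). The eQTL-enrichment
universe defaults to pairs predicted by ≥1 source (the a-priori prioritized
set); `universe="all"` uses every tested pair. The TF-target test is
one-sided (enrichment), with DEG gates adj_p < 0.1 and |log2FC| > 0.5,
≥50 annotated targets and ≥5 DEGs, and concordance defined against the
annotated mode of regulation under knockdown (activating target expected
down). Gene-set tests are hypergeometric upper-tail with BH across sets;
discreteness makes them conservative at small overlaps.

## Cascades and disease programs

Hop-1 edges are the thresholded DEGs of perturbed layer-0 targets, hop-2
those of hop-1 genes; layer membership is first-reach (BFS), self-edges are
dropped, and `top_k` truncation exists for display exports only. The |log2FC|
gate is a required parameter with two named presets (0.2 "map", 0.1
"network") because both appear in practice. Disease programs aggregate
layer-0 targets and hop-1 genes (hop 2 stays in the map but out of programs,
matching the narrower definition used for program compilation); terms
enriched (BH-adjusted p < 0.05) in more than `min_shared` (default 5)
diseases are shared, in exactly one unique.

## Numerical and degenerate-input choices

* IRLS: working-response updates, η clipped to ±30, ridge 1e-10, tol 1e-8,
  ≤60 iterations; convergence failure → p = NA.
* Dispersion clipped to [1e-8, 100] (per cell); hat values clipped at 0.95.
* Empty pseudobulk groups, empty hop layers, zero-CRE diseases, and bins
  without significant pairs all degrade to explicit NA/empty outputs, never
  exceptions; genuinely inconsistent inputs (id mismatches, dimension
  mismatches, coordinate violations) raise typed errors that the CLI maps to
  exit codes 2/3/4.
* All randomness flows from explicit integer seeds; same seed, same bytes.

## Known limitations

* The Wald test is mildly anti-conservative in the extreme small-sample limit
  (2 residual df per contrast); the simulation suite bounds the effect
  (null type-I ≈ 5% at the bundled scale) but very low column counts with
  near-zero counts deserve caution.
* The mediation filter is deliberately conservative: a CRE with any real
  proximal effect loses all its distal links, trading recall for precision.
* Desk-scale screens (hundreds of cells per CRE) are underpowered for
  |log2FC| ≈ 0.1 effects; the acceptance suite reports (rather than gates)
  power in that regime.
* Hi-C contacts are consumed pre-normalized; no matrix balancing is
  performed.
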