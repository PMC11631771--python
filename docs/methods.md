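# Methods

This note documents the models, parameter choices and numerical conventions
behind `plaquenet`, and what the synthetic benchmarks do and do not
demonstrate about real tissue data.

## The synthetic study

Every quantitative claim the test suite and `scripts/acceptance.py` make is
measured on data from `plaquenet.simulate`, whose defaults define the study
conditions.

**Lattice.** Spots sit on a triangular lattice: odd rows offset by half the
pitch, rows √3/2 · pitch apart, so all six nearest-neighbor distances equal
the pitch exactly. Defaults follow the Visium geometry: 55 μm spots,
100 μm pitch, 20×20 spots per section. Region labels (the six cortical
layer annotations plus WM) are assigned to contiguous row bands — the
simplest geometry that yields region-restricted expression programs; it
does not emulate curved laminae or the smoothed boundaries a
spatially-aware clustering would produce.

**Amyloid point process.** Cluster centers are uniform over the section's
bounding box (5 by default); each center emits 30 binaries displaced by an
isotropic Gaussian (sd 150 μm), so center distances are Rayleigh with mean
σ√(π/2) — a check the tests use. Areas are log-normal (median 50 μm²,
log-sd 0.6) and the diameter is derived as that of the area-equivalent
circle. Real plaque fields are not Poisson-cluster processes (staging,
laminar preference, autofluorescence artifacts), so passing tests show the
integration arithmetic is right, not that the process model is.

**Counts.** Per gene g and spot s,

    μ_gs = L_s · exp(α_g + λ · f_m(g) · 1[s ∈ home region of m(g)] + β_g · a_s)

with counts negative binomial (size θ = 10 by default; variance
μ + μ²/θ). `L_s` is a log-normal library factor (log-sd 0.3). Each planted
module m has one latent factor draw per generator call — one call is one
sample — applied to all spots of its home region. A per-spot i.i.d. factor
was considered and rejected: pseudobulk summation would average it away and
no co-expression would survive at the level where networks are built. The
amyloid covariate `a_s` is the standardized per-spot total binary area,
computed with the same intersection rule the caller uses, so planted
β coefficients are on exactly the scale the calibration recovers.
Every generator takes an explicit seed and uses one local
`numpy.random.Generator`; identical configs give byte-identical output
files, which the determinism check asserts.

## Amyloid integration and the gene caller

**Assignment rule.** Binary i joins spot s iff
dist(centers) ≤ r_eff + diameter_i/2, a circle-circle intersection with the
binary's exported diameter. The effective spot radius is pitch/2 (50 μm)
rather than the physical 27.5 μm: capture areas tile only ~55% of the
section and the expanded radius attributes binaries in the gaps to the
nearest spot(s) while keeping double assignment rare. It is configurable;
binaries intersecting k spots count in all k.

**Gi\*.** Binary weights over the hex neighbor graph (edges up to
pitch·1.05), self-weight included, population standard deviation with the
(n−1) form inside the root — the classical statistic. A constant score
field raises a dedicated error rather than emitting NaN, so callers skip
e.g. wild-type sections without amyloid explicitly. Spots whose
neighborhood spans the whole graph would have a zero denominator and return
NaN; this cannot occur on lattices of practical size.

**GLM.** Per gene, a log-link count GLM of UMI on the hotspot score with
sample-of-origin dummies and log(total UMI + 1) as covariates.
Quasi-Poisson is the default variance model (Poisson fit, covariance scaled
by Pearson χ²/df); negative binomial is available. Library size enters as
a covariate, not an offset, deliberately. Collinear design columns are
dropped greedily left-to-right with a warning (the one-sample case), genes
with zero counts on included spots are skipped with a reason code, and the
two-sided Wald p uses the normal reference.

**Caller.** BH-FDR over all tested genes within the analysis unit;
`associated ⇔ FDR < 0.05 ∧ Pearson r > 0`, with r computed between
log1p-CPM expression and the score on the included spots. Human mode pools
non-WM spots into one unit; mouse mode iterates clusters.

**Calibration conditions.** The calibration benchmark uses 2 samples ×
1,024 spots, 20 responsive genes (mean count 5, β = 0.5) and 180 null
genes at baseline mean 500. The high null baseline is deliberate: the
nulls stand in for the bulk of a genome-wide library, keeping the
amyloid-responsive mass at ~0.1% of total UMI as it would be in a real
panel. At equal baselines the responsive genes would be ~10% of the
library, making the total-UMI covariate endogenous: its slope on the
amyloid score absorbs part of the planted effect and attenuates β̂ by
~0.1 — an artifact of panel down-scaling, not of the estimator. Under the
stated conditions the caller achieves empirical FDR ≈ 0.002–0.012 at
nominal 0.05, sensitivity 1.0, and mean β̂ ≈ 0.478 (the remaining ~0.02
attenuation is the residual endogeneity of total UMI). The calibration
regresses on `a_s` itself — the field β is planted on; the end-to-end
pipeline passes Gi\*(area), a spatially smoothed version of it, whose
coefficient is a related but distinct estimand.

**Overlap statistics.** Counts are formed against an explicit background;
Jaccard = a/(a+b+c); the odds ratio is the sample (a·d)/(b·c) with a 0.5
Haldane correction iff any cell is zero; the p-value is the one-sided
(enrichment) Fisher exact test, verified exhaustively against integer
hypergeometric enumeration for every table with background ≤ 60.

## Networks

**Pseudobulk.** Per (sample, region): summed UMI → CPM → log₂(CPM + 1).
The pseudocount is a declared choice (a bare log₂ CPM is undefined at
zero). Rows with zero total UMI are dropped with a warning.

**Soft power.** Signed networks by default, a = ((1 + cor)/2)^β. The
scale-free fit is −sign(slope)·R² of log₁₀ p(k) on log₁₀ k over 10
equal-count connectivity bins, with p(k) taken as a density (bin fraction
divided by bin width — with equal-count bins the raw fraction is constant
by construction and carries no information). Powers that drive mean
connectivity below 1 are ineligible regardless of fit: a vanishing network
produced by raising sampling noise to a high power can fit a log-log line
spuriously well, and the guard is what makes i.i.d. noise fail the scan
while a genuinely scale-free construction passes. The chosen power is the
smallest passing candidate; if none passes the best fit is returned with a
`passed=False` flag.

**TOM and module detection.** The standard topological overlap with unit
diagonal. Detection is average-linkage clustering of 1 − TOM with a static
height cut followed by iterative merging of module pairs whose eigengenes
correlate above 1 − merge height (defaults: min size 50, merge height
0.1). The static cut replaces adaptive tree cutting with a fully specified
rule; its default (0.995) is geared to signed power-6 TOMs of pseudobulk
with region-restricted modules, where cross-module dissimilarity is ≈ 1
(CPM compositionality makes unrelated genes anti-correlated). For
expression built directly from uncorrelated factors, cross-module
dissimilarity is only ≈ 0.95 and the cut must sit between the within- and
between-module heights (the tests use 0.9 there). This sensitivity to the
cut height is the main cost of the simplification and is why the merge
step exists as an independent, testable rule.

**Eigengenes.** ME = first principal component of the module's
column-standardized expression (population sd; constant genes excluded,
all-constant modules yield zeros), scaled to unit variance, sign fixed so
that cor(ME, mean standardized module expression) ≥ 0 — making results
deterministic across linear-algebra backends. kME is the plain Pearson
correlation of each gene with each ME. Projection into a query dataset
recomputes MEs on the module's genes present there (≥2 required; missing
modules are listed, not silently dropped). MEs are computed without any
batch correction; per-sample centering is left to the caller.

**Meta-spots and consensus TOM.** Meta-spots pool b×b blocks of lattice
indices (counts summed, centroid coordinates, majority region label with
lexicographic ties). The consensus TOM power-scales each matrix so its
95th percentile matches the first TOM's, then takes the element-wise
minimum — the conservative classical construction.

## Meta-modules

J is gene-overlap Jaccard over all module pairs (same-region pairs are 0
by partition disjointness, asserted). E is the element-wise maximum over
regions of the per-region Pearson correlation matrices of the ME columns,
computed over all spots of each region (regions with <3 spots or constant
MEs contribute nothing to the max). The dissimilarity is read as the
1:3-weighted mean D = 1 − (E + 3J)/4, which maps (E=1, J=1) to 0 and keeps
D in [0, 1] whenever E ≥ 0; the alternative literal reading 1 − (E + 3J/4)
reaches −0.75 for identical modules, incompatible with a dissimilarity,
and is exposed only behind a flag for sensitivity analysis. Meta-modules
are a k-cut (default 15, the tree is returned so any cut can be taken) of
average-linkage clustering on Euclidean distances between rows of D.
Meta-module eigengenes use the union of member genes with the same sign
rule; genes claimed by several meta-modules go to the one with the highest
kME, exact ties to the lexicographically smallest id. DME tests are
two-sided Wilcoxon rank-sum (exact when group sizes ≤ 30 and untied,
asymptotic otherwise) with BH within each contrast; the effect size is the
difference of group mean MEs — MEs are unitless and signed, so a fold
change would be ill-defined. Region-specific modules are tested only in
their home region; meta-modules in every region.

## Consensus mapping and deconvolution

The 10-NN labeling, composition metric and vote are as the README states.
All ties — modal region among the k neighbors, consensus votes, marker
effect ties — break lexicographically: determinism over fidelity to an
unstated convention, and invariance to input order is asserted by test.
The composition filter retains the closed interval [−0.3, 0.9] (values
strictly outside are excluded). The upper/lower cortical grouping (upper =
L1, L2/3, L3/4; lower = L3-L5, L5/6, L6b) is a configurable default. The
upstream coordinate prediction that produces (cell, sample) mappings is
consumed, not implemented. DEG deconvolution is set attribution against
marker tables, not statistical abundance estimation; the marker effect
column defaults to avg log₂FC and an optional marker-FDR filter is
available.

## Problem sizes and limitations

The benchmark sizes — 12-sample cohorts of 20×20 sections for module
recovery, 2×1,024 spots × 200 genes × 20 replicates for caller
calibration, 700 cells × 10 mappings for consensus accuracy, backgrounds
≤ 60 for the exhaustive Fisher check — were chosen so the full suite runs
in a few minutes on one CPU while keeping each estimate's Monte-Carlo
error far from its decision threshold.

Known limitations: no histology or image synthesis, no doublet/ambient-RNA
model, no batch structure in the generator beyond the library factor (so
the Harmony-style ME correction used in some studies has no synthetic
counterpart here); the static-cut module detector needs a sensible cut
height for data whose TOM scale differs from the pseudobulk default; the
quasi-Poisson Wald test is asymptotic and mildly anti-conservative at very
low counts; and recovery results on planted, well-separated structure are
upper bounds on what unstructured real tissue would yield.
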