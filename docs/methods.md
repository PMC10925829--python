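# Methods

`rootclines` implements a projection-based genotype–environment association
(GEA) workflow for root anatomy: environment→trait models are fitted on a
small phenotyped training panel, trait values are projected onto a large
genotyped, georeferenced panel, projected phenotypes are clustered and
converted into composite root anatomies with hydraulic properties, and
gene-level association is run on the projections and on the underlying
environmental descriptors. Every stage is exercised end to end on synthetic
studies whose signals are planted and recorded, so correctness is assessed
as parameter recovery rather than as agreement with any published dataset.

## The synthetic study

The generator emulates the *structure* of a landrace GEA study, not the
distributions of any real panel.

**Landscape.** Accessions receive coordinates uniform on a rectangle and an
elevation from a fixed smooth surface (a sum of two sinusoidal ridges, which
yields three roughly equal elevation terciles). `n_informative` of the
`n_descriptors` environmental descriptors are monotone transforms of the
elevation z-score plus Gaussian noise (noise SD 0.55, giving |r| ≈ 0.8 with
elevation and pairwise correlations of roughly 0.5–0.8 among informative
descriptors); the rest are independent noise. Three conventionally named
descriptors (annual precipitation, mean temperature, soil pH) are always
present for the PC–environment screen; the first two track elevation.

**Genotypes.** A Balding–Nichols model with three demes assigned by
elevation tercile: per SNP, an ancestral frequency p ~ U(0.1, 0.9) and deme
frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) with differentiation `fst`.
Dosages are Binomial(2, p_deme). One SNP per causal gene is planted inside
the gene body and receives an additional logistic frequency shift of
magnitude `adaptive_shift` along the cline variable; all SNPs are
regenerated or dropped until minor allele frequency exceeds 1%. By default
the cline variable is elevation. Setting `cline_on` to a trait code instead
makes the shift follow that trait's environmental component — i.e. selection
acting on the trait optimum, which is the premise of projection GWA; in that
mode traits carry no direct SNP effects (they must be generable before the
genotypes).

**Traits.** Seven primary anatomical traits (root cross-section area RXSA,
stele:root ratio TSA:RXSA, cortical file number CCFN, cortical cell size
CCS, aerenchyma area AA, metaxylem vessel count NMV and diameter MD) are
each generated as

    trait = sqrt(r2_env)·f_std + sqrt(h2_snp)·g_std + sqrt(1 − r2_env − h2_snp)·ε

where f is a recorded nonlinear function of the informative descriptors
(linear terms with |coefficients| in 0.6–1.4, one pairwise interaction, one
saturating tanh term), g is the standardized sum of causal-SNP effects, and
ε is Gaussian. The latent value is mapped onto a plausible scale per trait
(means/SDs/ranges in `TRAIT_SCALES`; counts rounded, percentages clipped).
Derived traits (TSA, TCA, X.A, MA, MVA) follow from the primaries using the
same geometric conventions as the cross-section builder, with the vessel
count capped so the implied anatomy is always buildable. The scales are
emulated magnitudes; nothing is calibrated to a measured panel, and
acceptance is parameter recovery, not distribution matching.

**Greenhouse replicates.** Per-plant records value = μ + accession + node +
tray + residual with variances (1.0, 0.3, 0.2, 0.5) by default. Plants are
placed on trays in randomized order; assigning trays in planting order would
confound tray with accession and make the variance components unrecoverable.

**Randomness.** All streams derive from one seed through fixed named
sub-streams (landscape 1, annotation 2, genotypes 3, traits 4, greenhouse
5), so any component regenerates byte-identically regardless of call order.

What the generator does **not** emulate: linkage disequilibrium decay within
demes (SNPs are exchangeable given deme), spatial autocorrelation of
descriptor noise, trait–trait developmental constraints beyond the geometric
caps, missing phenotypes, and genotyping error. Passing tests therefore
demonstrate that the algorithms recover signals of the planted form at desk
scale — not that real-panel effect sizes would be recovered.

## Quantitative genetics

BLUPs and variance components come from EM-REML on Henderson's mixed-model
equations (single fixed intercept, independent random factors). EM steps
never decrease the REML likelihood; convergence is a relative change below
1e-8 or 500 iterations. This is slower near the boundary than
average-information REML but is monotone, simple and adequate at greenhouse
scale (worst-case fits here are ~1,000 observations × ~120 levels). Measured
recovery on the default greenhouse design (50 accessions × 10 replicates ×
2 nodes, 20 seeds): 14% median relative error across all components; the
two-level node factor is individually poorly estimable (~80% error), which
is a property of the design, not the estimator. Broad-sense heritability is
σ²_accession/(σ²_accession + σ²_residual).

Trait PCA is an SVD of the centered/scaled matrix with a deterministic sign
convention (largest-magnitude loading positive). The PC–environment screen
reports Pearson r with Holm-adjusted p over the whole test family; a
convenience wrapper splits PC scores into terciles (ties to the lower bin)
and runs a one-way ANOVA of elevation across the groups.

## Feature selection and trait models

Selection is the shadow-feature (Boruta-style) scheme with three deliberate
implementation choices, each driven by the planted-truth studies:

* **Cross-fit permutation importance.** Each iteration splits the panel in
  half, fits a forest on each half (250 trees, `sqrt` split candidates) and
  permute-scores on the other, averaging three permutation repeats.
  Importance measured on in-bag rows rewards persistent chance
  correlations — real noise columns keep their sample pattern across
  iterations while shadows are re-permuted — which inflated false
  discoveries to ~0.4 before the change.
* **Full shadow pool.** Shadows are fresh permutations of *every*
  descriptor each iteration, even after rejections, so a hit always means
  "beat the maximum of p chance patterns". Rejected descriptors do leave
  the model matrix.
* **Decisions.** Hits accumulate per descriptor; a two-sided binomial test
  against 0.5, Bonferroni-adjusted over the initial descriptor count,
  confirms or rejects. If the undecided set is unchanged for 20 iterations
  the loop stops early (the stragglers are headed for the rough fix
  anyway). Tentative descriptors are then resolved by a one-sided Wilcoxon
  signed-rank of the per-iteration (importance − max shadow) differences at
  the same α: the paired-comparison form of "is the median importance above
  the median shadow maximum", which rejects chance features whose
  differences straddle zero. With a plain median-vs-median rule the
  single strongest chance correlate of a pure-noise trait was promoted in
  ~40% of runs.

Measured at the documented study scale (200 accessions, 5 informative of 50
descriptors, trait_env_r2 = 0.6, 10 seeds): recall 0.84, false discovery
0.02; pure-noise traits return an empty confirmed set in 8/10 seeds. An
empty confirmed set marks the trait "not modeled" — a valid outcome, not an
error.

Trait models are random-forest regressions on the confirmed descriptors
(default 5,000 trees; split candidates = floor(p/3), minimum 1). Model
quality is out-of-bag percent variance explained, 1 − MSE_OOB/var(y), which
may be negative and is slightly negatively biased under the null, plus the
Pearson correlation of observed vs OOB-predicted values. Projection is a
pure function of the stored models; target accessions outside any
descriptor's training range are flagged in an extrapolation report, never
dropped.

Shapley attributions offer two estimators: `exact_tree` enumerates all
feature coalitions with a marginal (interventional) expectation over a
background sample (capped at 64 rows; feasible for the ≤ 14 descriptors
these models use), and `sampling` is the Monte-Carlo permutation estimator
whose base value is the mean prediction over the sampled background rows, so
additivity (base + row sum = prediction) holds exactly for both.

## Root hydraulics

The cross-section builder reconstructs a concentric-layer anatomy: outer
radius from RXSA, stele radius from TSA = TSA:RXSA × RXSA, fixed epidermis
and endodermis thickness (0.02 mm each, configurable), the remaining annulus
divided into CCFN equal cortical rings (cells per ring from the ring
circumference and the cell diameter implied by CCS), a thin pericycle, and a
stele-ground layer down to the vessel circle. Aerenchyma is assigned as a
circumferential fraction per ring from the mid-cortex outward until the
lacunae area reaches AA (capped at 0.95 per ring); the placement convention
is a modeling choice. NMV vessels of diameter MD sit uniformly on a circle
at 0.6 × stele radius; overlapping or non-fitting vessels are geometry
errors.

Hydraulics use an axisymmetric shell simplification of explicit cell-network
models. Axial conductance is the Hagen–Poiseuille sum over metaxylem vessels
(protoxylem ignored), Kx = Σ π d⁴/(128 μ) with μ = 1e-9 MPa·s (water,
20 °C). Radially, each layer contributes a parallel pair — a cell-to-cell
path with two membranes in series (2π r L Lp / 2) and an apoplastic wall
path (2π r L k_wall / t) — and the layers compose in series; the Casparian
scenario zeroes the apoplastic path at the endodermis, and aerenchyma scales
both paths of its ring by (1 − fraction). kr = Kr/(2π r_outer L) with
segment length L = 0.01 m. Defaults Lp = 5.3e-7 m s⁻¹ MPa⁻¹ and k_wall =
2.4e-11 m² s⁻¹ MPa⁻¹ are literature-plausible magnitudes for young maize
roots; they set the scale, not the orderings, of reported conductances. An
independent Kirchhoff node-network solve of the same shells (explicit
boundary and mid-membrane nodes, assembled conductance matrix, Dirichlet
boundary) agrees with the series/parallel composition to better than 1e-8
relative and serves as the test oracle. Everything derived from this model
is a "simplified model" result: it preserves the membrane/apoplast
structure, the Casparian barrier and aerenchyma obstruction, but not
cell-scale heterogeneity.

Cluster composites take the per-cluster median of each projected trait;
traits the models do not predict (RXSA in particular) are filled with the
training-panel mean, and derived traits are recomputed from geometry because
medians of products are not products of medians.

## Clustering and concordance

Projected traits are z-scored per trait on the pre-removal distribution;
accessions with any |z| > 3 are removed in a single pass (row removal keeps
the distance matrix complete). PAM runs on Euclidean distances: exact
enumeration of medoid sets for tiny instances (C(n,k) ≤ 20,000), since
BUILD+SWAP stalls in local optima on ~13% of 8-point instances, and
deterministic BUILD+SWAP (best strictly-improving exchange, lowest-id ties)
at real scale. Labels are renumbered by descending cluster size. The WSS
curve uses sums of squares to cluster means, so WSS(1) = TSS and WSS(n) = 0.
Default k = 7.

Variety enrichment is a two-sided Fisher exact test per (cluster, variety)
2×2 table over the variety-assigned accessions, Holm-adjusted over the whole
family. Procrustes concordance column-centers both matrices, scales each to
unit total sum of squares, takes the rotation from the SVD of the
cross-product, and reports m² (residual sum of squares) with an optional
row-permutation test (p = (1 + #{m²_perm ≤ m²})/(n_perm + 1)).

## Association

The genetic relationship matrix is ZZᵀ/m on centered, scaled dosages
(monomorphic SNPs excluded); its leading five eigenvectors are fixed-effect
covariates in every model — one consistent structure correction rather than
a per-panel mix of machinery. SNP tests are least squares with Wald t tests
(t distribution, not normal, so the gene-level F identity is exact); with a
−1/+1 treatment vector the model gains treatment, dosage and
dosage×treatment terms and reports main (G) and interaction (G×E) tests.

Gene-level association follows the multiple-regression aggregation idea:
the gene's SNP block and the response are residualized on the covariates,
the block is reduced to principal components reaching 99.9% of its variance
(capped at n − c − 2; LD pruning), and the joint PC regression is F-tested
against the covariate-only model. A single-SNP gene reduces exactly to the
squared-t Wald test. Measured type-I error at α = 0.05 on a structured
panel with environment-driven (non-genetic) responses and eigenvector
correction: 0.047 over ~2,300 gene tests.

Candidate pooling restricts all analyses to their shared gene universe,
takes the k = 100 smallest-p genes per (analysis, trait) with ties broken
by gene id, pools per analysis, and reports pairwise overlap counts and row
percentages. Cluster MAF profiles track the frozen panel-wide minor allele:
per cluster, the mean elevation, mean projected traits and candidate-SNP
minor-allele frequencies, with Pearson correlations of MAF against
elevation and traits across clusters. Complementing dosages relabels
REF/ALT but re-identifies the same physical minor allele, so profiles are
invariant to allele-label swaps.

### Why projection GWA can beat single-descriptor GEA

The package's value-added check plants selection on the trait: clinal SNP
frequencies follow the trait's environmental component f (a nonlinear
combination of four descriptors), not raw elevation. Each descriptor is a
noisy monotone elevation proxy, so no single descriptor tracks f as well as
the fitted projection does, and the planted genes rank better (median rank
over three clinal genes) under projected-trait association than under the
best single-descriptor analysis in ~2/3 of seeds (8/12 wins vs 3 losses in
the shipped configuration, stable across disjoint seed blocks). When the
cline instead follows raw elevation, single descriptors are the better
proxy and projection GWA loses — the advantage of projection GWA is
conditional on selection acting on the modeled trait combination, which is
exactly its motivating premise.

## Pipeline and reproducibility

`run_full` executes features → models → projection → clustering →
hydraulics → gwas → pooling → maf, writing every output as headered CSV with
a fixed float format and a manifest (config hash, seed, stage list, output
hashes). Re-running an identical config is byte-identical; the shipped
study scale (60 training, 400 target accessions, 2,000 SNPs, 200 genes)
completes in a few minutes on one core with the fixture-scale tree counts
(selection 250, models 600). Test-suite studies use 200–500 trees; the
5,000-tree default is the full-analysis setting. Stage failures halt with a
machine-readable error and the manifest records the failed stage; exit
codes are 2 (configuration), 3 (data), 4 (numeric).

## Known limitations

* The shell hydraulic model is axisymmetric; azimuthal heterogeneity
  (patchy aerenchyma, xylem poles) is outside its geometry.
* EM-REML handles the crossed greenhouse design but would be slow for
  thousands of levels; no sparse-matrix path is implemented.
* The gene test's PC-regression form assumes a dense dosage block per gene;
  SNP-wise p-value combination is not implemented.
* Boruta decisions are calibrated for tens-to-hundreds of descriptors;
  with thousands, the Bonferroni adjustment will be conservative.
* The generator's demes are discrete; continuous isolation-by-distance
  structure is not emulated, so eigenvector correction is easier here than
  on real panels.
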