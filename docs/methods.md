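# Methods

This note records the statistical models phenogs implements, the choices
made where the design was genuinely open, and what the synthetic data can
and cannot tell you about real trials.

## Field-trial model and REML

The augmented block design replicates a small set of check cultivars in
every block while each test entry appears once per environment. The
per-environment model is Y = μ + block + C + I + G + ε, where C separates
checks from entries and I identifies individual checks; entries enter G.
For single-environment BLUEs every term is fixed and the fit is ordinary
least squares: the design uses genotype-identity one-hots plus
sum-to-zero block contrasts, so an entry's BLUE is its value at the
average block. Sum-to-zero (rather than anchoring to a reference check)
is a reporting convention; all entry contrasts are identical under either.

For the combined analysis and for variance components, genotype and
genotype-by-environment effects are random and environment,
block-within-environment, and the check structure (check identity crossed
with environment) are fixed nuisance. The entry-mean heritability
formula uses only (σ²_G, σ²_GEI, σ²_ε), which is why the nuisance terms
can be fixed without affecting the quantity of interest; for balanced
data the REML estimates of these three components coincide with the
classical ANOVA expected-mean-squares estimators (verified to 1e-6 in the
tests). Fixing the nuisance also makes the marginal covariance
block-diagonal by entry — checks contribute a pure σ²_ε diagonal — so a
REML likelihood evaluation costs O(p²) after precomputing per-group
sufficient statistics (entries observed once per environment have
compound-symmetric blocks aJ + dI with closed-form inverses).

The optimizer is L-BFGS-B on log-variance scale from a method-of-moments
start plus two fixed fallback starts, followed by a Nelder–Mead polish
(the REML surface is flat near its optimum and quasi-Newton alone stops
one or two digits short of full parameter precision). Estimates are
exactly invariant to record order because records are canonically sorted
before any design matrix is built. Variances driven below 1e-8 of the
response variance report exactly 0. With a single environment σ²_GEI is
not estimable and is reported NaN with a flag. In an augmented design
σ²_GEI and σ²_ε are confounded within entries (one plot per
environment); their separation rests entirely on the checks' replication,
which is the standard property of the design, not an artifact.

## Indirect-selection statistics

Genetic covariance between two traits scored on the same plots uses the
pairwise-sums identity Cov_g(x,y) = [σ²_G(x+y) − σ²_G(x) − σ²_G(y)]/2,
reusing the univariate REML engine; this is exact for balanced data and
avoids a bivariate REML implementation. The genetic correlation divides
by √(σ²_gx σ²_gy) — Falconer's definition; a variance product without the
square root would not be bounded by 1. Estimates outside [−1, 1]
(possible in small samples) are clipped and flagged.

In the report, the correlated response CR = √H²_x · r_G · σ_gy uses the
same σ_gy as the direct response R_y = √H²_y · σ_gy, so the identity
RE = r_G √(H²_x/H²_y) holds to machine precision on every row, not only
when two separately estimated yield variances happen to agree. Selection
intensity cancels in RE and is omitted throughout. Phenotypic
correlations are Pearson correlations of per-environment entry BLUEs
pooled across environments (per-environment reporting is available).

## RRBLUP

The shrinkage parameter δ = σ²_ε/σ²_u is profiled by REML on the
eigenvalues of S(MM′)S (S the fixed-effect projection), with a coarse log
grid followed by bounded scalar refinement; fixed effects are then
estimated by GLS and marker effects recovered through the dual ridge
identity u = M′(MM′ + δI)⁻¹(y − Xβ̂). Dosages are centered by training-set
column means, stored with the model along with the per-panel minor-allele
orientation flags so that a test panel read from the same source coding is
aligned marker-by-marker before prediction. δ is estimated once per
training set and reused across CV folds (standard rrBLUP practice; a
per-fold option exists). Models with SRI covariates require test-line
covariate values by default — the indices are measured on test plots in
the intended workflow — with an explicit `train-mean` fallback documented
as an extrapolation.

Marker QC retains MAF strictly above the threshold (default 0.05).
LD-kNN imputation selects, per target marker, the l = 30 most r²-correlated
markers (complete pairs), ranks donor lines by matching distance on those
markers, and takes the inverse-distance-weighted mean of the k = 10
nearest donors' calls; ties break by line order, so the procedure is
deterministic.

## Synthetic data

The generator emulates: a diversity training panel (default 456 doubled-
haploid-style inbred lines, 11,089 independent biallelic markers with
founder MAF uniform on (0.05, 0.5)); grain yield (mean 5 t/ha, genotypic
SD 0.4 t/ha, entry-mean H² 0.19 over 4 environments); five spectral
indices at three growth stages with means, heritabilities (0.16–0.63) and
genetic correlations with yield (−0.58 to +0.67) patterned on the ranges
a winter-wheat diversity panel shows, the water index negative; and the
augmented layout (24 blocks per environment, two checks in every block,
entries un-replicated). Non-genetic variance is sized from the target H²
via the heritability formula and split 40/60 between G×E and residual by
default. Index genotypic SDs are set to ~6% of the trait mean (floored at
0.02) — a coherent scale chosen by the package; every statistic the tests
and acceptance script assert (H², r_G, RE, stage changes, accuracies) is
invariant to this scale.

Trait architecture is infinitesimal: yield effects i.i.d. normal over all
markers; an index's effects are r_G·u_yield + √(1−r_G²)·u_independent.
Test panels diverge from the trainer through a single relatedness knob
ρ ∈ [0, 1]: founder frequencies blend toward an independent pool with
weight 1−ρ, and marker effects are correlated at ρ across panels, so
allele-frequency distance and cross-panel predictive signal shrink
together. The presets use ρ = 0.7 for the DH-like panel (n 449, yield
H² 0.55, single environment) and ρ = 0.4 for the F5-like panel (n 501,
H² 0.14). Reflectance is synthesized by inverting the index formulas
band-by-band from an anchor R800 = 0.5 (indices clipped into their
invertible ranges first), plus Gaussian band noise with SD 0.01 — an
invented noise model, configurable.

All randomness flows from one seed through named `SeedSequence` children;
the field layout stream is a property of the panel, not the trait, so all
traits share plots as in a real multi-trait trial.

What the generator does **not** emulate: linkage disequilibrium (markers
are independent by default; an optional block-haplotype mode exists to
exercise LD-kNN imputation), selection history, pedigree structure,
spatial field trend beyond block effects, or radiometric physics. Two
consequences matter for interpretation. First, with ~11k independent
markers and ~450 lines the marker-only prediction accuracy is
intrinsically small (≈ 0.1); in real wheat, LD concentrates the signal
into far fewer effective segments and marker-only CV accuracies of
0.3–0.4 are typical. The covariate-driven gains, the heritability
ordering of panels, and all recovery statistics are unaffected, and these
are what the tests assert. Second, Rogers distances between the synthetic
panels (≈ 0.10 DH-like, ≈ 0.18 F5-like) are smaller than typical
between-programme distances, but their ordering — the DH-like panel
closer to the trainer — is the property the validation exercises.

## Problem sizes and numerical conventions

The test suite runs reduced but structurally identical scenarios
(150–500 lines, 500–2,000 markers) so the whole suite stays in a few
minutes; the acceptance script runs the prediction scenarios at full
panel scale (456/449/501 lines; 11,089 markers) averaged over 2–4 seeds
and the recovery scenarios at 456 lines × 2,000 markers over 4 seeds.
Parameter-recovery checks use 20 seeds at 500 entries × 4 environments
with tolerances ±0.05 (H²) and ±0.1 (r_G).

Other conventions: RMSE of the least-squares index→yield models divides
by n (predictive convention; switchable to n−p); BIC is the Gaussian
n·ln(SSE/n) + p·ln(n), so only differences are meaningful; top-fraction
selection includes all entries tied at the threshold and reports the
realized set size; percent stage change is signed,
100·(m_to − m_from)/|m_from|, so "decrease" reads negative even for
negative-valued indices. Genotype containers enforce dosage orientation
toward the within-panel minor allele (mean dosage/2 ≤ 0.5) and record
which markers were flipped relative to the source coding. VCF positions
are 1-based per the standard; internal indexing is 0-based. Heterozygous
calls are representable throughout even though DH material is homozygous —
a data property, not a type constraint.

## Known limitations

Bivariate REML (rather than the pairwise-sums trick) would propagate
uncertainty into r_G; none of the reported statistics carries a standard
error. The LD-kNN imputer is O(markers × missing columns) and meant for
the moderate missingness of post-QC panels, not raw GBS output. The
check model assumes check identity × environment cells are estimable
(each check present in every environment it is modelled in); trials with
environment-specific checks are handled by the rank-reduction step but
the affected cells then calibrate fewer contrasts.
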