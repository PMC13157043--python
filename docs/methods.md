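# Methods

This note records the models, defaults and design decisions behind
`admixpgs`, in the order data flows through the pipeline.

## Synthetic cohorts

The generator produces the three cohorts the analysis assumes — a large
homogeneous discovery cohort (source of GWAS summary statistics), a
homogeneous training cohort (weight estimation), and an admixed target
cohort — plus, in the experiment drivers, an ancestry-matched held-out
cohort used as the comparison arm for the ancestry-gain contrast.

**Allele frequencies.** Balding–Nichols drift: per variant a base frequency
`p_j ~ Uniform(0.05, 0.95)` and, for ancestral population k with fixation
index F_k,

    p_kj ~ Beta(p_j (1−F_k)/F_k, (1−p_j)(1−F_k)/F_k),

so E[p_kj] = p_j and Var[p_kj] = F_k p_j (1−p_j); draws are clipped to
[0.001, 0.999]. Defaults F = (0.10, 0.12, 0.16) sit inside the range of
continental human differentiation and are configurable. Components are
ordered (European, Amerindian, African) everywhere.

**Admixture.** Individual admixture rows are Dirichlet draws. The
European-like preset uses concentration (100, 0.1, 0.1). The admixed preset
draws each individual's concentration from three sub-group presets —
mainland-like (2, 6, 1), Cuban-like (8, 1, 1), Caribbean-like (5, 1, 4) —
mixed 40/30/30, which yields a cohort dominated by European- and
Amerindian-predominant individuals with a smaller African-predominant group
(roughly 50/39/11 % in the default smoke run), qualitatively matching a US
Latino cohort.

**Genotypes.** `g_ij ~ Binomial(2, Σ_k q_ik p_kj)`, independent across SNPs:
no linkage disequilibrium by default. The penalized solver must still cope
with correlated predictors, so an optional duplicate-with-noise mode appends
copies of existing SNPs with per-allele flip probability ρ, creating
correlated pairs without haplotype machinery. Sibling pairs replace the last
2·(number of pairs) cohort members: two unobserved parents are drawn with
the pair's shared admixture row and each child receives one allele per
parent per SNP (Bernoulli(g_parent/2)); the kinship table records each pair
at 0.25 and parents are discarded.

**Trait.** The causal set is the *first* m_causal variants (deterministic,
so tests can reference it). Raw effects are N(0, 1), rescaled so the
realized genetic-score variance equals h² in the anchoring cohort; the
realized effect vector is then reused verbatim in every other cohort of a
study so weights are transferable by construction. The trait is

    y = Σ_j β_j g_ij + Σ_k δ_k q_ik + 0.3·z(age) + 1.0·sex + ε,
    ε ~ N(0, 1−h²),  age ~ U(18, 74),  sex ~ Bernoulli(1/2).

δ is in trait-SD units per unit ancestry proportion; the default contrast
(+0.5, 0, −0.5) makes the trait ancestry-dependent, which is the regime the
two-stage model targets. No estimate of a real trait's δ is implied — it is
a knob. Age and sex effects default to 0.3 and 1.0 SD so residualization is
non-trivial; the age effect applies to standardized age so its variance
contribution is scale-free. h² = 0 is allowed and zeroes the causal effects
(the null pipeline).

**Discovery GWAS.** Per variant, simple OLS of the (age/sex/PC-residualized,
standardized) phenotype on the allele count; beta, SE and the two-sided t
p-value are exported as summary statistics. Monomorphic variants are flagged
(beta 0, p 1) and excluded from export, since the summary-stats schema
requires a positive SE. In an unstructured cohort null p-values are uniform;
in a structured cohort without PC adjustment, ancestry-differentiated null
SNPs are enriched for small p — both calibrations are asserted in tests.

**What the generator does not emulate:** realistic LD and recombination,
rare-variant architecture, genotyping error and batch structure, selection,
X-chromosome dosage, environment correlated with ancestry beyond the linear
δ term. Passing tests therefore demonstrate the *machinery* (selection,
solver, splits, the ancestry-gain contrast under ancestry-dependent traits),
not real-data effect sizes; the headline real-cohort accuracy values from
population biobanks are out of reach of desk-scale simulation by design.

## Phenotype preparation

Residualize on covariates by OLS (intercept always included; rank checked
via the QR diagonal, collinear columns named), standardize, exclude |z| ≥ 4
in a single pass (boundary excluded), re-standardize survivors. The
exclusion is deliberately not iterated. SDs use the n−1 denominator.
Exclusion counts are reported. Two configurations are first-class:
*training* (residualize on age, sex and optionally the leading genotype
PCs) and *evaluation* (age and sex only) — the evaluation phenotype must
not be pre-residualized on PCs, or stage two's PC terms would have nothing
left to explain.

## SNP selection

QC filters run in a fixed order — missingness (> 10 %), minor-allele
frequency (< 0.001, computed on called genotypes), exact Hardy–Weinberg
(p < 1e-10) — and the first failure is the variant's recorded drop reason,
so reasons partition the dropped set. The "call rate" criterion is
implemented as a missingness ceiling of 10 %, the standard reading. The HWE
test is the exact conditional test: given the allele counts, the p-value
sums the probabilities of all heterozygote counts no more probable than the
observed one; the implementation uses log-gamma arithmetic with a relative
tie tolerance of 1e-10 and matches exact-rational enumeration to < 1e-12
for every configuration with n ≤ 50.

Harmonization intersects on variant ID (allele pairs verified, not
chr:pos), resolves effect/other swaps (effect sign flips) and strand
complements, and drops self-complementary (A/T, C/G) pairs unconditionally
before any strand logic — no frequency-based rescue. When the target
cohort's allele orientation is itself swapped relative to the training
cohort, the panel records a `target_flip` and target counts are reflected
(2−g) at scoring time. Threshold selection is strict (p < τ), so selected
sets are nested across the grid (1e-16, 1e-12, 1e-8, 1e-4, 1e-3, 1e-2,
1e-1).

## Penalized solver

Genotypes are mean-imputed (missing → training mean) and column-standardized
with n−1 SDs; zero-SD columns are dropped and reported. The λ grid is
glmnet-style: λ_max = max_j |x_jᵀy| / (n·max(α, 0.001)) — the guard keeps
ridge finite — with 10 log-equispaced values down to 0.01·λ_max, recomputed
per p-value threshold since the design changes. Cyclic (not randomized)
coordinate descent with soft-thresholding updates and warm starts runs from
large to small λ; convergence is declared when the largest coefficient
change in a cycle falls below 1e-7. Ridge uses the closed form
(XᵀX + nλI)⁻¹Xᵀy when M ≤ 2,000. The intercept is handled implicitly by
centering; only α ∈ {0, 1} are supported. Verified properties: KKT
conditions at convergence, non-increasing objective within a λ, Lasso
sparsity monotone along the path, agreement with closed forms and with a
slow proximal-gradient reference.

Scoring applies training-cohort standardization statistics to any cohort
(missing calls impute to the training mean, i.e. standardized zero);
per-allele weights β_j/sd_j are exported for conventional raw-count scoring.
The best λ is the one maximizing squared Pearson correlation with the
phenotype, ties broken toward the larger λ (sparser model). By default λ is
selected inside each evaluation iteration's 80 % training fraction to keep
the test fraction untouched; a `full_cohort_lambda` flag instead selects once on
the full cohort, reproducing protocols that select on the entire validation
set.

## Ancestry

PCA standardizes and mean-imputes the genotype matrix, then takes the exact
eigendecomposition of the smaller Gram matrix (N×N or M×M); sample
coordinates are left singular vectors scaled by singular values. The sign
convention — the largest-magnitude variant loading on each PC is positive —
makes runs platform-reproducible. Requests beyond the rank truncate with a
warning. PCs are computed within each cohort separately; no cross-cohort
projection is needed.

Admixture proportions are estimated per sample by maximizing the binomial
log-likelihood with the ancestral frequencies held fixed (supervised: in
simulation they are ground truth; for real data they must be supplied —
unsupervised joint estimation is a solved problem elsewhere and out of
scope). The maximizer is expectation-maximization with multiplicative
updates from the uniform 1/K start: monotone in the likelihood,
simplex-preserving, deterministic. Convergence is a change below 1e-8
relative to |log-likelihood| (an absolute 1e-8 is below float resolution at
N·M ≈ 10⁶ scale), capped at 10,000 iterations. Accuracy is information-
limited, not solver-limited: at M = 2,000 and the default F values the
per-component mean absolute error is ≈ 0.008 for one-hot truth and ≈ 0.03
for uniform admixture, with worst-case per-sample errors several times
larger — bounds the tests assert were themselves calibrated by Monte Carlo.
Predominant-ancestry labels are the argmax component, ties to the lowest
index.

## Two-stage evaluation

Related clusters are connected components of the kinship graph with edges
strictly above 0.0442; every member of any cluster is forced into the test
fraction (if the forced set exceeds the 20 % budget the run errors rather
than silently shifting the ratio). Remaining test slots are filled by seeded
sampling; iteration i uses seed base+i, so every split is auditable.
Stage two is OLS of the prepared phenotype on intercept + PGS + the first k
PCs (+ optional extra covariates, e.g. a recruitment-center indicator);
accuracy is the squared Pearson correlation on the held-out 20 % — not
1 − SSE/SST, which differs out of sample. Per-iteration values are stored,
so reported means and SDs are exactly recomputable and error bars come for
free. Iterations that fail (e.g. an infeasible split) are skipped and
counted; more than 1 % skips fails the run. The PC grid default
(0, 1, 2, 3, 4, 5, 10, 20, 40) covers the landmarks of interest; stratified
evaluation repeats the whole protocol within each predominant-ancestry
group, skipping groups below 50 members.

## Pipeline

A single YAML config (unknown keys are errors) drives
simulate → select → train → score → evaluate → report; one global seed fans
out to stage seeds by fixed offsets so stages can be re-run individually
from the CLI. Every artifact is a text format (PLINK1 bed/bim/fam for
genotypes, TSVs elsewhere, JSON results); floats print at 17 significant
digits and readers parse in round-trip mode, so re-running an identical
config reproduces every numeric output byte-for-byte. The manifest records
the config echo, package version, stage timings and SHA-256 checksums of
all artifacts.

## Problem sizes

Default problem sizes were chosen so each layer is exercised at the smallest
scale where its statistical claims are decidable: the smoke pipeline uses
M = 500 SNPs and cohorts of 5,000/2,000/1,000; the weight-recovery
experiment uses a 20,000-sample discovery GWAS, 8,000-sample training
cohort and 3,000-sample evaluation cohorts at M = 2,000 with 200 causal
SNPs and h² = 0.5; the ancestry-gain contrast runs 20 replicate studies
(discovery 8,000, training 2,000, evaluation cohorts 1,500, 50 sib pairs)
with 100 split iterations each. The 1,000-iteration default for split
averaging is retained in the library; experiments use 100 because the
Monte-Carlo error of a mean ΔR² over 100 iterations is already an order of
magnitude below the contrast being measured.

## Known limitations

Unlinked SNPs make the Lasso's LD-handling advantage invisible (the
duplicate-with-noise mode only probes solver correctness under
correlation); supervised ancestry estimation sidesteps the identifiability
questions of unsupervised methods; squared-correlation accuracy hides
calibration errors (a miscalibrated but monotone predictor scores
perfectly); and the two-stage gain ΔR² conflates genetic ancestry with
anything correlated with it, which is intrinsic to the method, not the
implementation.
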