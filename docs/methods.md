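# Methods

This note records the models, conventions and design choices behind
`ckdmrm`, in the spirit of a model-documentation page: what is assumed,
what is tunable, and what the synthetic experiments do and do not show.

## Quantification model

Each protein is represented by one proteotypic peptide measured as a
Q1/Q3 transition in light (endogenous) and heavy (SIS) form.  The
light/heavy area ratio cancels injection-to-injection response variation;
replicate injections are averaged **at the ratio level** (not the area
level) for the same reason.  The replicate CV is reported with the
population SD — it describes the injections actually made, not an estimate
for hypothetical further ones.

Calibration regresses measured ratio on known concentration ratio and
inverts.  The weighting is fixed at 1/x², the bioanalytical standard that
equalizes *relative* error across a standard curve spanning decades of
concentration; the fit is the closed-form weighted normal equations, and
the reported R² is the weighted coefficient of determination.  Back-
calculated negative concentrations are clamped to missing (with a warning)
rather than reported: they indicate a signal below the calibrated range.
When no standards are supplied, quantification falls back to plain SIS
normalization (ratio × spike amount), which is the same up to an affine
map and therefore equivalent for all rank-based downstream statistics.

Missingness convention, used everywhere: below-LOD signals and zero heavy
areas yield *missing*, never zero.  A zero light area with a valid heavy
area is a true zero.  Total-protein normalization is assumed already
applied at the sample-preparation stage (equal protein load per digest), so
the module adds no per-sample scaling.

## Prevalence panels and imputation

Presence means "quantified" (zero counts as present).  The descriptive
panel uses a ≥ 2/3-of-some-group threshold, core proteins meet it in every
group, and the Venn partition assigns each panel protein to the exact set
of groups where it meets the threshold — cells are disjoint and cover the
panel by construction.  Threshold comparisons are `>=` with a 1e-12 float
guard so that exactly 2-of-3 passes a 2/3 threshold.

The prevalence table prints "% present (log2 median)" per group, with the
median suppressed as "Nan" below 50 % presence: under left-censoring a
low-prevalence median describes the censoring threshold, not the protein.

Imputation fills missing cells per (group × protein) with draws from
`N(m − shift·B, (width·B)²)`, defaults shift = 0.4 and width = 0.2, with
`B = m`, the group's observed mean.  This is the literal reading of the
"fraction of the group mean" parameterization; the Perseus convention
scales by the observed SD instead and is available as `basis="group_sd"`.
With the defaults the downshift is two widths, so imputed draws land below
the group mean with probability Φ(2) ≈ 97.7 % — the property tests assert
this exact figure.  Groups with no observed value for a protein fall back
to the protein's global statistics.  Observed cells are never modified.

Two processing paths are kept deliberately distinct:

* differential path: ln(x+1) → ≥ 2/3 core filter → tests on observed
  values only (no imputation — rank tests on imputed data would partly
  test the imputation model);
* classification path: ln(x+1) → ≥ 70 % filter → impute → standardize.

## Differential statistics

Mann–Whitney U is two-sided throughout; `auto` uses the exact null
distribution when both samples are tie-free and the smaller has ≤ 8 values
(the cohort's smallest group), otherwise the tie- and continuity-corrected
normal approximation.  BH and Holm adjustments are applied across proteins
*within* each of the eight contrasts, matching how per-contrast
significance is usually reported; correcting across the full
protein × contrast family is a stricter alternative the caller can apply by
pooling p-values.  Cohen's d uses the pooled (n−1) SD.  Hierarchical
clustering uses 1 − Pearson r with average linkage (UPGMA); only the
distance, not the linkage, is canonical, so the linkage is an argument.
The PCA(7) → t-SNE embedding (perplexity 10, auto learning rate) is for
visual QC only; nothing beyond determinism under a fixed seed and coarse
group separation is asserted about it.

## FSGS severity index

eGFR points: ≥ 60 → 0 (renal function "saved"), [45, 60) → 1, [35, 45) → 2,
< 35 → 3.  Proteinuria points: < 2 g/24 h → 0, then half-point steps per
gram band up to ≥ 7 → 3.  Steroid resistance adds 1.  Total ≥ 3 → severe
(sFSGS), else mild (mFSGS).  The published bin edges overlap at their
boundaries; every bin here is half-open and closed on the left, and the
printed "> 2 → 0" proteinuria row is read as "< 2 → 0" (otherwise the
zero-point row would swallow all heavier bands).  All boundary choices live
in two table constants (`EGFR_BINS`, `PROTEINURIA_BINS`); half points are
exact `Fraction`s, never rounded floats.  Unknown steroid status makes a
record explicitly unscorable — the index never guesses.

## Feature selection and classification

Mild = MCD ∪ mFSGS, severe = sFSGS ∪ MN (configurable); controls are
excluded.  "Ramping the tree depth" means increasing a single decision
tree's maximum-depth limit from 1 until its training ROC-AUC reaches 1.0 —
the only standard tunable matching that description — with a cap of 20 and
a warning when inseparable data never get there.  Note that a greedy tree
cannot resolve a perfectly balanced XOR at depth 2 (the first split has
zero impurity gain); the depth ramp is only guaranteed to stop early when
greedy splits have gain.

Screening evaluates each pooled protein alone with a default-configuration
logistic regression under stratified 5-fold CV and keeps the top 4 (an
exposed threshold, not a detected elbow).  The exhaustive search evaluates
every non-empty candidate subset (capped at 12 candidates = 4095 subsets)
against four algorithms, each grid-searched **on the same folds**; per
(subset, algorithm) the best grid point's per-fold AUC mean/SD and pooled
out-of-fold ROC curve are recorded, and results are ordered AUC-descending
then subset-size-ascending (parsimony breaks ties).  Grids are
configuration, not code; the default random-forest grid is kept small
(100 trees, depth ∈ {2, 5, ∞}) so a full search runs in tens of seconds on
one CPU.

Fold safety: by default standardization is fitted inside training folds.
`paper_faithful=True` Z-scores the whole matrix before CV — the common but
leak-prone global ordering.  The leakage regression test compares
full-data feature selection against nested (per-fold) selection on pure
noise and asserts the leaky variant scores higher, which is the reason the
fold-safe path exists.

## Synthetic cohort: what it emulates, and what not

Abundances are ln-scale Gaussian: protein p in group g is
`N(μ_p + δ_{p,g}, σ²)` with per-protein baselines μ_p drawn once from
(0, 6) ln-units and within-group σ = 0.6.  The exported raw matrix is
`expm1` of the ln values (so `ln1p` recovers the generative scale exactly);
ln values are floored at 0, which only affects proteins that are almost
never detected.  A cell is observed with probability
`logistic((x − 4.05)·2.5)` — missingness is mechanistic and left-censored,
the regime the downshifted-Gaussian imputation targets, not MCAR.  With
these defaults a 177-protein panel keeps roughly 55–65 features after the
70 % filter, matching the scale of a real cohort of this design.

Group sizes default to the study design (23 controls; MCD 8, mFSGS 11,
sFSGS 15, MN 12).  Three planted markers (baseline pinned at 5.2
ln-units, above the detection midpoint, so they survive the filter) carry severe-group effects sized for
a mild-vs-severe Cohen's d of about 2 on the analysis matrix — strong but
not single-handedly separating, so recovering them requires combining two
or three.  Clinical covariates are log-normal around the published group
medians (eGFR 93/96.9/42.0/77.3, proteinuria 3.24/2.3/5.0/3.25 for
MCD/mFSGS/sFSGS/MN; controls 105 and 0.1) with ln-SDs 0.30/0.40 chosen to
match the reported interquartile spans; steroid-resistance rates are
0 %/30 %/84.6 % for MCD/mFSGS/sFSGS and *unknown* for MN (not determined
in the source cohort), which exercises the index's unscorable path.  FSGS
covariates are rejection-sampled until the severity index reproduces the
group label, so generator truth and scorer agree by construction.

The transition-report generator gives both traces of an injection a shared
log-normal injection factor plus independent per-trace noise of CV 5 %, so
ratios carry a residual CV of about √2 × 5 % — quantification recovers
true concentrations within 3 × CV for ≥ 95 % of observed cells.

What the generator does **not** emulate: correlated protein blocks,
batch/drift effects, interference transitions, digestion variability, or
real biological effect sizes (the source study reports none).  Passing the
recovery experiment therefore shows the *procedure* is sound and
leak-free at realistic n, not that any particular real panel would reach
the same AUC.

## Experiment sizes and numerical choices

Oracle comparisons use 1000 random p-vectors (BH/Holm), all sample-size
pairs with n₁+n₂ ≤ 10 × 5 draws (exact Mann–Whitney), and 100 random
instances each for the calibration-WLS oracle, the quantify∘fit round
trip and the AUC = U/(n₁n₂) identity, at tolerances 1e-12/1e-10/1e-9.
The imputation moments use 1e5 draws (2 % tolerance ≈ 6 Monte-Carlo SDs).
The severity grid is eGFR 10–120 × proteinuria 0–10 (0.1 steps) ×
resistance, ~22k cells.  The marker-recovery experiment runs the full
pipeline on 10 seeded cohorts (~35 s each on one CPU) and requires ≥ 9
successes; the dominant failure mode is a seed where one marker's realized
separation is so strong that a singleton ties the best pair at AUC 1.0 and
parsimony returns it alone.  The null-calibration experiment checks the
raw-flag rate against the 1 % nominal level (the exact test's discreteness
keeps it at or below nominal) and that null single-feature CV AUCs center
on 0.5.

All randomness flows from explicit integer seeds through numpy
`SeedSequence` streams; there is no global random state, and every
pipeline stage is bit-reproducible under a fixed seed.
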