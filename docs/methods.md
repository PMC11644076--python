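# Methods

## The trial and its generative model

The package targets replicated screening trials of the form
genotype × treatment × block with a single destructive harvest. The default
preset emulates a winter-wheat semi-hydroponic screen: 100 genotypes, four
treatments (control C; low phosphorus LP; osmotic drought D; combined DLP),
four complete blocks (staggered sowing dates), harvest at 65 days after
transplanting, roots measured in 20 cm depth layers down a 120 cm panel.

Every positive-valued measurement `y` of trait `t` for genotype `i`,
treatment `j`, block `k` is simulated on the log scale:

    ln y = ln mu_t + ln m_tj + g_i + (gt)_ij + b_k + eps,

with `g ~ N(0, s2_G)`, `(gt) ~ N(0, s2_GT)`, `b ~ N(0, s2_block)` and
`eps ~ N(0, s2_e)` independent. The log-normal form guarantees positive
lengths and weights and makes the log response ratio the natural effect
scale for treatment contrasts, which is how treatment effects enter
(multipliers `m_tj`, with `m_tC = 1` by definition). Counts (root, leaf,
tiller number) are generated the same way and rounded to the nearest
non-negative integer.

### Preset parameter choices

Baseline means and treatment multipliers are set to the treatment-level
means observed in such screens (control root length ≈ 1290 cm, root dry
weight ≈ 0.12 g, shoot dry weight ≈ 0.52 g, mean diameter ≈ 0.18 mm, and so
on), so the qualitative contrasts are built in: drought raises root length
(×1.43), depth and diameter; low phosphorus and especially the combined
stress depress biomass (shoot dry weight ×0.23 under LP, ×0.21 under DLP)
and phosphorus traits; depth rises under every stress. Log-scale variance
components default to `s2_G = 0.05–0.25` per trait (giving genotypic CVs of
roughly 0.3–0.6, the range these screens report), `s2_GT = 0.03`,
`s2_block = 0.01`, `s2_e = 0.05`. The preset is qualitative: it reproduces
directions and magnitudes of variation, not any specific dataset.

### Root geometry

Total root length is split over the layers the root system reaches
(`ceil(MRD/20)` layers) by a Dirichlet draw whose concentration weights
decay with depth — fast decay (0.9 per layer) under C and LP, slow decay
under D (0.25) and DLP (0.35), encoding the deeper root placement drought
induces. Allocation noise is treated as residual noise: if the residual
variance of root length is zero the split is the deterministic Dirichlet
mean, so a fully noise-free configuration yields identical replicates.
Per-layer diameters follow a fixed 6%-per-layer taper rescaled so their
length-weighted mean equals the generated whole-plant diameter exactly;
derived traits therefore round-trip to the generator's values. Layer
surface area and volume use cylinder geometry; measured `ra_*`/`rv_*`
columns in real input override the geometric formulas.

### What the generator does not emulate

No osmotic physiology, nutrient chemistry, imaging noise, spatial
correlation within bins, mortality or missingness. Passing tests on
synthetic data demonstrate the statistical machinery (estimators,
identities, calibration), not biological validity of any particular
dataset.

## Trait definitions and unit conventions

Traits follow the standard screen definitions (SRL = RL/RDW,
RLI = RL/MRD, RTD = RDW/RV, RLD = RL per 1430 cm² panel area, RGR =
MRD/DAT, SGR = SH/DAT, RSR = RDW/SDW, TDM = RDW + SDW, P contents =
concentration × dry weight). Two unit choices deserve note: SRL is
reported in cm·g⁻¹ and RTD in g·cm⁻³, the units consistent with the
magnitudes these screens print (SRL ≈ 10⁴ for RL ≈ 1300 cm and RDW ≈ 0.1 g;
RTD ≈ 0.2). The whole-plant diameter is the length-weighted mean of layer
diameters. Layer reference areas for local length density use the panel
width implied by the 1430 cm²/110 cm convention (13 cm), i.e. 260 cm² for
the 0–20 cm layer. Undefined ratios (zero denominators, an empty sub-layer
for RLR_s1/sub) propagate as NaN, never as zeros or exceptions.

## Stress indices

All seven indices use total dry mass (root + shoot) as the dry-weight
basis; genotype values are block-averaged first, and the population means
are taken over genotypes with complete control and stress data. STS is the
literal unweighted sum of the seven indices even though they mix units and
directions — that is the convention the score defines; a z-standardized
variant (`standardize=True`) is provided for users who want a unit-free
score but is never the default. The AM–GM–HM inequality guarantees
HMI ≤ GMPI ≤ MPI with equality only when control and stress weights agree,
and STI·D̄W_C² = GMPI² identically; both identities are enforced by tests.

## ANOVA and heritability

Treatments decompose into phosphorus (±P) and water (±W) factors, giving
the factorial G × P × W + block fixed-effects model, fitted by OLS with
sequential (type I) sums of squares — on balanced data all SS types
coincide, and unbalanced input triggers a warning. Tukey HSD letters come
from the studentized-range test with an insert-and-absorb compact letter
display ordered by descending means.

Variance components use expected mean squares of the genotype (random) ×
treatment (fixed) layout, matching the classical heritability formulas:
single-treatment V_G = (MS_G − MS_E)/r; combined V_GE = (MS_GE − MS_E)/r
and V_G = (MS_G − MS_GE)/(r·e). Negative estimates are truncated at zero
and flagged, keeping H and H_com in [0, 1]. No REML fitting is attempted —
the EMS construction is the one the formulas define. Because the synthetic
model is log-normal, the calibration suites estimate components on the log
scale (`log_scale=True`), where the generative decomposition is exactly
linear; the recovery check simulates traits at analytic
H = 2/(2 + 2/4) = 0.8 and recovers the mean to within 0.03 over 200 traits.

## Effect sizes

LnR, the percent transform and the independent-groups sampling variance
are computed over genotype-level (block-averaged) values, stress versus
control. Pooling uses fixed-effect inverse-variance weights with normal
±1.96·√v intervals — the standard meta-analytic treatment of the log
response ratio; zero-variance records are excluded from pooling with a
warning. Pooling is exposed at any grouping the user chooses (per trait,
per treatment, or grand), since overall-effect conventions differ between
studies.

The null-calibration suite simulates traits with all multipliers 1, no
genotype main effect and no block effect (`null_screen_config`), so
control and stress groups are statistically independent — the regime in
which the independent-groups variance formula is exact. With shared
genotype or block effects the formula is conservative (control and stress
group means are positively correlated), which is a documented property of
the estimator, not a defect of the calibration. Under the null, 4–5% of
95% intervals exclude zero over 1000 traits of 100 genotypes.

## Multivariate screening

Trait selection keeps traits with CV ≥ 0.3 (inclusive) across genotype
means within a treatment, with an explicit drop-list for traits that are
deterministic transforms of already-selected ones (RGR from MRD, RLD from
RL). Pearson correlations use pairwise-complete observations with
t-distribution p-values (n − 2 df) and 0.05/0.01/0.001 star classes; no
multiple-testing correction is applied, matching common practice in these
screens (a documented limitation). PCA z-scores each trait and
eigendecomposes the correlation matrix, retaining eigenvalue > 1
components (Kaiser rule); component signs are fixed by making the
largest-magnitude loading positive, for deterministic output. Clustering
standardizes traits before Euclidean distances (otherwise SRL at ~10⁴
dominates RTD at ~10⁻¹) and uses average linkage cut to k groups (default
5). Group trait profiles are normalized per trait to proportions across
groups (x′ = x/Σx). STS-based grouping clusters the one-dimensional
STS_SUM values the same way and renumbers groups by descending mean score,
so Group 1 always holds the top-scoring genotypes — the verbal grouping
rules in the literature mix ranking and clustering, and this convention
makes the assignment deterministic and reproducible.

## Pipeline and numerical choices

All randomness flows from one root seed; the pipeline writes CSVs with a
fixed float format and a log without timestamps, so identical
configurations are byte-identical. The pipeline's ANOVA stage analyses
traits with complete data (deep-layer diameters are structurally missing
for plants whose roots do not reach those layers and are skipped).
Problem sizes in the calibration suites — 200 traits for heritability
recovery, 1000 traits × 100 genotypes for null calibration, 90 genotypes ×
12 traits for cluster recovery — are chosen to put Monte-Carlo error well
below the tolerances being checked while keeping the whole suite fast.

## Known limitations

- The preset is qualitative; it does not reproduce any published table's
  exact numbers, which depend on unreleased raw data.
- The EMS heritability treats the design as balanced; strongly unbalanced
  data should use a mixed-model package instead.
- The lnRR variance formula ignores genotype-level pairing between control
  and stress groups (conservative when genotype main effects are large).
- STS mixes units by construction; cross-study comparison of raw STS
  values is not meaningful.
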