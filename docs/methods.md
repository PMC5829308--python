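# Methods

This note records the statistical models implemented in `gmbiome`, the
design choices made where several defensible options existed, and what the
synthetic-data generator does and does not emulate.

## Latent market-integration factors

Seven lifestyle indicators are analysed: five ordered house-construction
codes (wall, floor, bathroom, water, electricity) and two ownership
proportions (fraction of a 6-item traditional list and of a 12-item market
list owned). Ordinal codes are treated as numeric after z-scoring —
fidelity to how such indicators are typically fed to factor analysis was
preferred over polychoric machinery. Rows with missing indicators are
dropped (listwise) and logged.

The factor model is fitted by maximum likelihood on the sample correlation
matrix. The likelihood is profiled over loadings: for fixed uniquenesses
`Ψ`, the optimal `Λ` comes from the top-k eigenpairs of `Ψ^{-1/2} R Ψ^{-1/2}`,
leaving the criterion `F(Ψ) = Σ_{j>k} (λ_j − log λ_j) − (p − k)` minimized by
L-BFGS-B over `Ψ ∈ [0.005, 1]^p`. The lower bound prevents Heywood cases;
four starting points (the classic `(1 − k/2p)/diag(R⁻¹)` start, a flat
start, and randomized starts) guard against local minima. Fit is judged by
the Bartlett-corrected likelihood-ratio statistic with
`df = ((p − k)² − (p + k))/2`; `max_factors(p)` is the largest k with
non-negative df (3 for p = 7). This implementation was cross-checked
against an independent reference (R's `factanal`) to ~1e-3 on statistics
and loadings.

Model growth stops, by default, when the fit test no longer rejects
(p ≥ 0.05) or the df ceiling is reached. The opposite direction — stop as
soon as p < 0.05 — is available as `stopping="as_printed"` because field
descriptions of this procedure are sometimes phrased that way; on data with
genuine multi-factor structure that direction stops at k = 1 (the one-factor
model is immediately rejected), so the fit-adequate direction is the
default. Loadings are varimax-rotated with Kaiser row normalization;
rotation choices are conventions, so columns are canonicalized: ordered by
explained variance and signed so each column's largest-magnitude loading is
positive. Factor labels (house modernity, subsistence items, power usage)
follow the variance ordering; on synthetic replicates the semantic identity
of the second and third factors can occasionally swap — the labels describe
positions, the loadings table is authoritative. Scores are regression
(Thomson) scores `f = Z R⁻¹ Λ`.

## Community metrics

Samples under 20,000 reads are removed (boundary inclusive: exactly 20,000
is kept). The default normalization is rarefaction without replacement to
the smallest retained library — a multivariate hypergeometric draw per
sample. A median-of-ratios size-factor transform
(`x_ij = log2(count_ij / s_i + 1)`, `s_i` the median ratio over OTUs positive
in every sample) is provided as the alternative; the full parametric
variance-stabilizing machinery of count-model packages is out of scope, and
rarefaction is the default used by the acceptance checks. Distances are
computed from relative abundances of the normalized table. The OTU screen
correlates log2(count + 1) of the rarefied table (or the size-factor
transform when selected): rarefied counts are depth-matched but still
heavy-tailed, and Pearson correlation on the log scale is the standard
choice.

Faith's PD is presence-based: the sum of branch lengths connecting a
sample's taxa to the root (`include_root=True` by default, the common
convention for rooted trees; the to-MRCA variant is available). Descriptions
that speak of abundance-weighted PD notwithstanding, the canonical Faith
statistic uses presence only; abundances enter PD solely through which taxa
are present after normalization.

Weighted UniFrac is implemented on a flattened tree: a boolean
branch × leaf incidence matrix plus a branch-length vector. Per-branch
abundance loads are `incidence @ p`, the raw distance is the
branch-length-weighted L1 difference of load vectors, and the normalized
variant divides by the weighted load sum (branch-sum normalization; in
[0, 1], and verified to coincide with the scikit-bio implementation).
Zero-length branches are legal and contribute nothing. Whole-cohort
distance matrices use one load pass per sample and one weighted L1 per
pair — about 0.2 s for 213 samples × 998 branches.

## Windowed beta-dispersion

On a continuous gradient, the dispersion of sample i is the mean distance
to samples j with `|f_j − f_i| ≤ w · range(f)`, self excluded; `w = 0.05` by
default with a 0.025–0.10 sensitivity sweep. The window is defined on the
score *range* so that affine changes of the score leave the statistic
unchanged (a value-relative window would degenerate near zero scores).
Samples with empty windows become missing and are excluded from the
dispersion regression — this bookkeeping is exactly why per-factor
regression sample sizes can differ from the cohort size, and it is asserted
to reconcile (`n_regression = n_cohort − n_empty`).

Inference on the dispersion-versus-score slope is by permutation, not a
t-test. Dispersion values of nearby samples average overlapping sets of
pairwise distances, so their errors are strongly positively correlated
along the gradient; under the null generator the classical t-test on the
OLS slope rejected at 31–37% instead of 5%. Permuting which sample sits
where on the gradient — recomputing windows and dispersions each time — is
exact under exchangeability. Because the multiset of scores is fixed under
permutation, the slope statistic is `sum(K ∘ D[σ][:,σ])` for a kernel `K`
built once per window (banded in sorted-score space), so hundreds of
permutations are cheap and one permutation set is shared across the sweep.
The OLS slope and R² are still reported as descriptive statistics.

## PERMANOVA and partial db-RDA

Squared distances are Gower-centered (`G = −½ J D² J`). PERMANOVA uses
sequential sums of squares: terms enter in the user's stated order, each
term's SS is `tr(ΔH G)` for the increment in hat matrices, and pseudo-F
compares the term mean square to the full-model residual mean square.
p-values come from freely permuting sample labels (rows and columns of G
together), with the `(1 + exceedances)/(1 + n_perm)` convention so p is
never zero. On Euclidean distances of a univariate response this reproduces
the classical one-way ANOVA F exactly (an oracle class in the tests).

Partial db-RDA first projects the condition block out of G
(`G_r = (I − H_c) G (I − H_c)` — the condition's variance is removed before
anything else is considered), residualizes the centered constraints on the
condition, and eigen-decomposes `H_x G_r H_x` for the constrained axes
(positive eigenvalues only; weighted-UniFrac matrices can be non-Euclidean
and traces legitimately include small negative parts). Constraint
significance permutes the conditioned matrix — permutation of residuals
under the reduced, condition-only model. The constrained plus residual
inertia of a grouping's dummy block equals the PERMANOVA SS decomposition
for that grouping (cross-module consistency test).

## Taxon screen and FDR

Pearson r between every (variance-positive) OTU and every factor score;
`t = r√(n−2)/√(1−r²)` on n−2 df, two-sided. The Benjamini–Yekutieli
adjustment is applied jointly across all OTU × factor tests:
`q_(i) = min(1, p_(i) · m · c(m)/i)` with `c(m) = Σ_{j≤m} 1/j`, made
monotone from the largest rank downward. BY was chosen (over BH) because
OTU abundances are arbitrarily dependent — compositional and phylogenetic
correlation — and BY controls FDR under any dependence. Constant OTUs get
missing results, never zeros.

## Linear models

OLS (with classical SEs) backs the PD regressions. Model selection is
backward elimination by nested F-tests at α = 0.05, respecting marginality
(a main effect is never dropped while its interaction remains); the
elimination path is logged so alternative paths can be audited. Interaction
structure is visualized by prediction profiles: the moderator runs from 0
to its observed maximum in 100 steps, each step giving one fitted
response-versus-focal line with other covariates at reference values (mean
for numeric, modal level for categorical).

## The synthetic-data generator

The generator is the package's test bed and defines the conditions every
statistical check runs under: 213 participants in 5 villages (2 in a
market-proximal region, 3 across a mountain range), 500 taxa, and lognormal
library sizes (median ≈ 1.7e5) truncated below at 20,843 reads — the
emulated cohort is post quality control, matching a deeply sequenced 16S
study's depth range of roughly 2e4–2.6e6.

Latent factor scores are exactly standardized normals plus region shifts
(+0.6 modernity, −0.45 subsistence, +0.6 power in the market-proximal
region; compensating shifts keep overall means at zero). Indicators are
`f Λᵀ + ε` with uniqueness-matched noise; the default loading pattern puts
house-construction codes on factor 1, traditional-item ownership on
factor 2 (with −0.35 cross-loadings on bathroom, water and market items —
a factor marked by a single indicator is statistically unidentifiable, and
real style-of-life batteries correlate this way), and electricity plus
market items on factor 3. House codes are quantile-binned to ordered levels
(4 levels; 3 for electricity), preserving rank correlation with the latent
variable; ownership proportions use a probit link and binomial draws over
the item lists, so they live on {0, 1/6, …, 1} and {0, 1/12, …, 1} exactly
as list-based scales do.

Communities are Dirichlet-multinomial over an accessible pool. Half the
taxa are "environmental"; a sample includes each with probability
`0.7 · exp(pd_slope · m_i + η_i)` where `m_i = f1_i (1 + 0.3 f3_i)` is
effective modernity and `η_i ~ N(0, 0.3²)` is individual exposure
heterogeneity (without it, PD would be a nearly deterministic function of
the gradient). The Dirichlet concentration `θ_i = 50 · exp(−0.25 m_i)`
falls with modernity; lower concentration provably raises expected pairwise
distance, producing the dispersion gradient. Defaults (`pd_slope = −0.25`,
`disp_slope = 0.25`, `interaction = 0.3`) were calibrated once, by pilot
simulation, to the qualitative structure the design requires — negative
PD–modernity slope, positive dispersion–modernity slope, modernity
significant in the pipeline's region-first PERMANOVA, and three factors
selected, each in ≥90% of replicates *with estimated (not true) factor
scores*; estimation noise attenuates compositional signals by roughly the
squared score-truth correlation (~0.65), which is what pushed the
accessibility slope from −0.15 to −0.25.

What the generator does not emulate: real taxonomic abundance structure
(no Prevotella/Bacteroides biology — taxa are anonymous leaves), diet,
within-village clustering beyond the region shift, longitudinal or age
structure in the microbiome, and sequencing artefacts (chimeras, OTU
mis-clustering). Passing tests therefore demonstrate statistical
correctness and calibration of the machinery, not biological realism of
any particular effect size.

## Problem sizes and numerical choices

Monte Carlo suites keep the cohort at its full size (n = 213) but scale the
per-replicate cost: the type-I calibration loops (1000 replicates, 199
permutations per test) use 64 taxa and ~8,000-read libraries, since error
rates under the null do not depend on those dimensions; the recovery loops
(100 replicates) run at the full default scale. Reported p-values from
permutation tests are granular at 1/(n_perm + 1); with 199 permutations a
5%-level rejection is p ≤ 0.05 exactly (10/200). Distances are clamped
non-negative; degenerate inputs (constant gradients, zero-variance
indicators, empty windows, all-zero distance matrices) raise typed errors
or produce missing values rather than silent zeros. All randomness flows
through named substreams derived from one master seed (simulation,
rarefaction, PERMANOVA, db-RDA, dispersion), recorded in the run manifest;
identical configurations reproduce every output file byte for byte.

## Known limitations

- The ML factor fit can sit at the uniqueness bound for weakly identified
  factors (two markers or fewer) — loadings for such factors are reported
  but should be read with care.
- Sequential (order-dependent) PERMANOVA is the only SS type implemented;
  marginal (type-III-like) tests are not.
- Free permutation is used for PERMANOVA even with covariates in the model;
  restricted permutation schemes (within-block) are not implemented.
- The db-RDA permutation test permutes the conditioned matrix as a whole;
  exactness is asymptotic when the condition block is non-trivial.
- Weighted UniFrac on size-factor-transformed values uses zero-clamped
  relative abundances; negative transformed values have no canonical
  UniFrac interpretation.
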