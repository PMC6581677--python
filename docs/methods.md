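# Methods

`herdnet` implements the analysis chain used in behavioural-ecology studies
of managed cattle herds: scan-sampled nearest-neighbour observations and
agonistic interaction logs are turned into social networks, dominance
hierarchies, individual centralities, homophily tests, mixed-model
inference with permutation significance, and transfer-impact statistics.
This note records the models, the conventions, and the design choices made
where the methodology admits more than one reading.

## Data model

Four tables describe a study: a roster (individual, sex in {F, M, CM},
birth date, residence intervals), a scan log (per scan, each focal's
single nearest neighbour), an agonistic log (winner, loser, behaviour in
{supplant, avoidance, aggression}), and a composition manifest (stable
membership episodes per group, with enclosure-only changes flagged).
Dates are ISO-8601; residence intervals are closed on the start and open
on the end. Birth dates given to year precision are imputed to July 1
(ages are used at whole-year resolution downstream, so mid-year imputation
bounds the error by half a year).

**Age** is the day count from birth to the reference date divided by
365.25.

**Familiarity** of an individual in a composition is the number of
groupmates whose accumulated co-residence before the composition start
strictly exceeds 90 days ("more than 3 months"). Co-residence accumulates
only over intervals at the same location; total overlap is summed without
decay, so brief removals pause the clock rather than reset it. The strict
inequality means exactly 90 days does not qualify.

## Association matrices

Every scan records, for each focal, one nearest neighbour (the closest
animal, whatever the distance). Directed designations are summed into a
symmetric per-composition matrix: A naming B and B naming A each increment
the (A, B) dyad, so a mutual designation contributes 2. Whether field
protocols count a mutual designation once or twice is a convention, not a
fact about the animals; the alternative (`convention="once"`) is provided
and the directed sum is the default because downstream analysis uses only
the symmetric dyadic weight.

Relationships are unstable immediately after a transfer or enclosure
change, so scoring starts on the eighth day after a change: scans in days
0–7 of a composition that follows a change are excluded
(`exclusion_days=7`). Scan logs carry scan indices rather than
timestamps; the package maps index to observation day as
`scan_index // scans_per_day` with 72 scans per full observation day (one
scan every 5 minutes over a 6-hour observation day). The synthetic
generator emits indices consistent with this convention.

## Dominance: Modified David's Score

For each ordered dyad, with `n_ij = wins_ij + wins_ji`:

    P_ij = wins_ij / n_ij
    D_ij = P_ij - (P_ij - 0.5) / (n_ij + 1)

`D_ij` is the chance-corrected dyadic index: it shrinks `P_ij` toward 0.5
by an amount that vanishes as the dyad's sample grows, so a 1–0 record is
not scored as total dominance. Scores combine unweighted and weighted win
and loss sums:

    w_i = Σ_j D_ij         w2_i = Σ_j D_ij · w_j
    l_i = Σ_j D_ji         l2_i = Σ_j D_ji · l_j
    DS_i = w_i + w2_i - l_i - l2_i

Individuals are ranked 1..N by descending DS. Two conventions are
documented toggles because the method family admits both:

* **Zero-interaction dyads contribute 0** to every sum (not 0.5): absent
  evidence adds no score, and the choice preserves the zero-sum property
  of DS over the dyads that did interact.
* **`chance_corrected=False`** uses the raw `P_ij` (classic David's
  score).

Rank ties are broken by lexicographic id order and reported in the result
object. All three agonistic behaviours count equally as wins.

## Centralities and the group-size correction

**Strength** is the row sum of the association matrix. **Eigenvector
centrality** is the entrywise non-negative dominant eigenvector, computed
by exact symmetric eigendecomposition (with a power-iteration refinement
guard) and normalised to unit Euclidean length within each composition;
max-entry normalisation is an option. On a disconnected association graph
the dominant eigenvector concentrates on the strongest component and a
structural warning lists the components.

Both metrics scale mechanically with the number of nodes, so they are
corrected for group size before regression. The correction fits the
pooled regression `metric = a·group_size + b` and, in the default
`residual` mode, removes the fitted trend while preserving the mean:
`y' = y - a·(x - mean(x))`. A `literal` mode (`y' = y·b`, multiplication
by the fitted intercept) is also shipped: the multiplicative reading of
the correction appears in the applied literature, but multiplying by a
constant cannot remove a size effect, so it is provided for reproduction
and is not the default. Fitted `(a, b)` are recorded in the run manifest.

## Homophily: difference matrices and Mantel tests

For each composition, pairwise difference matrices are built for age and
dominance rank (absolute difference) and sex (0 same, 1 different) and
correlated with the association matrix. Because dyadic weights are not
independent, correlation is assessed with a Mantel test: the Pearson
correlation of vectorised upper triangles, with a null built by permuting
rows and columns of one matrix simultaneously.

* Sampled p-values use the +1/+1 rule, `p = (#extreme + 1)/(n_perm + 1)`,
  so `p > 0` always and `p = 1` is representable. Default
  `n_perm = 1000`.
* When `N! <= 5000` the full permutation group is enumerated and the
  p-value is exact.
* Sidedness is a required explicit argument. The pipeline tests age and
  rank one-sided for negative correlation (homophily: smaller difference,
  stronger association) and sex two-sided; single-sex compositions are
  reported as NA rather than silently dropped.

Per-composition p-values are combined into a global statistic with
Fisher's method (`X² = -2 Σ ln p_k` on 2k df); Stouffer's inverse-normal
method is an option. Fisher is the default because it is the conventional
choice when nothing favours weighting; the combination method used by any
particular prior analysis of this kind is rarely stated, and the choice is
surfaced in the config rather than buried.

## Mixed models, multi-model inference, permutations

The regression unit is one individual in one composition. Responses
(corrected centralities, or their before/after differences) are modelled
with a Gaussian linear mixed model with a random intercept per individual.
Candidate fixed effects for the centrality models are age, sex, dominance
rank and familiarity; for the delta models age, familiarity in the new
composition, rank change and the number of individuals transferred — sex
is excluded from delta models (too few transferred males; the term aliases
with age there). Sex enters as dummies against a castrated-male reference
when all three categories are present; reference and levels adapt to the
categories observed.

**Estimation.** The random-intercept-only Gaussian LMM admits a
closed-form profile likelihood over the variance ratio
`theta = tau²/sigma²`: the marginal covariance is block-diagonal
`sigma²(I + theta·Z Z')` and each block inverts analytically. `fit_mixed`
optimises `theta` by a log-spaced grid scan plus bounded refinement;
maximum likelihood (not REML) is used so AICc is comparable across
fixed-effect sets. When the random variance is unidentifiable (one
observation per individual) the boundary `tau² = 0` is reported and the
fit reduces exactly to ordinary least squares. The implementation is
cross-checked against statsmodels' MixedLM in the test suite; the
in-package fit exists because node-label permutation inference refits the
model thousands of times per analysis and the one-dimensional profile
makes each refit cheap.

**Multi-model inference.** Every subset of the candidate terms is fitted
(guarded at 6 candidates, 2^6 models). Akaike weights
`w_m ∝ exp(-ΔAICc_m/2)` are normalised over the full set; the relative
variable importance of a term is the summed weight of the models
containing it. "Best models" are those with ΔAICc ≤ 2 (the conventional
cut); term estimates are model-averaged over the best set with zero
substitution for absent terms, and unconditional SEs include the
between-model spread. `k` counts the fixed effects plus both variance
components; `AICc = AIC + 2k(k+1)/(n-k-1)`.

**Node-label permutations.** Significance comes from permuting the
response across individuals and refitting: by default within each
composition (preserving composition-level structure; whole-table
permutation is an option). For each term,
`p_right = (#{beta* >= beta_hat}+1)/(n_perm+1)` and `p_left`
symmetrically; both columns are reported. The permuted statistic is the
raw estimate (not its z-value). Refit failures are retried with a fresh
permutation and counted, never dropped silently.

**Diagnostics.** Variance inflation factors (`1/(1-R²)` of each predictor
on the others) gate the model set: perfect collinearity is rejected before
any fitting. Residual normality of the full model is summarised by a
Shapiro–Wilk test in the inference result.

## Transfer analysis

Adjacent compositions of one group are compared on their shared members
(at least 3): association matrices restricted to the intersection are
correlated with a Mantel test (one-sided positive: is the network
conserved?), and per-individual centrality deltas (after − before) are
taken on the corrected metrics by default (raw-metric deltas are an
option). An individual without a defined rank on either side yields a
missing rank delta, never an imputed one. Enclosure-only changes are
transfers of 0 individuals, giving the no-transfer baseline. Across
changes, the per-change Mantel r is summarised (mean, range) and
correlated with the number transferred by a Spearman test with
permutations.

## The synthetic herd generator

No field data ship with the package; the generator produces datasets with
the statistical structure the analysis assumes, with known ground truth:

* **Roster**: 20 individuals by default, 70% female / 15% male / 15%
  castrated male, 40% juveniles (0.5–3 y) and 60% adults (3–12 y),
  arrival staggered 10–300 days before the study starts (which is what
  makes familiarity vary).
* **Dominance**: latent score `gamma·age + N(0, sigma)` with `gamma = 1`
  per year and `sigma = 2`; dyads interact `Poisson(0.1/day)` times per
  composition and the higher-scoring animal wins with probability
  `logistic(k·Δscore)`, `k = 1`.
* **Scans**: each focal names one neighbour per scan with probability
  proportional to `exp(-0.8·|Δage| - 0.15·|Δrank| + 0.5·[same sex]
  + 0.5·[familiar])`; 100–900 scans per composition (the scale of
  published scan-sampling studies on herds of 8–21 animals). The rank in
  the kernel is the latent rank, not the estimated one, so generation and
  inference stay separable. Neighbour draws are independent across focals
  within a scan; a mutual-nearest-neighbour constraint is a documented
  extension, not the default.
* **Timeline**: two groups with seven compositions linked by transfers of
  2, 1 and 0 (enclosure-only) animals, so the transfer bookkeeping has
  every case.

All randomness flows from the scenario seed; a fixed seed reproduces the
written CSV tables byte for byte.

**What the generator does not emulate.** Dyadic preferences beyond the
attribute kernel (idiosyncratic friendships), temporal drift within a
composition, observation biases, and mother–calf bonds are absent. Two
consequences matter when reading test results: homophily effects and
across-change network stability are *stronger* in synthetic herds than in
field data (the kernel is noiseless and stable), so passing power tests
show the machinery detects the structure it is pointed at — not that
field effect sizes would be detected at these sample sizes; and the
generator's Mantel correlations across transfers sit near 1 rather than
in the moderate range seen in real herds.

## Numerical choices and degenerate inputs

* Eigendecomposition residual tolerance 1e-10 (relative to the dominant
  eigenvalue); all-zero association matrices are an error (centrality
  undefined), not a silent zero.
* Permutation statistics equal to the observed one count as extreme
  (tolerance 1e-12), which keeps p-values exact under ties.
* Correlation of a constant vector or matrix is an error everywhere, and
  the pipeline converts it to an explicit NA row where the study design
  makes it expected (single-sex compositions).
* Dominance ties are broken deterministically (lexicographic) and
  reported.
* `combine_pvalues` rejects `p = 0`; the +1/+1 rule upstream guarantees
  it cannot occur in-pipeline.
* The deviance grid for `theta` spans 1e-4–1e4 on a log scale; the
  boundary `theta = 0` is preferred whenever it is numerically as good,
  so unidentifiable random variance is reported as exactly zero.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on synthetic
data at the scale the package targets: herds of 10–20 animals, 60–900
scans per composition, permutation counts of 99–1000, and simulation
batches of 50–500 replicates. These sizes were chosen so the statistical
contracts (calibration within exact binomial bounds, power and recovery
thresholds) are sharp at desk scale.

## Known limitations

* Only Gaussian responses and a single random intercept are supported; no
  random slopes or temporal autocorrelation.
* The literal group-size correction is reproduced but cannot be
  recommended; the residual mode answers the question the correction is
  meant to ask.
* Familiarity treats co-residence as the only channel; kinship is out of
  scope by design.
* The Mantel test assumes exchangeable rows under the null; attribute
  structure that violates exchangeability (e.g. strong spatial blocking)
  is not modelled.
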