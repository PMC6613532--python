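# Methods

This note documents the models and procedures implemented in
`macronull`, the conventions and numerical choices behind them, what the
synthetic-data generators emulate, and the limitations a user should
know before trusting a number.

## The incidence matrix and the latitudinal domain

All analyses operate on a binary species × band matrix over a bounded
one-degree discretization of a latitudinal gradient (default 18–56°S,
the hard continental limits of the Chilean freshwater systems: the arid
diagonal to the north, the fjord/glacier fragmentation to the south).
Band `k` covers the half-open interval `[k, k+1)` degrees S; a latitude
exactly at the south limit is clamped into the last band, so the default
domain has exactly 38 bands and no phantom 39th at 56°S.

Latitudes are stored as degrees-S magnitudes (positive, increasing
poleward); CSV readers accept signed decimal degrees (negative = south)
behind a flag.

Two constructions are provided because range data can be reported either
way: **interval fill** (default; a species occupies every band its
closed `[lat_min, lat_max]` range intersects, so each row is a
contiguous run) and **record binning** (only bands containing an actual
occurrence record are marked). Interval fill is the default because
range tables (min/max per species) are the usual distribution format for
this fauna; the choice matters for every downstream statistic, and both
modes are exposed.

`pack_matrix` sorts rows and columns by decreasing totals with a
**stable** sort: tie order is inherited from the input. This makes
packing, BR and temperature deterministic; implementations that optimize
tie order (e.g. vegan's `nesteddisc`) can differ by a unit or two of
discrepancy on tied matrices.

## Chao2

With bands as incidence samples, `S_est = S_obs + Q1²/(2·Q2)` (classic
form) when duplicates exist, and the bias-corrected
`S_obs + ((m−1)/m)·Q1(Q1−1)/(2(Q2+1))` when `Q2 = 0`. Note that on
interval-filled range data with the default generator (minimum range
size one degree) almost no species occupies exactly one band, so
`Q1 ≈ 0` and the estimator reports a complete inventory; uniques arise
from point-like ranges or record-binned matrices.

## Rapoport randomized regression

Each species contributes (midpoint, extent) = ((min+max)/2, max−min).
The test is OLS of extent on midpoint with a permutation null: extents
are shuffled across midpoints `n_perm` times and the slope recomputed
(vectorized as a dot product per permutation). The p-value uses the
add-one rule `p = (1 + #{|slope_null| ≥ |slope_obs|})/(1 + n_perm)`, so
`p > 0` always; two-tailed by default (`tails=1` tests a positive slope
only). The midpoint method is used as such, not Stevens' band-averaged
variant.

Calibration caveat: the permutation null assumes extents exchangeable
across midpoints. Ranges *generated under a bounded domain* violate
this by construction (wide ranges are forced toward the centre), so
p-values are exactly uniform only for unconstrained
midpoint–extent pairs; the calibration test draws them independently.

## Mid-domain-effect null

Each simulation takes the full set of empirical range sizes (without
replacement = the empirical multiset itself, a randomization; with
replacement = a bootstrap resample of the same count) and places each
range's lower edge uniformly over its feasible positions inside the
domain, accumulating a richness curve; 2.5/97.5 percentiles over
`n_sim` curves form the 95% envelope.

Choices:

- **Discrete placement** (whole-band offsets, `{0 … D−r}` for an
  `r`-band range) is the default: the observed curve is
  band-discretized anyway, and integer placement admits an exact
  enumeration oracle, `E[richness_k] = Σ_s (positions covering k)/(D−r_s+1)`,
  which the tests verify by exhaustive enumeration at small D. A
  continuous-midpoint variant is available (`placement="continuous"`).
- **Closed envelope**: observed equal to a bound counts as inside
  (conservative).
- **Percentile envelopes**, not normal-theory: constrained range
  placement gives skewed per-band distributions.

Simulation is vectorized with a difference array and `bincount`, linear
in (simulations × species): 50,000 simulations of an 84-species fauna
take about two seconds.

Because richness counts are discrete and the interval closed, per-band
coverage of the 95% envelope under the null itself is slightly above
nominal (≈0.96–0.97 rather than 0.950); the calibration test allows
±0.03.

## Nestedness

All three metrics are computed on the packed matrix (packing applied
internally; NODF is invariant to it, temperature and BR depend on it).

- **NODF**: for every ordered pair of rows (and of columns) with
  strictly decreasing fill, paired nestedness = 100 × shared presences /
  fill of the poorer line; equal-fill pairs and empty poorer lines
  contribute 0. Rows/columns components are means over their pairs;
  total is the mean over all pairs combined. Verified cell-for-cell
  against brute-force loops and against vegan's `nestednodf`.
- **BR discrepancy**: after stable column packing, the number of
  absences inside each row's leftmost-`r_i` window — presences that
  would have to shift left for maximal packing.
- **Temperature T**: the isocline of perfect order is the superellipse
  `x^a + y^a = 1` on the unit square (x rightward, y downward, presence
  region containing the top-left corner), with `a` solved so the
  presence-region area `Γ(1+1/a)²/Γ(1+2/a)` equals the matrix fill
  (Brent's method). A cell is *unexpected* when it both breaks row
  order in the packed matrix (a presence after the row's first absence,
  or an absence before its last presence) and lies on the wrong side of
  the isocline. Each unexpected cell is scored by its squared relative
  distance to the isocline along the cell's diagonal of slope +1 (the
  crossing solved by vectorized bisection; the crossing function is
  strictly monotone); `T = 100·U/0.04145` (the classic normalization
  constant), clipped to [0, 100]. The row-order condition makes T
  exactly 0 for every perfectly nested packed matrix; the isocline-side
  condition keeps sparse matrices from saturating. This is a fully
  specified, reproducible variant of the temperature concept; published
  calculators use different (and not fully published) isocline
  parameterizations, so exact numeric parity with legacy T values is
  not expected — on the same matrix vegan's `nestedtemp` lands within a
  few degrees.
- **Null models**: `fixed-equiprobable` (default; each species redrawn
  into a uniform random band subset of the same row total — occurrence
  frequencies conserved, band richness free), `equiprobable-equiprobable`
  (global shuffle at fixed fill) and `fixed-fixed` (the SIM9 chain).
  P-values are one-tailed in the nested direction (NODF high,
  T and BR low), with the add-one correction; the 95% interval reported
  is the 2.5/97.5 percentile range of the null ensemble.

## C-score and SIM9

C-score = mean checkerboard units `(r_i − S)(r_j − S)` over unordered
species pairs. The SIM9 null preserves both marginals and is sampled by
a sequential-swap Markov chain: pick a random row pair and column pair;
if the 2×2 submatrix is a checkerboard, swap its diagonal. *Attempted*
swaps (including rejections) count toward burn-in and thinning: this
makes chain length deterministic and, because every attempt is a
symmetric proposal whose swap is its own inverse, the transition kernel
is symmetric and the stationary distribution uniform over the
fixed-fixed ensemble — verified by exhaustive enumeration on small
matrices. Defaults: 30,000 attempts of burn-in, one retained state per
10 attempts, 5,000 retained states; the defaults are config-exposed
since published analyses name the algorithm but not the chain settings.
Both tail probabilities are reported (upper = segregation, lower =
aggregation) with SES = (obs − null mean)/null SD.

Interpretation caveat: interval-filled range matrices score *high*
C-scores against SIM9 (contiguous ranges checkerboard the matrix), so a
positive SES on such data reflects range cohesion, not necessarily
competition.

## Jaccard / UPGMA / SIMPROF

Band similarity is Jaccard on species sets; empty bands are excluded
(J is undefined between empty sets) and reported. UPGMA runs on
`d = 1 − J` via scipy's average linkage. SIMPROF at a node compares the
observed sorted profile of pairwise band similarities with the
rank-wise mean profile of permutations in which each species' presences
are shuffled independently across the node's bands (Clarke's Type 1
scheme); `π = Σ|s_obs − s̄_null|`, and the p-value compares π against
further permuted profiles scored the same way (one permutation budget
is split 2/3 mean, 1/3 test). Within-profile similarity of two bands
left empty by a permutation is defined as 1 (indistinguishable
composition). The tree is tested top-down from the root; descent stops
at homogeneous (p > α) nodes, whose leaves form the reported groups;
nodes under 3 bands are untestable and treated as homogeneous. Default
α = 0.05.

## Poisson GLMs and AICc

Richness per band is modelled as `y_k ~ Poisson(exp(β0 + x_k·β))` via
statsmodels IRLS (tolerance 1e-8, max 100 iterations, non-convergence
raised). Predictors are z-scored by default, so coefficients are
comparable across variables spanning degrees Celsius to square
kilometres; a raw-scale option remains. The log-likelihood includes the
`log(y!)` term. `AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)` with k counting the
intercept. Both McFadden (`1 − ℓ1/ℓ0`) and Nagelkerke pseudo-R² are
reported since the common helper packages default differently.
Single-predictor ranking fits one model per column and sorts by AICc;
stepwise selection is bidirectional from the full candidate set,
scanning drops and adds in sorted name order and taking the best strict
improvement, so the result is independent of column order.

Limitation: with ~10 inert candidate predictors at n = 38, plain AICc
stepwise retains one or more noise variables in most runs (each enters
with probability ≈ 0.1; the chance that none does is ≈ 0.3). A planted
strong predictor is reliably *included*, but exact-set recovery should
not be expected from AICc stepwise at this n; the single-predictor
AICc ranking is the robust selector.

## Synthetic data: what it emulates, what it does not

`gen_ranges` emulates the empirical fauna: 84 species by default, range
extents drawn from a lognormal (log-scale μ = 0, σ = 1) truncated to
[1 degree, domain width] — right-skewed with roughly half the ranges
under two degrees — and midpoints uniform on the feasible interval
given the extent (the mid-domain null's own placement rule). Generated
gradients therefore *are* MDE-consistent by construction, which is what
makes them a null fixture; they do not emulate environmental filtering,
basin structure, or spatial aggregation of records.

`gen_nested(ρ)` builds a perfectly nested matrix (prefix rows,
non-increasing fills) at exact target density and relocates a `(1−ρ)`
fraction of presences into random vacant cells; ρ = 0 draws a uniform
random cell subset of the same exact size. NODF rises and T falls
monotonically in ρ.

`gen_cooccurrence` plants co-occurrence structure *orthogonal to the
marginals*: starting from an iid Bernoulli matrix (which, conditional
on its marginals, is a uniform fixed-fixed draw), a biased
checkerboard-swap walk pushes the C-score up (segregated) or down
(aggregated) while preserving row and column sums exactly. This is the
only way to plant a signal that a marginal-preserving null can see:
mechanisms that alter profiles directly (duplicated cluster profiles,
explicit checkerboard species pairs) mostly move the marginals, and the
fixed-fixed null absorbs — or even inverts — their apparent effect
(duplicated independent cluster profiles *raise* the C-score, because
species sharing between clusters falls below what the concentrated
column totals predict). `effect` is the probability of rejecting a
wrong-direction move: 1 = greedy extreme, 0 = unbiased walk.

`gen_glm_bands` draws Poisson counts from standardized covariates with
known coefficients; `gen_covariates` produces an 11-predictor per-band
table as latitude-correlated trends plus noise, scaled to magnitudes
realistic for the Chilean gradient (temperatures of a few °C to ~12°C,
precipitation up to ~3,000 mm, band areas of order 10⁷ km², …).

Passing tests on these fixtures demonstrate the statistics and null
models are correct and calibrated; they do not validate ecological
conclusions on real data, where record effort, basin geometry and
spatial autocorrelation (none of them modelled here) all intrude.

## Iteration budgets and determinism

Published analyses of this kind use 50,000 iterations per stochastic
stage; library defaults follow suit where cheap (Rapoport, MDE), while
the pipeline's desk-scale defaults (1,000–5,000) keep a full run under
a minute and a `--paper-scale` switch restores 50,000 everywhere. The
test-suite and acceptance-script problem sizes (200 replicates × 5,000
simulations for envelope calibration, 200 seeds × ~200 permutations for
uniformity checks, 2,000-draw null ensembles at 84 × 38) were chosen to
estimate each rate to well within the asserted tolerances. Every
stochastic routine takes an explicit integer seed; the pipeline derives
per-stage seeds from one master seed and records them in its summary.

## Known limitations

- Temperature is a documented variant; do not compare its absolute
  values against legacy calculator output (directions and null-model
  p-values are comparable).
- BR uses stable tie-breaking, not tie-order optimization; values can
  exceed the optimized discrepancy by a small amount on tied matrices.
- The SIM9 chain is exact but autocorrelated; very sparse or very full
  matrices mix slowly, and a matrix with no 2×2 checkerboard has a
  degenerate (single-state) ensemble, which is warned about.
- One-dimensional domain only: no 2-D ranges, no soft boundaries, no
  spatial autocorrelation corrections in the GLMs.
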