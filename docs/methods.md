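# Methods

`idiodyn` analyses one person's multivariate intensive longitudinal series —
typically a handful of bounded self-report items (e.g. six motivation
questions on a 0–100 visual-analog scale) answered once or twice a day for
a hundred or more occasions.  The guiding view is that such a series is the
trace of a complex adaptive system: the interesting structure is which
multivariate configurations ("profiles") recur, how the system moves
between them, and whether that movement is compatible with a linear
stochastic process.  This note records the models, formulas, defaults and
design choices, and what the synthetic benchmarks do and do not show.

## Recurrence quantification

Each complete occasion is a point in V-dimensional profile space; no delay
embedding is used — the observed items are taken as the state vector.
Occasions i and j recur when `d(x_i, x_j) <= eps` (Euclidean by default;
Manhattan and Chebyshev selectable).  Profiles may be raw scores or first
differences ("change profiles", useful when scale usage drifts), optionally
z-standardised per variable.

**Radius.**  No physically meaningful radius exists for questionnaire
scales, so `eps` is calibrated to a target recurrence rate — the standard
RQA practice.  The default target RR is 0.05; `eps` is the smallest
eligible-distance quantile whose achieved RR reaches the target, so with
distinct distances `|achieved − target| <= 1/n_eligible`.

**Theiler window.**  A band of half-width 1 around the main diagonal is
excluded everywhere (recurrence counting, RQA, network edges), so trivial
self/neighbour matches never count as recurrences.

**RQA measures.**  Classical line-census definitions with `l_min = 2`:
DET = fraction of recurrent points on diagonal lines of length ≥ l_min
(upper triangle; the matrix is symmetric), LAM the vertical-line analogue,
`mean_line` the mean length of counted diagonal lines.  DET/LAM are
reported missing when RR = 0.  Note a finite-size edge effect: a fully
recurrent (constant) series has DET slightly below 1 because the corner
diagonal has length 1; this is the standard census behaviour and the
brute-force oracle in the test suite reproduces it exactly.

**Network and categorisation.**  The recurrence matrix doubles as a
weighted undirected network over occasions with edge similarity
`w = 1 − d/eps` (an exponential kernel is selectable).  Strength centrality
is the incident-weight sum.  Profile classes are found by a greedy hub
rule: the strongest node and its neighbours form class 1; each subsequent
hub is the strongest unlabelled node not adjacent to any earlier hub (k = 4
classes by default); remaining connected nodes are "uncategorised",
isolated nodes "unique".  Ties in strength break toward the earlier
occasion, making the labelling deterministic and insertion-order
invariant.  A known failure mode, visible in roughly one in twenty planted
two-regime runs: a strong node of an already-labelled regime that happens
not to be adjacent to its hub can seed a spurious micro-class.  We keep the
rule as specified rather than patching it, and summarise recovery by the
mean over classes and seeds.

## Transition model

Labels of consecutive occasions (only temporally adjacent ones — gaps from
excluded incomplete occasions are skipped) are tabulated into a count
matrix with **columns as source** and rows as destination; percentages are
column-normalised and kept at full precision, rounding only at display.
The asymmetry index `sum|C − C^T| / (2 · sum offdiag C)` is 0 for fully
reciprocated flows (what a linear system should produce in expectation) and
1 for one-way flows; it is undefined without off-diagonal transitions.

## Surrogate testing

The null hypothesis is a rescaled Gaussian linear process.  Methods:
shuffle (exact permutation), phase randomisation (exact periodogram), and
IAAFT (exact value multiset, approximate spectrum; iteration cap 100 or
spectrum change < 1e-6, final amplitude-adjustment step last).
Multivariate series get one shared phase draw per surrogate across
variables, preserving cross-correlations.  The default statistic is DET at
fixed recurrence rate, recalibrated per series so observed and surrogate
series face identical settings; the default side is "greater" (nonlinear
structure inflates determinism).  The rank p-value
`(1 + #{s >= obs})/(n + 1)` is exact and floored at `1/(n+1)`, hence the
minimum ensemble size 19 at alpha = 0.05, and rejection uses `p <= alpha`.

Calibration and power are measured, not assumed: on Gaussian AR(1) series
(phi = 0.6, T = 128, 99 surrogates, 200 replicates) the type-I error sits
near 5%; on logistic-map series (r = 4, T = 512, 50 seeds) power is ~100%.

## Time-varying VAR and early warnings

TV-VAR(1) uses Gaussian-kernel weighted least squares at each of 50 grid
times (default bandwidth 10% of the time range).  The estimator errors out
when the local effective sample size drops below V + 2, with the advice to
enlarge the bandwidth.  With a very large bandwidth it reproduces the
global VAR(1) fit to numerical precision.  Lag is fixed at 1; longer lags
are out of scope.  Snapshot networks threshold `|beta|` (default 0.1) and
carry a +/− sign attribute.

The assumption battery runs three per-variable checks, each calibrated by
simulation in the test suite: *level* (split-half Welch t on means plus
Levene on variances, Bonferroni at alpha/2 each), *trend* (whole-series
slope ≠ 0 OR half-slope difference ≠ 0, Bonferroni at alpha/2 each — the
union is deliberate: a constant global trend leaves half-slopes equal,
while a sign-flipping trend can cancel the global slope), and *linearity*
(the surrogate DET test).  These checks assume approximately independent
errors for their nominal level; strong autocorrelation inflates the level
and trend checks' size, which is why their calibration is stated for white
noise only.

Rolling early-warning indicators use a sliding window (default 14
occasions, about a week at two prompts/day): lag-1 autocorrelation
(missing for constant windows), variance, and dynamic complexity
`C = F · D`, where F is the mean absolute successive difference scaled by
the scale range (1 under maximal min/max alternation) and D is one minus
the normalised total-variation distance between the windowed value
histogram (10 bins over the scale) and uniformity (0 for a constant
window, 1 for a perfectly uniform spread).  Both factors live in [0, 1],
so C does too; unbounded variables fall back to their observed range.

The generalized logistic curve
`y(t) = floor + (ceiling − floor)/(1 + exp(−growth (t − midpoint)))` is fit
by bounded least squares (floor/ceiling within observed range ± 20%) from
8 deterministic starts (two growth magnitudes × two signs × two
midpoints).  The parameterisation is symmetric under
`(floor, ceiling, growth) → (ceiling, floor, −growth)`; fits are
normalised to floor ≤ ceiling, so decreasing curves carry negative growth.
Constant series return a degenerate fit with growth reported missing.

## Synthetic data: what it emulates, what it does not

The generator plants exactly the structure the analysis claims to detect:
a hidden-Markov switch among K mean profiles (column-stochastic transition
matrix), Gaussian or right-skewed centred-lognormal noise, clipping to the
bounded scale (clips are counted and logged — resampling would distort the
planted noise), piecewise-linear trends and step level shifts, and sparse
subsampling.  The default demo scenario mirrors a single-participant EMA
study: V = 6 items on a 0–100 scale, T = 122 occasions, K = 4 attractor
profiles (minimum pairwise separation 2 × noise SD per variable, i.e.
neither trivially separable nor hopeless) plus a noisier mid-scale
background state, stay probability 0.6, noise SD 10.

Profile geometry comes from rescaled truncated Hadamard rows, so the
*minimum* pairwise distance is controlled exactly.  Recovery analyses use
a target recurrence rate of `0.9/K`: with K roughly balanced regimes the
within-regime pair fraction is about 1/K, and calibrating just below it
captures within-regime recurrences without bridging regimes.

What passing these benchmarks does *not* show: real EMA data have no
ground-truth states, their regimes are not spherical Gaussian clouds, item
noise is heteroscedastic and serially dependent, and missingness is
informative.  The synthetic results certify the machinery (the estimators
recover what was planted, the tests hold their error rates under the
null), not the substantive interpretation of any particular person's data.

## Problem sizes and numerical choices

The verification experiments run at desk scale: planted-recovery at
T = 1000 (K = 2) and T = 500 (K = 4) over 20 seeds; surrogate calibration
with 200 replicates of T = 128 and power with 50 seeds of T = 512, 99
surrogates each; battery growth at T = 50 vs 500 over 100 seeds with
19-surrogate linearity checks.  Distances use `scipy.spatial.distance.pdist`;
line censuses are vectorised run-length scans; categorisation runs directly
on the recurrence/weight matrices (the networkx graph is an export view).
Degenerate inputs are refused loudly rather than patched: identical
distances (no quantile radius), all-constant variables under
z-standardisation, unstable VAR coefficients, non-stochastic transition
matrices.

## Known limitations

- Categorisation quality degrades when regime occupancies are very
  unbalanced (the fixed-RR heuristic assumes rough balance).
- Cross-recurrence between two series, joint recurrence, lag > 1 models,
  multilevel pooling across persons and any intervention-delivery logic
  are out of scope.
- The battery's level/trend checks are calibrated for serially independent
  errors; for strongly autocorrelated series their p-values are
  anti-conservative.
- Surrogate p-values across a battery of variables are reported raw, with
  no multiple-testing control.
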