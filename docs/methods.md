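# Methods

## Agreement coefficients

For a q x q table of joint probabilities `p_ij` (rater A on rows, rater B on
columns), all five coefficients share the chance-corrected form
`delta = (p_a - p_e) / (1 - p_e)` with weighted observed agreement
`p_a = sum_ij w_ij p_ij`. They differ only in the chance term `p_e`
(`pi_i = (p_i+ + p_+i)/2` are the averaged marginals, `T_w = sum_ij w_ij`):

| measure | p_e | marginal assumption |
|---|---|---|
| Cohen's kappa | `sum w_ij p_i+ p_+j` | conditions on both raters' margins |
| Scott's pi | `sum w_ij pi_i pi_j` | common marginal distribution |
| Krippendorff's alpha | as Scott | common margins, finite-sample corrected |
| Gwet's AC2 | `T_w / (q(q-1)) * sum pi_i (1 - pi_i)` | chance rating uniform over "hard" subjects |
| Brennan–Prediger S | `T_w / q^2` | uniform chance rating |

Krippendorff's alpha applies the two-rater finite-sample correction to the
observed agreement, `p_a' = p_a (1 - 1/(2N)) + 1/(2N)`, so `alpha >= pi`
with the gap vanishing as N grows; on a probability table without an N the
asymptotic value (equal to pi) is returned. Any coefficient is exactly 1
when `p_a = 1`; `p_e = 1` with `p_a < 1` raises an undefined-coefficient
error. User-facing values are rounded half-even to 3 decimals; computation
is full precision. Because AC2 and S build `p_e` without rewarding marginal
concentration, they are the least sensitive to the marginal distortion a
grey zone causes — the package's cross-table CV summary (sample standard
deviation over mean, ddof = 1) quantifies exactly this.

## Weight matrices

Categories are scored 1..q (custom strictly increasing scores are accepted;
the ordinal scheme uses ranks only). For distance d = |i - j|:
unweighted `1{d=0}`; linear `1 - d/(q-1)`; quadratic `1 - d^2/(q-1)^2`;
radical `1 - sqrt(d)/sqrt(q-1)`; ordinal `1 - C(d+1,2)/C(q,2)` (the number
of category pairs the two ratings span, normalised by the total number of
pairs). All are symmetric, unit-diagonal, in [0, 1] and non-increasing in
d, with quadratic >= linear >= radical off the diagonal.

## Latent-variable table generation

Ordinal ratings are modelled as a discretized standard bivariate normal
pair with correlation rho; cell probabilities are bivariate-normal
rectangle probabilities between consecutive cutoffs, computed from the
distribution function (SciPy's bivariate CDF, accurate to ~1e-12) rather
than by simulating per-subject latent draws — statistically identical and
exact for the population table, which also serves as the "true" table for
population coefficients. Observed tables are single multinomial draws of
size N over the q^2 cells from a seeded generator.

Cutoffs encode the marginal structure. Balanced: normal quantiles k/q
(equal category probabilities). The two unbalanced structures are package
defaults, not pinned by an external source: slightly unbalanced uses
category probabilities proportional to 1..q, heavily unbalanced
proportional to 2^(i-1); both are overridable by any strictly increasing
quantile vector in (0, 1). Agreement levels map rho in {0.1, 0.6, 0.9} to
low / medium / high.

## Grey-zone injection and matched-truth searches

A grey zone at category g of the column rater moves a fraction `lambda1` of
the probability in cell (g-1, g-1) into (g-1, g) and `lambda2` of
(g+1, g+1) into (g+1, g). Sources are decremented, so total mass and all
row margins are conserved while column g's margin inflates — a rater who
"rates more" on g. Movement never jumps more than one category (the
ordinal scale discretizes a continuous latent trait), boundary categories
use their single neighbour, and only one grey zone is modelled. The default
grey category is the mid-category ceil(q/2).

Both searches target a prescribed *true* agreement so that simulations with
and without a grey zone share the same truth. Convergence is declared when
the mean absolute difference between reference and achieved coefficients
over a measure set is at most epsilon = 0.01; by default the CP search uses
all 25 measure x scheme pairs, each compared with its own reference value
on the start table.

**PA search** starts from the diagonal perfect-agreement table for the
given structure. The achieved agreement decreases continuously from 1 along
the symmetric ray `lambda1 = lambda2`, so a bisection finds the target; a
coarse 0.05 grid with local refinement (tie-break: smallest
`lambda1 + lambda2`, least distortion) covers asymmetric cases. Because
full migration leaves a floor on reachable agreement (0.6 for a balanced
6 x 6 with g = 3 under Cohen/unweighted), lower targets raise an
unreachable-target error. The PA default measure set is the single pair
(Cohen, unweighted): with a scalar target, averaging |target - kappa_i|
over structurally different measures is infeasible below any useful
epsilon, since the measures legitimately disagree on non-perfect tables.

**CP search** starts from a given joint table (typically the latent-model
output). The grey shift (which in CP may also drain the off-diagonal cells
(g-1, g+1) and (g+1, g-1) into column g) lowers agreement; compensating
transfers of size `gamma * p_ii` (gamma = 0.01) between adjacent diagonal
cells adjust the chance terms back. The compensation is greedy and
target-seeking: at each step the adjacent-diagonal transfer (either
direction, any position) that most reduces the criterion is applied,
re-applied while it helps, and the search stops as soon as the criterion
reaches epsilon. Migration rates are tried on a descending ladder from 0.3
(about the migration rate visible in the motivating example) down to 0.01,
each rung receiving an equal share of the 10,000-evaluation budget; the
first rung that converges wins, so the result carries the strongest grey
zone compatible with matched truth. Smaller tables and higher agreement
admit smaller rates, because the irreducible part of the criterion — the
Brennan–Prediger pairs, whose chance term no diagonal transfer can move —
grows with the migrated mass. Non-convergence is flagged on the returned
result, never silent, and every converged result re-verifies from scratch.

## Paired Monte Carlo study

For each design triple (structure, q, agreement level) the latent table `p`
and its grey-zone counterpart `p_hat` are built once and shared by all 25
measure/weight scenarios. Each scenario draws r independent tables of size
n from `p` (simulation I) and, from an independently seeded stream, r
tables from `p_hat` (simulation II), estimates its coefficient on every
table, and summarises accuracy against the population coefficient of `p`:
MAE, MSE and MAPE (MAPE is reported missing when the true coefficient is
0). Replicates whose coefficient is undefined (degenerate margins at small
n) are dropped and counted; effective replication counts are reported.
Per-scenario seeds derive deterministically from one master seed, and two
runs with the same master seed are identical. The default r is 1000; the
shipped verification runs use r = 200 and a reduced factor sub-grid
({BL, UB1} x {n = 200, 1000} x {q = 3, 5} for Cohen/linear) so the whole
study completes in seconds; the full 3 x 5 x 4 x 3 x 5 x 5 = 4500-scenario
grid is expressible through the same configuration surface.

What the generator emulates — and does not. The latent-normal model yields
symmetric, unimodal agreement tables with margin structure controlled
solely by the cutoffs; real rating data may show rater drift, subject
heterogeneity, or multiple ambiguous category pairs, none of which are
modelled. The grey zone is a single, one-category-wide, one-rater effect.
Passing checks therefore demonstrate the behaviour of the coefficients
under this stylised mechanism, not under arbitrary real-world disagreement
patterns.

## Numerical choices and degenerate inputs

- Probability tables validate to sum 1 within 1e-8 and renormalise exactly;
  joint probabilities from the bivariate CDF are accurate to ~1e-10.
- Weight matrices are cached per (scheme, q) and exposed read-only.
- Coefficient equality between a counts table and its normalized
  probability table holds to 1e-12 (except Krippendorff, which needs N).
- A table whose entire mass sits in one cell has `p_a = 1` and returns 1
  for every measure; empty tables, q < 2, |rho| >= 1, non-monotone
  cutoffs, and out-of-range rates or indices raise typed errors.
- Search determinism: no randomness anywhere in the searches; ladder order,
  greedy tie-breaking (first-found best step) and bisection depth are fixed.

## Fixture provenance

The packaged worked example ships in two scenario realizations: the
marginal-consistent reconstructions (N = 85) that reproduce the published
Cohen's kappa comparisons, and "additive" variants (N = 94, moved counts
added without decrementing sources) that reproduce the published
per-measure sensitivity analysis and its CV rows. The printed source tables
mark the scenario cells inconsistently; `fixtures.py` documents the exact
cell edits of both reconstructions.

## Known limitations

- Two raters only; no standard errors or confidence intervals for the
  coefficients.
- The unbalanced cutoff quantile sets are package conventions (documented
  above), so absolute results under UB1/UB2 are not comparable across
  implementations that choose different skews.
- The grey-zone magnitude selected by the CP search is the largest the
  matched-truth constraint admits; other defensible selection rules (e.g.
  least distortion) exist and would yield weaker grey zones.
- MAPE is unstable for true coefficients near 0 (low agreement with
  unweighted schemes).
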