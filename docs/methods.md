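# Methods notes

## Scope and model

The package implements the statistics of a coculture bioprocess
optimization: a central composite design (CCD) over three coded factors —
inoculation ratio A (% of the ester-producing strain), induction time B
(h), inducer concentration C (mM IPTG) — a polynomial response-surface
model selected from the cubic monomial basis, ANOVA validation against
replicate pure error, and single- and multi-response numeric optimization
over the coded design region. Wet-lab concerns (strain construction,
chromatography chemistry, bioreactor control) are out of scope; the
package starts from design/response tables and ends at predicted optima.

## Designs and coding

Coded units are linear and symmetric: natural = center + step · coded.
A full CCD probes each factor at {−α, −1, 0, +1, +α}; the axial distance
defaults to the rotatable value α = 2^(k/4) (≈ 1.682 for k = 3) and is
user-overridable, since the study's natural-unit level table is not
available and rotatability is the standard default in that situation.
Natural-unit defaults (centers 50 %, 2.5 h, 0.23 mM; steps 15 %, 1 h,
0.1 mM) are configuration, not constants: the centers are the stated
center point, the steps are chosen to span realistic laboratory ranges at
the axial points.

Run composition is deterministic; only the run order is randomized, by a
single seeded permutation, so a design is fully reproducible from its
seed. The default two-block split mirrors a two-day campaign: factorial
replicate 1 and half the centers on day 1; axial points, the second
factorial replicate and the remaining centers on day 2. Any other
assignment can be had via round-robin mode or by editing the design file.

## Polynomial models, hierarchy, and aliasing

Candidate terms are all monomials of total degree ≤ 3 (degree > 3 is an
explicit scope limit). Fitting is ordinary least squares (statsmodels
under the hood); stepwise selection uses partial-F p-values with
alpha_enter = alpha_remove = 0.10, the common default in DoE software.
Hierarchy (divisor closure: A²B forces A², AB, A, B) is repaired after
selection terminates rather than enforced during the search — simpler,
and equivalent for the designs considered here. Backward elimination with
alpha_remove ≥ 1 removes every removable term (p-values never reach 1
exactly), giving the intercept-only model.

A CCD cannot estimate the full 20-term cubic basis: mixed cubic monomials
are partially aliased with lower-order terms (for example BC² agrees with
B on factorial points and vanishes elsewhere, so it lies in the span of B
and B³). `estimable_subset` resolves this deterministically by walking
terms in canonical order (degree, then first-factor-major) and dropping
any column that does not increase the model-matrix rank, along with its
descendants; both selection routines use it, which is what allows
backward elimination to start from "the" cubic model on a CCD.

Block effects are excluded by default (the reference production model has
no block term). When enabled they enter as sum-to-zero fixed offsets:
reported per block, absorbed into the fit in-sample, excluded from
prediction at new points (the intercept then represents the average
block).

## ANOVA and predictive statistics

Pure error pools within-group deviations over runs with identical coded
levels (matching to 1e−9); lack of fit is the residual remainder, tested
by F = MS_lof / MS_pe. Per-term rows carry partial (drop-one) sums of
squares against the residual mean square. SS and df additivity
(model + residual = total; lack-of-fit + pure error = residual) are
asserted in tests at 1e−8 relative tolerance. PRESS uses the leverage
shortcut Σ(eᵢ/(1−hᵢᵢ))², which equals brute-force leave-one-out
refitting (verified in tests up to 40-run designs); predicted
R² = 1 − PRESS/SS_total. Degenerate inputs: a constant response reports
R² = 0 by convention; a saturated fit (any leverage = 1) raises rather
than reporting an undefined leave-one-out statistic; ANOVA with zero
residual df raises; designs without replicates omit the lack-of-fit rows
with a warning.

## Optimization

Single-response optima use multistart local optimization (L-BFGS-B with
box bounds on the cube; SLSQP with a norm constraint on the sphere) from
the origin plus seeded uniform draws in the region, 50 restarts by
default, tolerance 1e−9; value ties are broken toward the smaller coded
norm, and infeasible SLSQP terminations are discarded (a cubic is
unbounded outside the region). Tests cross-check against dense grid
search. The default region is the factorial cube [−1, 1]³; the reference
optimum is interior, so cube and sphere agree there.

Desirability goals are one-sided maximize transforms with shape r = 1 and
equal weights by default; the global score is the weighted geometric mean
with no epsilon flooring, so any fully undesirable response annihilates D
(a landscape whose best D is 0 is flagged degenerate). Because the
objective is flat wherever a response saturates its goal, the multistart
adds a deterministic 5-per-axis grid of starting points.

## Synthetic ground truth

The ester-production truth is the 13-coefficient reduced cubic surface
(intercept 23.91 A.U.); its cube-constrained maximum is 24.287 A.U. at
coded (−0.21, −0.09, 0.10). Replicate noise defaults to σ = 2.3 A.U.,
the reported center-point scatter. The cell-density (OD₆₀₀) surface has
no published coefficients, so the default is a synthetic concave
surrogate, Y₂ = 8.5 − 2A² − 2B² − 2C², centered near the reported
predicted OD of 8.48 — adequate for exercising the multiresponse
machinery, but the study's joint-optimum value D = 0.79 is therefore not
a reproduction target. Block offsets default to zero. Each response draws
from an independent seeded substream, so tables are byte-reproducible per
seed and adding a response never perturbs another's draws.

The growth simulator is deliberately minimal — per-strain lag followed by
exponential growth, with a shared hard cap standing in for substrate
exhaustion — because only rates (0.71 and 0.25 h⁻¹), the ~15 h lag and
the takeover outcomes are reported, not a mechanistic model. At the cap
crossing the final step is shortened by a bisection sub-step so total OD
lands exactly on the cap. It reproduces the qualitative fed-batch
behaviour (fast-strain takeover at equal inocula; monotone decrease of
the fast fraction with increasing slow-strain inoculum) and is not a
substrate-explicit fed-batch model: no feeding, no Monod kinetics, no
growth coupling to production.

What passing simulation-backed tests shows: the estimators and optimizers
recover known ground truth at realistic noise under the stated layout.
What it does not show: robustness to non-Gaussian measurement error,
day-to-day drift beyond additive block shifts, or model misspecification
of real fermentations.

## Test problem sizes

Monte-Carlo checks use 200 fits for confidence-interval coverage and
selection frequency, 1000 simulations for the lack-of-fit type-I error
(exact F-test, so ≈ 5% ± 2% is comfortably resolved), and 100 seeds for
pipeline-level optimum recovery — sizes at which the binomial standard
errors are small against the asserted margins while the whole suite stays
fast. Optimum-value recovery at σ = 1.0 is tight (within 1.5 A.U. of 24.3
in ≥ 90% of seeds); optimum *location* is intrinsically loose because the
surface is flat near its peak (curvature ≈ −10 A.U./unit², so a 0.3-unit
shift costs ~0.5 A.U., below noise resolution) — the tests therefore
assert the median coded distance, not a tight per-seed bound.

## Known limitations

- Only one-sided maximize desirability is implemented; target-is-best and
  minimize transforms are an extension point.
- Cubic is the hard ceiling of the term basis.
- Natural-unit conversions are only as good as the configured
  center/step values.
- The OD₆₀₀ surrogate is synthetic; conclusions about the real
  cell-density response require the actual fitted model.
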