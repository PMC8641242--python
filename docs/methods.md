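# Methods

## Model

The package computes information quantities attached to a single act of
perception. A generative model `p(x, θ) = p(x|θ) p(θ)` links sensory data
`x` to causes `θ`; a recognition density `q(θ)` approximates the Bayesian
posterior. All quantities are reported in nats.

Two settings are implemented:

* **Finite discrete models** (`collative.discrete`): prior vector plus a
  likelihood matrix over a finite sensory alphabet. Every expectation is
  an exact finite sum, so the decomposition identities
  `F = KL(q‖post) + surprisal = KL(q‖prior) + ⟨−ln p(x|θ)⟩_q` hold to
  round-off. This module doubles as the brute-force oracle for the
  Gaussian closed forms (a finely discretised Gaussian model is itself a
  valid discrete model; discretising both axes with step h shifts every
  density-based term by −ln h, which the oracle tests account for).
* **Conjugate Gaussian models** (`collative.gaussian`, `.arousal`):
  source `N(μ, σ²)`, prior `N(η, s_p)`, known sensory variance `s_l`
  treated as an estimate of σ². The posterior after n samples is
  `N((n s_p x̄ + s_l η)/X, s_p s_l/X)` with `X = n s_p + s_l`.

Causes are assumed static: no drift or dynamics parameters exist anywhere
in the API.

## Closed-form coefficients

The three arousal quantities are exact quadratics in the prediction error
`δ = x̄ − η` (positive δ means data above the prior expectation; all forms
are even in δ). The implemented coefficients are re-derived from first
principles — the gain from the closed-form Gaussian KL of the conjugate
update, the uncertainty from the posterior expectation of the joint
negative log-likelihood — rather than transcribed, and are locked in by
three independent oracle tests (KL closed form, Monte-Carlo posterior
expectation, discretised free energy) plus the exact additivity
`A_F = A_G + A_U`, `B_F = B_G + B_U`.

The staged (two-batch) forms treat the belief after n samples as the prior
for m further samples *from the same source*, so x̄ and S keep their
whole-run meaning. In the staged uncertainty, the second bracket term is
`s_p/((n+m)s_p + s_l)`: this is what `⟨(μ − x̄)²⟩` under the staged
posterior produces (its variance divided by `s_l`), consistent with the
`s_p/X` term of the single-stage form, to which the staged form reduces
exactly at n = 0. Both candidate readings of that term vanish in the
large-n limit, so the limits are unaffected; the Monte-Carlo oracle test
discriminates in favour of the implemented one.

Limits: as n → ∞ the gain vanishes and the uncertainty tends to
`m · H(s_l)` with `H(σ²) = ½(ln 2πσ² + 1)` — uncertainty becomes
perceived complexity. The large-n gain is evaluated with `log1p` so the
`−ln(X/Y) + X/Y − 1` term stays accurate (≈ t²/2 for t = −m s_p/Y) instead
of cancelling catastrophically.

## Conventions and degenerate inputs

* Sample variance S uses the maximum-likelihood divisor n; the expansion
  `n(μ − x̄)² + nS` of the joint log-likelihood is an identity only under
  that convention. `n = 0` summaries are legal and make the posterior
  update a no-op.
* `0 · ln 0 = 0` in every entropy/KL sum. Recognition mass on outcomes of
  zero joint probability yields `+inf` (a value, not an exception), so
  bound properties remain assertable on degenerate inputs; constructor
  validation catches the common errors (negative entries, rows not
  summing to one — reported with the offending row named).
* Probability vectors are accepted when they sum to 1 within 1e-9 and are
  renormalised exactly, so downstream identities see true simplex points.
* Random discrete instances draw priors and likelihood rows flat on the
  simplex (Dirichlet(1)) from a caller-supplied seeded generator.

## Sensitivity analysis

All ten non-trivial derivatives of the six coefficients with respect to
`s_p` and `s_l` are implemented as the exact derivatives of the
implemented coefficients and verified against central finite differences
(relative error < 1e-6 over a log-spaced grid).

One genuinely open choice: `B_U` and `B_F` contain the data-fit ratio
`S/s_l`. Because the model reads `s_l` as an estimate of the source
variance (`S ≃ s_l` after enough data), the default sensory-variance
derivatives hold that *ratio* fixed — S rides along with `s_l` — which
yields the unconditional signs `∂B_U/∂s_l > 0` and `∂B_F/∂s_l > 0`. The
plain partials at constant S are available via
`couple_sample_variance=False`; they flip sign when `S > s_l − s_p s_l²/X²`.
The finite-difference tests check both conventions, perturbing S
proportionally in the coupled one.

Known tensions in the source material, resolved in favour of the
equations: the qualitative sensory-variance table attaches the condition
`n s_p + s_l ≥ 1` to the uncertainty intercept and `s_p > s_l` to the gain
intercept, but the exact derivatives make the uncertainty intercept rise
and the gain intercept fall unconditionally (so the table is matched
wherever its conditions hold); and the prose claim that small prediction
errors with higher prior variance mean *smaller* free energy contradicts
`∂B_F/∂s_p > 0`, which implies the opposite at δ = 0 — the implementation
follows the derivative. `sign_classification` therefore reports the
effect implied by the exact derivative together with the tabulated
condition and whether it holds.

Crossovers: two forms of the same quantity cross at
`δ* = sqrt((B_b − B_a)/(A_a − A_b))` when that ratio is positive and
finite; parallel (equal A) and nested (no positive root) pairs return no
crossing, and identical forms are flagged degenerate. Interaction
detection defaults to the window δ ∈ (0, 4] (401-point grid in sweeps),
the range over which the model's two predicted interaction patterns are
examined: a prior-variance sweep (s_l = 0.5, s_p ∈ [1, 5]) crosses in all
three quantities; a sensory-variance sweep (s_p = 3, s_l ∈ [1, 5])
crosses only in free energy, at δ* ≈ 2.3548 for s_l = 1 vs 5. The sweeps
default to n = 1 and S = s_l; the source material does not state the
sample count behind its curves, so n = 1 is a documented assumption, and
both defaults are configurable.

## Simulations

`StimulusSource` draws Gaussian samples under a mandatory seed
(`numpy.random.default_rng`); identical seed, identical output.
`bayesian_trajectory` alternates perception and learning: per step it
draws a batch of m samples, computes the staged gain/uncertainty of that
batch against the belief accumulated so far, then performs the conjugate
update. It keeps running sufficient statistics (count, sum, sum of
squares) rather than raw samples; equality with batch updating is
guaranteed by conjugacy and tested. δ and S therefore always refer to the
original prior mean and the full sample run, matching the staged closed
forms.

What the generator emulates — and does not: a stationary Gaussian source
observed under exactly-known sensory variance, the regime in which the
convergence statements are exact. Real stimuli are non-Gaussian,
non-stationary, and observed with misestimated precision; passing tests
show the *identities and limits* are computed correctly, not that real
arousal data will follow them. One consequence surfaces even inside the
model: when the source sits near the prior mean, the running estimate of
S approaches σ² from below and the measured uncertainty creeps *up*
toward the entropy floor (the `+1/n²` ramp of the `S/s_l` term slightly
outweighs the `−s_p²/Y²` decay of the prior term). The
uncertainty-reduction property is therefore demonstrated in a
novel-stimulus condition — initial prediction error δ = 3 with prior
`N(0, 3)`, i.e. δ² > s_p, where the belief-driven decrease dominates —
and asserted on seed-averaged runs (20 seeds) with per-step slack of four
Monte-Carlo standard errors.

Problem sizes: convergence runs use cumulative n = 10⁵ (batches of 1 for
the single-seed check, 100 × 1,000 steps across 20 seeds elsewhere);
convergence tolerances (terminal gain < 10⁻⁴, |U/m − H| < 10⁻²) are
package choices — the theory states only the limits — sized so the
sampling noise of S at n = 10⁵ (sd ≈ σ²√(2/n)) sits well inside them.

## Interfaces

Discrete models round-trip through a JSON schema
(`causes/symbols/prior/likelihood`); sample vectors load from
single-column CSV (header optional); sweep and trajectory tables are
written as CSV with 12 significant digits and fixed column order, so
identical config + seed reproduces byte-identical files. The CLI
(`collative`) is a thin layer over these functions; configs are JSON or
YAML with an explicit mandatory seed, and runs log seed, parameters and
package version to stderr.

## Limitations

Only known-variance, univariate Gaussian conjugacy (no Normal-Inverse-
Gamma, no multivariate case); no continuous-θ variational optimisation
beyond exact enumeration on grids; no second-order sensitivities; the
hedonic (Wundt-curve) valence function that consumes arousal potential is
out of scope, as are neurophysiological validation and active-inference
extensions.
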