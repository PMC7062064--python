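# Methods

## Model

Inter-event times τ₁,…,τₙ > 0 of one individual are modelled as i.i.d. draws
from an exponential mixture

p(τ; π, μ) = Σⱼ (πⱼ/μⱼ) e^{−τ/μⱼ},  j = 1…k,

the stationary IET distribution of a process that switches between k
Poissonian states.  The model assumes independence between successive IETs
and stationarity over the recording; circadian structure is handled only
crudely, by optionally excluding day-spanning gaps during preprocessing.

## Estimation

The EM algorithm alternates responsibilities
γᵢⱼ ∝ πⱼ p(τᵢ; μⱼ) (E step, computed in log space with a log-sum-exp
reduction so that means spanning several orders of magnitude cannot
underflow) and the weighted-mean updates πⱼ ← mean γ·ⱼ,
μⱼ ← Σγᵢⱼτᵢ/Σγᵢⱼ (M step).  Initialisation: uniform weights and
log₁₀ μⱼ⁽⁰⁾ ~ U[log₁₀ τ_min, log₁₀ τ_max], which covers the data's dynamic
range while placing most initial means at small values.

Because EM only finds local optima, fits are restarted 10 times by default
(sub-seed = master seed + restart index, fully reproducible) and the restart
maximising the *joint* likelihood p(τ, ẑ; θ̂) of the completed model is kept;
the same restart supplies the marginal likelihood used by AIC/BIC.  The runs
are executed as one vectorised batch; converged runs are frozen, so each
trajectory is identical to a standalone run.

Stopping: relative change of the marginal log-likelihood below `tol = 1e-10`
or `max_iter = 1000` iterations, both configurable.  A convergence-based stop
was preferred to a fixed iteration count because it dominates any fixed
budget on easy data and caps hard cases.  Components whose weight falls below
1e−12, or whose mean falls below 1e−12·τ_min, are frozen out of the E step;
the completion's k\* mechanism then discards them.

Latent completion: ẑᵢ = argmax γᵢⱼ at the final parameters (ties to the
lowest component index, for determinism), then the exact joint MLE
π̂ⱼ = nⱼ/n, μ̂ⱼ = within-group mean.  Components with nⱼ = 0 are dropped and
k\* counts the rest.

## Codelengths

All codelengths are in nats.  For a single exponential the NML codelength is
L_NML = n log μ̂ + n log n − log Γ(n) + log(m_max − m_min), with the MLE
constrained to [e^{m_min}, e^{m_max}] to keep the complexity integral finite.

For the completed mixture, the parametric complexity C_EMM(n, k\*) is
evaluated by the exact recursion over splits of n between a new component and
the rest (conventions 0⁰ = 1 and C_EMM(0, ·) = 1 make the boundary terms
well-defined; both conventions are validated against brute-force enumeration
over compositions in the tests).  The recursion is carried entirely in log
space — (n/e)ⁿ overflows linear arithmetic near n ≈ 700 — with lgamma-based
binomial coefficients, and level arrays are memoised per (n, m-range) so a
selection sweep over many k values pays the O(n²) cost once per level.

The multinomial complexity C_mult(n, k\*) for the DNML's latent part uses the
closed binomial sum at k = 2 and the linear three-term recursion above, also
in log space.

Mean bounds are the integers m′_min = ⌊log min μ̂ⱼ⌋ and
m′_max = ⌈log max μ̂ⱼ⌉.  When the two coincide (a single mean that is an
exact power of e) the upper bound is widened by one, since a zero-width range
would give the codelength −∞; in practice this occurs only on contrived
inputs.  The bounds themselves are encoded with a universal prefix code for
signed integers: one sign bit plus Rissanen's log\* code for |m| + 1, with
normaliser c₀ ≈ 2.865064.  Iterated logarithms are taken base 2 and the
result converted to nats, which preserves the Kraft inequality exactly.  Any
valid prefix code would do — the term is shared across candidate k and moves
only mildly with the fitted means — so selection is insensitive to this
choice, but scores could shift by O(1) nats under a different integer code.

Selection minimises each criterion over a candidate grid of k (default
1–10, 20, 50, 100), with ties broken toward smaller k: a larger requested k
whose completion has the same k\* typically encodes the same effective
distribution.

## Power-law baselines

The Pareto MLE anchors b̂ = min τᵢ and uses the Hill-type exponent
â = 1 + 1/(mean log τᵢ − log b̂); all-equal samples are rejected as
degenerate.  The tail fit follows the Clauset-style continuous-data dialect:
candidate cut-offs are the unique data values with at least two tail points,
the exponent is the Hill estimate on the tail, and the cut-off minimising the
Kolmogorov–Smirnov distance between tail empirical CDF and fitted Pareto CDF
wins (ties to the smaller cut-off; no small-tail penalty).  Dialect details
(candidate pruning, discrete handling) vary between public implementations,
so cut-offs on real data may differ slightly from other tools.

In likelihood comparisons on truncated point sets (all points, τ > min τ,
τ ≥ b̂), mixture and Pareto densities are deliberately *not* renormalised:
the mixture pays for mass it assigns below the cut-off, which is the honest
comparison when the tail fit is allowed to discard small values.  The tail
fit's survival curve is rescaled by n′/n when displayed against the full
sample.

## Synthetic data

The generators define the study conditions used throughout the tests:

* labelled mixture samples — ground-truth labels ride along for recovery
  scoring but never reach the fitting path;
* a state-switching Poisson stream (exponential dwells, per-state rates,
  events placed uniformly within each dwell conditional on a Poisson count),
  the mechanism the mixture approximates;
* a recovery harness repeating sample → select_model and recording the
  selected k\* and the sorted-mean relative errors (sorting handles label
  switching).

Reference scenarios: a well-separated two-component mixture π = (0.5, 0.5),
μ = (1, 100) — fits at n = 10⁴ recover means within 10% and weights within
0.05 — and selection studies at n = 2000 with 50 seeded repeats, 10 restarts
and candidate grid k ∈ {1,…,5}, in which each completed-likelihood criterion
selects k\* = 2 (and k\* = 1 on single-exponential data) in at least 90% of
repeats.  The reduced grid relative to the default is a deliberate
problem-size choice for the repeated studies; the true k never exceeds 2
there, and larger candidate k values only collapse back via k\*.

What the synthetic conditions do **not** emulate: circadian and weekly
rhythms, nonstationary activity levels, correlations between successive
IETs, and discretisation to a finite recording resolution.  Passing tests
therefore demonstrate correctness of the estimators and codelengths under
the mixture's own assumptions, not that real behavioural data are mixtures.

## Preprocessing conventions

Day membership of an event at time t is ⌊(t − day_origin)/day_length⌋ with
day_origin = 0 by default; recordings that anchor days elsewhere (local
midnight vs. recording start) can shift the origin.  Directed records
attribute events to senders only; undirected contacts to both endpoints.
Runs of events at spacing exactly equal to the recording resolution are
collapsed to their first event (one continued activity), so the minimum IET
equals the resolution; zero IETs surviving preprocessing raise an error,
since they indicate mis-set merge flags and would break the log-scale
initialisation.

## Known limitations

* The NML codelength of the *marginal* (uncompleted) mixture has no known
  closed form and is not attempted.
* C_EMM's O(n²k\*) recursion dominates run time for n ≳ 10⁴; the memoisation
  helps across a selection sweep but not across different n.
* The tail power-law fit provides no bootstrap goodness-of-fit p-value.
* Criterion scores include the integer-code term; comparisons across
  packages using a different integer code differ by an additive O(1).
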