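"""Model-selection criteria for exponential mixtures of inter-event times.

Six criteria are implemented, all expressed as codelengths in nats (smaller is
better).  With ``L = -log p(tau; theta_EM)`` the marginal negative
log-likelihood at the EM estimate and ``Lc = -log p(tau, z; theta_hat)`` the
joint negative log-likelihood of the completed fit:

* ``AIC  = L + (2k - 1)`` and ``BIC = L + ((2k - 1)/2) log n`` — the classical
  criteria applied to the (non-identifiable) marginal mixture; included for
  comparison even though their asymptotic justification fails for mixtures.
* ``AIC_LVC = Lc + (2k* - 1)`` and
  ``BIC_LVC = Lc + ((k* - 1)/2) log n + (1/2) sum_j log n_j`` — the same ideas
  applied after latent-variable completion, which restores identifiability;
  ``k*`` is the number of components actually used.
* ``NML_LVC`` — the normalized-maximum-likelihood codelength of the completed
  model: ``Lc + log C_EMM(n, k*)`` plus the integer code for the mean bounds.
  ``C_EMM`` is the parametric complexity of the completed mixture, evaluated
  by an exact O(n^2 k*) recursion.
* ``DNML`` — the decomposed NML codelength: NML of the multinomial latent
  sequence plus, conditionally on it, the NML of each component's exponential
  data.  Its multinomial complexity ``C_mult`` has an exact O(n + k*)
  recursion.

Component-mean bounds enter through integers ``m'_min = floor(log min mu_hat)``
and ``m'_max = ceil(log max mu_hat)``, themselves encoded with a universal
prefix code for integers, so the total codelength is decodable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .emm import CompletedFit, FitResult, fit_with_restarts, _as_array

__all__ = [
    "CRITERIA",
    "IntegerBounds",
    "CriterionValue",
    "SelectionReport",
    "aic",
    "bic",
    "aic_lvc",
    "bic_lvc",
    "integer_codelength",
    "log_c_exp",
    "nml_exponential",
    "mu_bounds",
    "log_c_emm",
    "nml_lvc",
    "log_c_mult",
    "dnml",
    "evaluate_criteria",
    "select_model",
]

CRITERIA = ("AIC", "BIC", "AIC_LVC", "BIC_LVC", "NML_LVC", "DNML")

#: default candidate numbers of components
DEFAULT_K_GRID = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 20, 50, 100)

_LN2 = math.log(2.0)
_RISSANEN_C0 = 2.865064  # normaliser of the log* universal code for integers


@dataclass(frozen=True)
class IntegerBounds:
    """Integer bounds on log(mean): means are coded as lying in [e^lo, e^hi]."""

    m_min: int
    m_max: int

    def __post_init__(self) -> None:
        if self.m_max <= self.m_min:
            raise ValueError("m_max must exceed m_min")

    @property
    def m_range(self) -> int:
        return self.m_max - self.m_min


@dataclass
class CriterionValue:
    """One criterion score with its additive decomposition.

    ``components`` maps term names (``fit``, ``penalty``, ``complexity``,
    ``latent``, ``integer_code``) to nats; their sum equals ``score``.
    """

    criterion: str
    k: int
    k_star: int
    score: float
    components: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.components:
            total = sum(self.components.values())
            if not math.isclose(total, self.score, rel_tol=1e-9, abs_tol=1e-9):
                raise ValueError("components must sum to score")


@dataclass
class SelectionReport:
    """Score table over (criterion, k) pairs and the per-criterion winner."""

    table: dict[str, dict[int, CriterionValue]]
    selected: dict[str, tuple[int, int]]  # criterion -> (k, k_star)
    k_grid: tuple[int, ...]
    fits: dict[int, FitResult] = field(default_factory=dict, repr=False)

    def best(self, criterion: str) -> CriterionValue:
        k, _ = self.selected[criterion]
        return self.table[criterion][k]

    def to_dict(self) -> dict:
        return {
            "k_grid": list(self.k_grid),
            "criteria": {
                crit: {
                    "selected": {"k": self.selected[crit][0], "k_star": self.selected[crit][1]},
                    "scores": {
                        str(k): {
                            "score": cv.score,
                            "k_star": cv.k_star,
                            "components": cv.components,
                        }
                        for k, cv in rows.items()
                    },
                }
                for crit, rows in self.table.items()
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        lines = ["criterion\tk\tk_star\tscore"]
        for crit, rows in self.table.items():
            for k, cv in sorted(rows.items()):
                lines.append(f"{crit}\t{k}\t{cv.k_star}\t{cv.score:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# AIC / BIC families


def aic(fit: FitResult) -> CriterionValue:
    """AIC on the marginal EM fit: -log L + (2k - 1) (codelength scale)."""
    fit_term = -fit.marginal_loglik
    penalty = 2 * fit.k_requested - 1
    return CriterionValue(
        "AIC", fit.k_requested, fit.completed.k_star, fit_term + penalty,
        {"fit": fit_term, "penalty": float(penalty)},
    )


def bic(fit: FitResult) -> CriterionValue:
    """BIC on the marginal EM fit: -log L + ((2k - 1)/2) log n."""
    n = fit.completed.n
    fit_term = -fit.marginal_loglik
    penalty = (2 * fit.k_requested - 1) / 2 * math.log(n)
    return CriterionValue(
        "BIC", fit.k_requested, fit.completed.k_star, fit_term + penalty,
        {"fit": fit_term, "penalty": penalty},
    )


def aic_lvc(completed: CompletedFit, k: int | None = None) -> CriterionValue:
    """AIC after latent-variable completion: -log p(tau,z) + (2k* - 1)."""
    k_star = completed.k_star
    fit_term = completed.joint_neg_loglik
    penalty = 2 * k_star - 1
    return CriterionValue(
        "AIC_LVC", k if k is not None else k_star, k_star, fit_term + penalty,
        {"fit": fit_term, "penalty": float(penalty)},
    )


def bic_lvc(completed: CompletedFit, k: int | None = None) -> CriterionValue:
    """BIC after latent-variable completion.

    -log p(tau,z) + ((k* - 1)/2) log n + (1/2) sum_j log n_j: the weights
    contribute (k*-1)/2 dimensions at sample size n, each mean half a log of
    its own component count.
    """
    k_star = completed.k_star
    n = completed.n
    fit_term = completed.joint_neg_loglik
    penalty = (k_star - 1) / 2 * math.log(n) + 0.5 * float(
        np.log(completed.counts).sum()
    )
    return CriterionValue(
        "BIC_LVC", k if k is not None else k_star, k_star, fit_term + penalty,
        {"fit": fit_term, "penalty": penalty},
    )


# ---------------------------------------------------------------------------
# universal integer code


def _log2_star(j: float) -> float:
    """Sum of iterated positive base-2 logarithms of j >= 1."""
    total = 0.0
    x = math.log2(j)
    while x > 0:
        total += x
        x = math.log2(x) if x > 0 else 0.0
        if x <= 0:
            break
    return total


def integer_codelength(m: int) -> float:
    """Universal prefix-codelength (nats) for a signed integer.

    One bit for the sign, then Rissanen's log* code for the natural number
    |m| + 1: ``log2(c0) + log2*(j)`` bits with c0 ~= 2.865064, which satisfies
    the Kraft inequality.  Symmetric in +-m and non-decreasing in |m|.
    """
    j = abs(int(m)) + 1
    bits = 1.0 + math.log2(_RISSANEN_C0) + _log2_star(j)
    return bits * _LN2


# ---------------------------------------------------------------------------
# NML for a single exponential


def log_c_exp(n: int, m_min: int, m_max: int) -> float:
    """Log parametric complexity of the exponential family at sample size n.

    log C_exp(n) = n log n - n - log Gamma(n) + log(m_max - m_min), with the
    MLE constrained to lie in [e^{m_min}, e^{m_max}].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if m_max <= m_min:
        raise ValueError("m_max must exceed m_min")
    return n * math.log(n) - n - float(gammaln(n)) + math.log(m_max - m_min)


def nml_exponential(tau, bounds: IntegerBounds | None = None) -> CriterionValue:
    """NML codelength of a single exponential fit (k = 1).

    L_NML = n log mu_hat + n log n - log Gamma(n) + log(m_max - m_min); the
    reported score additionally pays the universal integer code for the two
    bounds.  Default bounds are floor/ceil of log mu_hat (widened by one when
    they coincide).
    """
    t = _as_array(tau)
    n = len(t)
    mu_hat = float(t.mean())
    if bounds is None:
        lo = math.floor(math.log(mu_hat))
        hi = math.ceil(math.log(mu_hat))
        if hi == lo:
            hi = lo + 1
        bounds = IntegerBounds(lo, hi)
    if not (math.exp(bounds.m_min) <= mu_hat <= math.exp(bounds.m_max)):
        raise ValueError(
            f"mean {mu_hat:g} outside [e^{bounds.m_min}, e^{bounds.m_max}]; widen the bounds"
        )
    fit_term = n * math.log(mu_hat) + n
    complexity = log_c_exp(n, bounds.m_min, bounds.m_max)
    int_code = integer_codelength(bounds.m_min) + integer_codelength(bounds.m_max)
    return CriterionValue(
        "NML_EXP", 1, 1, fit_term + complexity + int_code,
        {"fit": fit_term, "complexity": complexity, "integer_code": int_code},
    )


# ---------------------------------------------------------------------------
# completed-mixture complexity C_EMM


def mu_bounds(completed: CompletedFit) -> IntegerBounds:
    """Integer bounds enclosing all completed component means.

    m'_min = floor(log min_j mu_hat_j), m'_max = ceil(log max_j mu_hat_j);
    a degenerate range (both equal, e.g. a single mean that is an exact power
    of e) is widened upward by one so the range has positive log-measure.
    """
    lo = math.floor(math.log(float(completed.means_hat.min())))
    hi = math.ceil(math.log(float(completed.means_hat.max())))
    if hi == lo:
        hi = lo + 1
    return IntegerBounds(lo, hi)


# cache of complexity levels: (n, m_range) -> list of arrays, element k-1 is
# log C_EMM(r, k) for r = 0..n
_cemm_levels: dict[tuple[int, int], list[np.ndarray]] = {}


def _cemm_level_one(n: int, m_range: int) -> np.ndarray:
    """log C_EMM(r, 1) for r = 0..n; C_EMM(0, .) = 1 by convention."""
    r = np.arange(n + 1, dtype=float)
    out = np.zeros(n + 1)
    # note Gamma(r), not r!: the exponential complexity carries 1/Gamma(n)
    out[1:] = r[1:] * np.log(r[1:]) - r[1:] - gammaln(r[1:]) + math.log(m_range)
    return out


def log_c_emm(n: int, k_star: int, m_range: int) -> float:
    """Log parametric complexity of a completed exponential mixture.

    Evaluated by the exact recursion

        C_EMM(n, k+1) = sum_{r1 + r2 = n} C(n, r1) (r1/n)^{r1} (r2/n)^{r2}
                        C_EMM(r1, k) C_EMM(r2, 1),

    with C_EMM(n, 1) = (n/e)^n (m'_max - m'_min) / Gamma(n) and the
    conventions 0^0 = 1, C_EMM(0, .) = 1.  Everything is carried in log
    domain (log-sum-exp with lgamma binomials), so it is overflow-free;
    cost O(n^2 k*).  Results are memoised per (n, m_range).
    """
    if n < 1 or k_star < 1 or m_range < 1:
        raise ValueError("n, k_star and m_range must all be >= 1")
    levels = _cemm_levels.setdefault((n, m_range), [])
    if not levels:
        levels.append(_cemm_level_one(n, m_range))
    c1 = levels[0]
    r = np.arange(n + 1, dtype=float)
    while len(levels) < k_star:
        prev = levels[-1]
        # f(r) = r log r with f(0) = 0
        f = np.zeros(n + 1)
        f[1:] = r[1:] * np.log(r[1:])
        lg = gammaln(r + 1)  # log r!
        new = np.zeros(n + 1)
        for m in range(1, n + 1):
            r1 = np.arange(m + 1)
            terms = (
                (lg[m] - lg[r1] - lg[m - r1])
                + f[r1] + f[m - r1] - f[m]
                + prev[r1] + c1[m - r1]
            )
            new[m] = logsumexp(terms)
        levels.append(new)
    return float(levels[k_star - 1][n])


def nml_lvc(
    completed: CompletedFit, bounds: IntegerBounds | None = None, k: int | None = None
) -> CriterionValue:
    """NML codelength of the completed mixture (criterion NML_LVC).

    L_LVC = n H(n_1/n, ..., n_k*/n) + sum_j n_j log mu_hat_j + n
            + log C_EMM(n, k*)
    (the first three terms are exactly the joint negative log-likelihood);
    the score adds the universal integer code of the two mean bounds.
    """
    if bounds is None:
        bounds = mu_bounds(completed)
    fit_term = completed.joint_neg_loglik
    complexity = log_c_emm(completed.n, completed.k_star, bounds.m_range)
    int_code = integer_codelength(bounds.m_min) + integer_codelength(bounds.m_max)
    return CriterionValue(
        "NML_LVC", k if k is not None else completed.k_star, completed.k_star,
        fit_term + complexity + int_code,
        {"fit": fit_term, "complexity": complexity, "integer_code": int_code},
    )


# ---------------------------------------------------------------------------
# multinomial complexity C_mult and DNML


def log_c_mult(n: int, k_star: int) -> float:
    """Log parametric complexity of the multinomial with k* categories.

    C_mult(n, 1) = 1; C_mult(n, 2) is the binomial sum
    sum_t C(n, t) (t/n)^t ((n-t)/n)^{n-t}; for k >= 3 the linear recursion
    C_mult(n, k) = C_mult(n, k-1) + (n/(k-2)) C_mult(n, k-2) applies.
    Cost O(n + k*); carried in log domain.
    """
    if n < 1 or k_star < 1:
        raise ValueError("n and k_star must be >= 1")
    if k_star == 1:
        return 0.0
    t = np.arange(n + 1, dtype=float)
    f = np.zeros(n + 1)
    f[1:] = t[1:] * np.log(t[1:])
    lg = gammaln(t + 1)
    log_c2 = float(logsumexp(lg[n] - lg - lg[::-1] + f + f[::-1] - n * math.log(n)))
    if k_star == 2:
        return log_c2
    prev2, prev1 = 0.0, log_c2  # log C_mult(n, 1), log C_mult(n, 2)
    for k in range(3, k_star + 1):
        cur = float(np.logaddexp(prev1, math.log(n / (k - 2)) + prev2))
        prev2, prev1 = prev1, cur
    return prev1


def dnml(
    completed: CompletedFit, bounds: IntegerBounds | None = None, k: int | None = None
) -> CriterionValue:
    """Decomposed NML codelength (criterion DNML).

    L_DNML = L_NML(tau | z) + L_NML(z) with

        L_NML(tau|z) = sum_j { n_j log mu_hat_j + n_j log n_j - log Gamma(n_j) }
                       + k* log(m'_max - m'_min)
        L_NML(z)     = n H(n_1/n, ..., n_k*/n) + log C_mult(n, k*);

    the score adds the universal integer code of the two mean bounds.
    """
    if bounds is None:
        bounds = mu_bounds(completed)
    nj = completed.counts.astype(float)
    n = completed.n
    k_star = completed.k_star
    cond = float(
        (nj * np.log(completed.means_hat)).sum()
        + (nj * np.log(nj)).sum()
        - gammaln(nj).sum()
    ) + k_star * math.log(bounds.m_range)
    q = nj / n
    latent = float(n * -(q * np.log(q)).sum()) + log_c_mult(n, k_star)
    int_code = integer_codelength(bounds.m_min) + integer_codelength(bounds.m_max)
    return CriterionValue(
        "DNML", k if k is not None else k_star, k_star, cond + latent + int_code,
        {"fit": cond, "latent": latent, "integer_code": int_code},
    )


# ---------------------------------------------------------------------------
# model selection over a grid of k


def evaluate_criteria(
    fit: FitResult, criteria: Sequence[str] = CRITERIA
) -> dict[str, CriterionValue]:
    """Score one fit under the requested criteria (one shared fit per k)."""
    completed = fit.completed
    bounds = mu_bounds(completed)
    out: dict[str, CriterionValue] = {}
    for crit in criteria:
        if crit == "AIC":
            out[crit] = aic(fit)
        elif crit == "BIC":
            out[crit] = bic(fit)
        elif crit == "AIC_LVC":
            out[crit] = aic_lvc(completed, k=fit.k_requested)
        elif crit == "BIC_LVC":
            out[crit] = bic_lvc(completed, k=fit.k_requested)
        elif crit == "NML_LVC":
            out[crit] = nml_lvc(completed, bounds, k=fit.k_requested)
        elif crit == "DNML":
            out[crit] = dnml(completed, bounds, k=fit.k_requested)
        else:
            raise ValueError(f"unknown criterion {crit!r}")
    return out


def select_model(
    tau,
    k_grid: Iterable[int] = DEFAULT_K_GRID,
    criteria: Sequence[str] | str = CRITERIA,
    n_restarts: int = 10,
    seed: int = 0,
    *,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> SelectionReport:
    """Fit EMMs over a grid of k and pick, per criterion, the minimiser.

    Each candidate k gets one restart-selected fit (shared across criteria);
    ties break toward smaller k, since larger requested k with the same k*
    typically encodes the same effective distribution.
    """
    if isinstance(criteria, str):
        criteria = (criteria,)
    for crit in criteria:
        if crit not in CRITERIA:
            raise ValueError(f"unknown criterion {crit!r}")
    k_grid = tuple(sorted(set(int(k) for k in k_grid)))
    if not k_grid or k_grid[0] < 1:
        raise ValueError("k_grid must contain positive integers")

    fits: dict[int, FitResult] = {}
    table: dict[str, dict[int, CriterionValue]] = {c: {} for c in criteria}
    for idx, k in enumerate(k_grid):
        fit = fit_with_restarts(
            tau, k, n_restarts=n_restarts, seed=seed + 1000 * idx,
            max_iter=max_iter, tol=tol,
        )
        fits[k] = fit
        for crit, cv in evaluate_criteria(fit, criteria).items():
            table[crit][k] = cv

    selected = {}
    for crit in criteria:
        best_k = min(table[crit], key=lambda k: (table[crit][k].score, k))
        selected[crit] = (best_k, table[crit][best_k].k_star)
    return SelectionReport(table=table, selected=selected, k_grid=k_grid, fits=fits)
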