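"""Pareto and tail power-law (PLFit-style) baselines.

The Pareto density ``p(tau; a, b) = ((a - 1)/b) (tau/b)^{-a}`` on ``tau >= b``
is the classical pure power law for inter-event times.  Two estimators are
provided:

* the full-sample MLE, which anchors ``b_hat = min(tau)`` and uses the
  Hill-type exponent estimate; and
* a tail-selection procedure in the style of Clauset et al.: every unique
  data value is tried as the lower cut-off ``b_hat``, the exponent is
  re-estimated on the tail ``tau >= b_hat``, and the cut-off minimising the
  Kolmogorov-Smirnov distance between the tail empirical CDF and the fitted
  Pareto CDF wins.

Likelihood comparisons against an exponential-mixture fit deliberately do NOT
renormalise the mixture on truncated subsets: the mixture pays for the
probability mass it assigns below the power law's cut-off, mirroring how the
estimators would be used in practice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .emm import EMMParams, emm_logpdf, _as_array

__all__ = [
    "ParetoFit",
    "PLFitResult",
    "TruncatedLikelihoodReport",
    "pareto_mle",
    "pareto_logpdf",
    "pareto_survival",
    "plfit",
    "truncated_likelihood_comparison",
    "rescaled_tail_survival",
    "rescaled_tail_odds_ratio",
]


@dataclass
class ParetoFit:
    """MLE of a Pareto distribution: exponent, lower bound, log-likelihood."""

    a_hat: float
    b_hat: float
    loglik: float


@dataclass
class PLFitResult:
    """KS-optimal tail cut-off and exponent."""

    b_hat: float
    a_hat: float
    n_prime: int  # number of points with tau >= b_hat
    ks_distance: float


@dataclass
class TruncatedLikelihoodReport:
    """Log-likelihoods of the three models on nested point sets.

    Sets: ``all`` (n points), ``gt_min`` (tau > min tau, n'' points) and
    ``tail`` (tau >= b_hat from the tail fit, n' points).  Mixture and Pareto
    densities are evaluated unrenormalised on the subsets; the tail power law
    is only defined on its own tail.  ``None`` marks an empty subset.
    """

    n: int
    n_double_prime: int
    n_prime: int
    emm: dict[str, float | None]
    pareto: dict[str, float | None]
    plfit: dict[str, float | None]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_double_prime": self.n_double_prime,
            "n_prime": self.n_prime,
            "loglik": {"emm": self.emm, "pareto": self.pareto, "plfit": self.plfit},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def pareto_logpdf(tau, a: float, b: float) -> np.ndarray:
    """Elementwise log density; -inf below the support bound b."""
    t = _as_array(tau)
    out = np.full(len(t), -np.inf)
    ok = t >= b
    out[ok] = np.log(a - 1.0) - np.log(b) - a * np.log(t[ok] / b)
    return out


def pareto_survival(tau, a: float, b: float) -> np.ndarray:
    """Survival (tau/b)^{-(a-1)} on tau >= b (1 below b)."""
    t = _as_array(tau)
    return np.where(t >= b, (np.maximum(t, b) / b) ** (-(a - 1.0)), 1.0)


def pareto_mle(tau) -> ParetoFit:
    """Full-sample Pareto MLE.

    b_hat = min(tau); a_hat = 1 + 1 / (mean(log tau) - log b_hat) — the
    Hill-type estimator.  Degenerate samples (all values equal) make the
    exponent diverge and are rejected.
    """
    t = _as_array(tau)
    if len(t) < 2:
        raise ValueError("need at least two values")
    if np.any(t <= 0):
        raise ValueError("tau must be strictly positive")
    b = float(t.min())
    if t.max() == b:
        raise ValueError("degenerate data: all values equal, exponent diverges")
    s = float(np.mean(np.log(t)) - np.log(b))
    a = 1.0 + 1.0 / s
    loglik = float(pareto_logpdf(t, a, b).sum())
    return ParetoFit(a_hat=a, b_hat=b, loglik=loglik)


def plfit(tau) -> PLFitResult:
    """Select the power-law tail cut-off by KS minimisation.

    Continuous-data dialect: candidates are the unique data values whose tail
    keeps at least two points; the exponent on each tail is the Hill-type MLE;
    the KS statistic compares the tail empirical CDF with the fitted Pareto
    CDF.  Ties in KS break toward the smaller cut-off.
    """
    t = np.sort(_as_array(tau))
    n = len(t)
    if n < 2:
        raise ValueError("need at least two values")
    if np.any(t <= 0):
        raise ValueError("tau must be strictly positive")

    logt = np.log(t)
    suffix_sum = np.concatenate((np.cumsum(logt[::-1])[::-1], [0.0]))
    uniq, first_idx = np.unique(t, return_index=True)

    best: tuple[float, float, float, int] | None = None  # (ks, b, a, n')
    for b, i in zip(uniq, first_idx):
        m = n - i  # tail size
        if m < 2:
            continue
        s = suffix_sum[i] / m - logt[i]
        if s <= 0:  # all tail values equal; no finite exponent
            continue
        a = 1.0 + 1.0 / s
        x = t[i:]
        model_cdf = 1.0 - (x / b) ** (-(a - 1.0))
        ecdf_hi = np.arange(1, m + 1) / m
        ecdf_lo = np.arange(0, m) / m
        ks = float(
            max(np.abs(ecdf_hi - model_cdf).max(), np.abs(ecdf_lo - model_cdf).max())
        )
        if best is None or ks < best[0]:
            best = (ks, float(b), float(a), int(m))
    if best is None:
        raise ValueError("no viable tail cut-off (data degenerate)")
    ks, b, a, m = best
    return PLFitResult(b_hat=b, a_hat=a, n_prime=m, ks_distance=ks)


def truncated_likelihood_comparison(
    tau,
    emm_params: EMMParams,
    pareto_fit: ParetoFit,
    plfit_result: PLFitResult,
) -> TruncatedLikelihoodReport:
    """Compare model log-likelihoods on all points, tau > min, and the tail.

    The mixture and the full-sample Pareto are scored on all three point
    sets without renormalisation; the tail power law is only scored on its
    own tail ``tau >= b_hat``.  Empty subsets are reported as ``None``.
    """
    t = _as_array(tau)
    n = len(t)
    tmin = t.min()
    subsets = {
        "all": t,
        "gt_min": t[t > tmin],
        "tail": t[t >= plfit_result.b_hat],
    }

    def score(fn) -> dict[str, float | None]:
        return {
            name: (float(fn(sub).sum()) if len(sub) else None)
            for name, sub in subsets.items()
        }

    emm_scores = score(lambda x: emm_logpdf(x, emm_params))
    pareto_scores = score(lambda x: pareto_logpdf(x, pareto_fit.a_hat, pareto_fit.b_hat))
    tail = subsets["tail"]
    plfit_scores: dict[str, float | None] = {
        "all": None,
        "gt_min": None,
        "tail": float(pareto_logpdf(tail, plfit_result.a_hat, plfit_result.b_hat).sum())
        if len(tail)
        else None,
    }
    return TruncatedLikelihoodReport(
        n=n,
        n_double_prime=int((t > tmin).sum()),
        n_prime=plfit_result.n_prime,
        emm=emm_scores,
        pareto=pareto_scores,
        plfit=plfit_scores,
    )


def rescaled_tail_survival(tau, plfit_result: PLFitResult, eval_points) -> np.ndarray:
    """Tail power-law survival rescaled to the full sample.

    The tail fit only models the fraction n'/n of points with
    tau >= b_hat, so its survival is rescaled as
    S(tau) = (n'/n) (tau/b_hat)^{-(a_hat - 1)}.  Evaluation points below
    b_hat are undefined and returned as NaN.
    """
    t = _as_array(tau)
    x = _as_array(eval_points)
    frac = plfit_result.n_prime / len(t)
    out = np.full(len(x), np.nan)
    ok = x >= plfit_result.b_hat
    out[ok] = frac * (x[ok] / plfit_result.b_hat) ** (-(plfit_result.a_hat - 1.0))
    return out


def rescaled_tail_odds_ratio(tau, plfit_result: PLFitResult, eval_points) -> np.ndarray:
    """Odds ratio (1 - S)/S of the rescaled tail survival (NaN below b_hat)."""
    s = rescaled_tail_survival(tau, plfit_result, eval_points)
    return (1.0 - s) / s
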