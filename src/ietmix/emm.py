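"""Exponential mixture models (EMMs) and their EM estimation.

An EMM with *k* components has density

    p(tau; pi, mu) = sum_j (pi_j / mu_j) exp(-tau / mu_j),    tau >= 0,

where ``pi`` is a probability vector of mixing weights and ``mu_j > 0`` is the
mean of the *j*-th exponential component.  Such mixtures arise when a point
process switches between a few Poissonian states with different rates, and
with well-separated means they closely mimic power-law-looking inter-event
time distributions.

Two estimators live here:

* the EM estimator ``theta_EM`` — the usual marginal maximum-likelihood
  fit obtained by iterating expectation and maximisation steps; and
* the *completed* estimator — hard assignments ``z_i`` of every observation
  to its most responsible component, followed by the exact joint
  maximum-likelihood estimate ``pi_hat_j = n_j / n`` and ``mu_hat_j`` equal to
  the within-component sample mean.  Components left empty by the hard
  assignment are dropped; ``k_star`` counts the survivors.

The completed fit restores identifiability (the marginal mixture is not
identifiable, e.g. two components with equal means collapse), which is what
lets information criteria and NML codelengths be applied downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .preprocess import InterEventTimes

__all__ = [
    "EMMParams",
    "CompletedFit",
    "FitResult",
    "emm_pdf",
    "emm_logpdf",
    "emm_survival",
    "odds_ratio",
    "sample_emm",
    "em_init",
    "em_fit",
    "complete_latent",
    "fit_with_restarts",
    "responsibilities",
]

# components with weight below this, or mean below this fraction of min(tau),
# are frozen out of the E step (they end with n_j = 0 at completion)
_WEIGHT_FLOOR = 1e-12
_MEAN_FLOOR_FACTOR = 1e-12


def _as_array(tau) -> np.ndarray:
    if isinstance(tau, InterEventTimes):
        tau = tau.values
    tau = np.asarray(tau, dtype=float)
    if tau.ndim == 0:
        tau = tau[None]
    return tau


@dataclass
class EMMParams:
    """Mixing weights and component means of an exponential mixture."""

    weights: np.ndarray
    means: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        if self.weights.shape != self.means.shape or self.weights.ndim != 1:
            raise ValueError("weights and means must be 1-d arrays of equal length")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be non-negative and sum to 1")
        if np.any(self.means <= 0):
            raise ValueError("means must be positive")

    @property
    def k(self) -> int:
        return len(self.weights)


@dataclass
class CompletedFit:
    """Hard latent assignments and the exact joint-likelihood MLE."""

    assignments: np.ndarray  # z_i in 0..k-1, indices into the original fit
    counts: np.ndarray  # n_j per retained (non-empty) component
    k_star: int
    weights_hat: np.ndarray  # n_j / n
    means_hat: np.ndarray  # within-component sample means
    joint_neg_loglik: float  # -log p(tau, z; theta_hat)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class FitResult:
    """One EM run (or the best of several restarts) plus its completion."""

    em_params: EMMParams
    completed: CompletedFit
    marginal_loglik: float
    k_requested: int
    seed: int
    n_restarts: int = 1
    iterations: int = 0
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "k": self.k_requested,
            "k_star": self.completed.k_star,
            "weights": self.em_params.weights.tolist(),
            "means": self.em_params.means.tolist(),
            "weights_hat": self.completed.weights_hat.tolist(),
            "means_hat": self.completed.means_hat.tolist(),
            "marginal_loglik": self.marginal_loglik,
            "joint_neg_loglik": self.completed.joint_neg_loglik,
            "n": self.completed.n,
            "seed": self.seed,
            "n_restarts": self.n_restarts,
            "iterations": self.iterations,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# density, survival, sampling


def _component_logpdf(tau: np.ndarray, means: np.ndarray) -> np.ndarray:
    """(n, k) matrix of log exponential densities -log mu_j - tau_i/mu_j."""
    return -np.log(means)[None, :] - tau[:, None] / means[None, :]


def emm_logpdf(tau, params: EMMParams) -> np.ndarray:
    """Log density of the mixture, elementwise over ``tau``."""
    t = _as_array(tau)
    if np.any(t < 0):
        raise ValueError("tau must be non-negative")
    with np.errstate(divide="ignore"):
        logw = np.log(params.weights)
    return logsumexp(logw[None, :] + _component_logpdf(t, params.means), axis=1)


def emm_pdf(tau, params: EMMParams) -> np.ndarray | float:
    """Mixture density sum_j (pi_j/mu_j) exp(-tau/mu_j)."""
    out = np.exp(emm_logpdf(tau, params))
    return out.item() if np.isscalar(tau) or np.ndim(tau) == 0 else out


def emm_survival(tau, params: EMMParams) -> np.ndarray | float:
    """Survival probability S(tau) = sum_j pi_j exp(-tau/mu_j)."""
    t = _as_array(tau)
    if np.any(t < 0):
        raise ValueError("tau must be non-negative")
    out = np.exp(-t[:, None] / params.means[None, :]) @ params.weights
    return out.item() if np.isscalar(tau) or np.ndim(tau) == 0 else out


def odds_ratio(tau, params: EMMParams) -> np.ndarray | float:
    """Odds ratio OR(tau) = (1 - S(tau)) / S(tau); 0 at tau = 0.

    The odds ratio magnifies differences between distributions at small tau,
    where survival curves are all close to 1.
    """
    s = emm_survival(tau, params)
    return (1.0 - s) / s


def sample_emm(params: EMMParams, n: int, seed: int) -> InterEventTimes:
    """Draw ``n`` i.i.d. inter-event times from the mixture (reproducible)."""
    values, _ = sample_emm_labelled(params, n, seed)
    return values


def sample_emm_labelled(
    params: EMMParams, n: int, seed: int
) -> tuple[InterEventTimes, np.ndarray]:
    """As :func:`sample_emm` but also return the generating component labels."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(params.k, size=n, p=params.weights)
    values = rng.exponential(params.means[labels])
    return InterEventTimes(values), labels


def responsibilities(tau, params: EMMParams) -> np.ndarray:
    """E-step responsibility matrix gamma_ij = P(component j | tau_i).

    Rows are normalised to 1; computed in log space so that components with
    means orders of magnitude apart cannot underflow a whole row.
    """
    t = _as_array(tau)
    with np.errstate(divide="ignore"):
        logw = np.log(params.weights)
    logjoint = logw[None, :] + _component_logpdf(t, params.means)
    return np.exp(logjoint - logsumexp(logjoint, axis=1)[:, None])


# ---------------------------------------------------------------------------
# EM algorithm


def em_init(tau, k: int, seed: int) -> EMMParams:
    """Broad random initialisation for EM.

    Weights start uniform at 1/k; each initial mean is drawn log-uniformly,
    ``log10 mu_j ~ U[log10 tau_min, log10 tau_max]``, so that the initial
    means span the full dynamic range of the data (most draws land at small
    means, occasionally a large one seeds the long tail).
    """
    t = _as_array(tau)
    if len(t) == 0 or np.min(t) <= 0:
        raise ValueError("tau must be non-empty and strictly positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = np.log10(np.min(t)), np.log10(np.max(t))
    means = 10.0 ** rng.uniform(lo, hi, size=k)
    return EMMParams(weights=np.full(k, 1.0 / k), means=means)


def _em_batch(
    t: np.ndarray,
    init_weights: np.ndarray,
    init_means: np.ndarray,
    max_iter: int,
    tol: float,
) -> list[tuple[np.ndarray, np.ndarray, int, np.ndarray]]:
    """Run EM on a batch of initialisations simultaneously.

    ``init_weights`` and ``init_means`` are (R, k) arrays for R restarts.
    Converged restarts are frozen (their parameters stop updating), so each
    restart's trajectory is identical to what a standalone run with the same
    stopping rule would produce.  Returns, per restart,
    ``(weights, means, iterations, loglik_trace)``.
    """
    n = len(t)
    n_runs, k = init_weights.shape
    weights = init_weights.copy()
    means = init_means.copy()
    mean_floor = _MEAN_FLOOR_FACTOR * float(np.min(t))
    active = np.ones((n_runs, k), dtype=bool)
    running = np.ones(n_runs, dtype=bool)
    iterations = np.zeros(n_runs, dtype=np.int64)
    loglik = np.full(n_runs, -np.inf)
    traces: list[np.ndarray] = []

    for step in range(1, max_iter + 1):
        active &= (weights >= _WEIGHT_FLOOR) & (means >= mean_floor)
        with np.errstate(divide="ignore"):
            logw = np.where(active, np.log(np.maximum(weights, 1e-300)), -np.inf)
        # (R, n, k) log joint: log pi_j - log mu_j - tau_i / mu_j
        logjoint = (
            (logw - np.log(np.maximum(means, 1e-300)))[:, None, :]
            - t[None, :, None] / np.maximum(means, 1e-300)[:, None, :]
        )
        peak = logjoint.max(axis=2)
        expd = np.exp(logjoint - peak[:, :, None])
        norm = expd.sum(axis=2)
        lognorm = peak + np.log(norm)
        new_loglik = lognorm.sum(axis=1)
        traces.append(np.where(running, new_loglik, np.nan))

        gamma = expd / norm[:, :, None]
        nk = gamma.sum(axis=1)  # (R, k)
        with np.errstate(invalid="ignore", divide="ignore"):
            new_means = np.einsum("rnk,n->rk", gamma, t) / nk
        upd = running[:, None]
        weights = np.where(upd, nk / n, weights)
        means = np.where(upd & (nk > 0), new_means, means)
        iterations[running] = step

        converged = (
            running
            & np.isfinite(loglik)
            & (np.abs(new_loglik - loglik) <= tol * np.abs(loglik))
        )
        loglik = np.where(running, new_loglik, loglik)
        running &= ~converged
        if not running.any():
            break

    results = []
    for r in range(n_runs):
        w = np.where(active[r], weights[r], 0.0)
        w = w / w.sum()
        trace = np.array([tr[r] for tr in traces[: iterations[r]]])
        results.append((w, means[r], int(iterations[r]), trace))
    return results


def em_fit(
    tau,
    k: int,
    seed: int,
    *,
    max_iter: int = 1000,
    tol: float = 1e-10,
    init: EMMParams | None = None,
) -> FitResult:
    """Single EM run from one random initialisation, plus latent completion.

    E step: responsibilities ``gamma_ij`` proportional to
    ``pi_j p(tau_i; mu_j)``, rows normalised (computed in log space).
    M step: ``pi_j <- mean_i gamma_ij``; ``mu_j <-`` responsibility-weighted
    mean of ``tau``.  Stops when the relative change of the marginal
    log-likelihood falls below ``tol`` or after ``max_iter`` iterations.
    The marginal log-likelihood is non-decreasing across iterations.
    """
    t = _as_array(tau)
    if len(t) == 0 or np.min(t) <= 0:
        raise ValueError("tau must be non-empty and strictly positive")
    params = init if init is not None else em_init(t, k, seed)
    (weights, means, iterations, trace), = _em_batch(
        t, params.weights[None, :], params.means[None, :], max_iter, tol
    )
    em_params = EMMParams(weights=weights, means=means)
    completed = complete_latent(t, em_params)
    return FitResult(
        em_params=em_params,
        completed=completed,
        marginal_loglik=float(emm_logpdf(t, em_params).sum()),
        k_requested=k,
        seed=seed,
        iterations=iterations,
        loglik_trace=trace,
    )


def complete_latent(tau, em_params: EMMParams) -> CompletedFit:
    """Hard-assign each observation and take the exact joint MLE.

    ``z_i = argmax_j pi_j p(tau_i; mu_j)`` (ties to the lowest index), then
    ``pi_hat_j = n_j/n`` and ``mu_hat_j`` the mean of the assigned values.
    Components receiving no observations are removed; ``k_star`` counts the
    rest.  The joint negative log-likelihood is

        -log p(tau, z; theta_hat) = n H(n_1/n, ..., n_k*/n)
                                    + sum_j n_j log mu_hat_j + n,

    equivalently ``-sum_j n_j log( pi_hat_j / (e mu_hat_j) )``.
    """
    t = _as_array(tau)
    n = len(t)
    with np.errstate(divide="ignore"):
        logw = np.log(em_params.weights)
    logjoint = logw[None, :] + _component_logpdf(t, em_params.means)
    z = np.argmax(logjoint, axis=1)  # argmax takes the first max: lowest index

    used = np.unique(z)
    counts = np.array([(z == j).sum() for j in used], dtype=np.int64)
    means_hat = np.array([t[z == j].mean() for j in used])
    weights_hat = counts / n

    # relabel assignments to 0..k_star-1 in original component order
    remap = {int(j): i for i, j in enumerate(used)}
    z_relabelled = np.array([remap[int(j)] for j in z], dtype=np.int64)

    entropy = float(-(weights_hat * np.log(weights_hat)).sum())
    joint_neg_loglik = float(n * entropy + (counts * np.log(means_hat)).sum() + n)
    return CompletedFit(
        assignments=z_relabelled,
        counts=counts,
        k_star=len(used),
        weights_hat=weights_hat,
        means_hat=means_hat,
        joint_neg_loglik=joint_neg_loglik,
    )


def fit_with_restarts(
    tau,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
    *,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> FitResult:
    """Best of ``n_restarts`` EM runs, judged by the joint likelihood.

    Restart ``i`` uses sub-seed ``seed + i``; the run whose completed fit
    maximises the joint likelihood p(tau, z; theta_hat) — i.e. minimises
    ``joint_neg_loglik`` — is returned.  This guards against local maxima of
    the EM objective.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    t = _as_array(tau)
    if len(t) == 0 or np.min(t) <= 0:
        raise ValueError("tau must be non-empty and strictly positive")
    inits = [em_init(t, k, seed + i) for i in range(n_restarts)]
    runs = _em_batch(
        t,
        np.stack([p.weights for p in inits]),
        np.stack([p.means for p in inits]),
        max_iter,
        tol,
    )
    best: FitResult | None = None
    for i, (weights, means, iterations, trace) in enumerate(runs):
        em_params = EMMParams(weights=weights, means=means)
        completed = complete_latent(t, em_params)
        if best is None or completed.joint_neg_loglik < best.completed.joint_neg_loglik:
            best = FitResult(
                em_params=em_params,
                completed=completed,
                marginal_loglik=float(emm_logpdf(t, em_params).sum()),
                k_requested=k,
                seed=seed + i,
                iterations=iterations,
                loglik_trace=trace,
            )
    assert best is not None
    best.n_restarts = n_restarts
    best.seed = seed
    return best
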