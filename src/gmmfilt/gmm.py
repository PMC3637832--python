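"""Univariate Gaussian mixture decomposition of a filter signal.

The per-gene signal x (mean or log variance of expression) is modeled as a
K-component Gaussian mixture

    f(x) = sum_k alpha_k f_k(x; mu_k, sigma_k),   sum_k alpha_k = 1,

fitted by maximum likelihood with the EM algorithm from random restarts.
The number of components is chosen by minimizing

    BIC = -2 logL + (3K - 1) ln N

over a range of K (default 1..15); 3K - 1 counts K means, K standard
deviations and K - 1 free weights.  Genes are then assigned to components
by the maximum a posteriori rule: gene n goes to argmax_k alpha_k
f_k(x_n).  Components are always stored sorted by ascending mean, so
"component 0" is the lowest-signal (least informative) one.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .signals import FilterSignal

_LOG_2PI = math.log(2.0 * math.pi)

#: sigma floor, as a fraction of the overall sample SD of the signal
SIGMA_FLOOR_FRACTION = 1e-3


class DegenerateDataError(ValueError):
    """All signal values identical: no mixture with K > 1 is identifiable."""


def _as_values(signal) -> np.ndarray:
    x = signal.x if isinstance(signal, FilterSignal) else np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a nonempty 1-D vector")
    return x


@dataclass
class GMMFit:
    """Result of an EM fit: parameters, fit diagnostics and MAP assignments.

    Components are in canonical order (means ascending); ``assignments``
    holds the 0-based MAP component index per gene.
    """

    K: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    logL: float
    bic: float
    assignments: np.ndarray | None = None
    converged: bool = False
    n_iter: int = 0
    seed: int | None = None
    sigma_floor: float = 0.0
    logL_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not (self.weights.shape == self.means.shape == self.sds.shape == (self.K,)):
            raise ValueError("weights, means, sds must all have length K")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("component standard deviations must be positive")
        if np.any(np.diff(self.means) < 0):
            raise ValueError("components must be sorted by ascending mean")

    # -- serialization (auditable, re-applicable filters) ------------------
    def to_json(self) -> str:
        d = {
            "K": self.K,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "logL": self.logL,
            "bic": self.bic,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "sigma_floor": self.sigma_floor,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, doc: str) -> "GMMFit":
        d = json.loads(doc)
        return cls(
            K=d["K"],
            weights=np.asarray(d["weights"]),
            means=np.asarray(d["means"]),
            sds=np.asarray(d["sds"]),
            logL=d["logL"],
            bic=d["bic"],
            converged=d.get("converged", False),
            n_iter=d.get("n_iter", 0),
            seed=d.get("seed"),
            sigma_floor=d.get("sigma_floor", 0.0),
        )


def component_density(x, mu: float, sigma: float):
    """Gaussian probability density f_k(x; mu, sigma)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    z = (np.asarray(x, dtype=float) - mu) / sigma
    return np.exp(-0.5 * z * z) / (sigma * math.sqrt(2.0 * math.pi))


def _log_component_matrix(x: np.ndarray, weights, means, sds) -> np.ndarray:
    """ln(alpha_k f_k(x_n)) as an (N, K) matrix, computed in log space."""
    z = (x[:, None] - means[None, :]) / sds[None, :]
    return (
        np.log(weights)[None, :]
        - np.log(sds)[None, :]
        - 0.5 * (_LOG_2PI + z * z)
    )


def mixture_density(x, fit: GMMFit):
    """Mixture density sum_k alpha_k f_k(x)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.exp(logsumexp(_log_component_matrix(x, fit.weights, fit.means, fit.sds), axis=1))
    return out if out.size > 1 else float(out[0])


def log_likelihood(signal, fit: GMMFit) -> float:
    """logL = sum_n ln sum_k alpha_k f_k(x_n)."""
    x = _as_values(signal)
    ll = logsumexp(_log_component_matrix(x, fit.weights, fit.means, fit.sds), axis=1)
    if not np.all(np.isfinite(ll)):
        raise FloatingPointError("zero mixture density encountered in log-likelihood")
    return float(ll.sum())


def bic(logL: float, K: int, N: int) -> float:
    """Bayesian information criterion, -2 logL + (3K - 1) ln N (natural log)."""
    if K < 1 or N < 1:
        raise ValueError("K and N must be positive")
    return -2.0 * logL + (3 * K - 1) * math.log(N)


def map_assign(signal, fit: GMMFit) -> np.ndarray:
    """MAP component index (0-based, canonical mean-ascending order) per gene.

    Ties go to the component with the smaller mean, i.e. the lower index.
    """
    x = _as_values(signal)
    logw = _log_component_matrix(x, fit.weights, fit.means, fit.sds)
    return np.argmax(logw, axis=1)


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def _weighted_em(
    x: np.ndarray,
    w: np.ndarray,
    K: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    sigma_floor: float,
    x_min: float,
    x_max: float,
    sd_all: float,
):
    """One EM run on (possibly weighted/binned) data.

    Returns (weights, means, sds, trace, converged, n_iter) or None if the
    restart collapsed (a component lost essentially all its mass).
    """
    n_eff = w.sum()
    means = rng.uniform(x_min, x_max, size=K)
    sds = np.full(K, sd_all)
    alphas = np.full(K, 1.0 / K)

    trace = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logr = _log_component_matrix(x, alphas, means, sds)
        norm = logsumexp(logr, axis=1)
        ll = float(np.dot(w, norm))
        trace.append(ll)
        r = np.exp(logr - norm[:, None])  # responsibilities, rows sum to 1
        wr = r * w[:, None]
        nk = wr.sum(axis=0)
        if np.any(nk < 1e-10 * n_eff) or not np.isfinite(ll):
            return None  # collapsed restart
        alphas = nk / n_eff
        means = (wr * x[:, None]).sum(axis=0) / nk
        var = (wr * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, sigma_floor**2))
        if ll - prev < tol * max(abs(ll), 1.0) and it > 1:
            converged = True
            break
        prev = ll
    return alphas, means, sds, np.asarray(trace), converged, it


def em_fit(
    signal,
    K: int,
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_bins: int | None = None,
) -> GMMFit:
    """Fit a K-component univariate Gaussian mixture by best-of-restarts EM.

    Each restart draws component means uniformly over the signal range,
    starts all SDs at the overall sample SD and weights uniform, and runs
    EM until the relative log-likelihood change drops below ``tol``.
    Restarts whose components collapse onto the variance floor with no mass
    are discarded.  All randomness derives from ``seed`` via per-restart
    child seeds, so results are bit-reproducible.

    ``n_bins``: if set and the signal is longer, EM runs on a histogram of
    the signal with bin counts as weights (a numerical acceleration for
    very large N); the reported logL and BIC are always recomputed exactly
    on the full unbinned signal.
    """
    x = _as_values(signal)
    N = x.size
    if K < 1:
        raise ValueError("K must be >= 1")
    if N < K:
        raise ValueError(f"need at least K={K} observations, got {N}")
    sd_all = float(x.std())
    if sd_all == 0.0 and K > 1:
        raise DegenerateDataError("all signal values identical; only K=1 is fittable")
    sigma_floor = max(SIGMA_FLOOR_FRACTION * sd_all, 1e-12)

    if K == 1:
        # closed-form MLE, independent of seed
        mu = float(x.mean())
        sd = max(float(x.std()), sigma_floor)
        fit = GMMFit(
            K=1,
            weights=np.array([1.0]),
            means=np.array([mu]),
            sds=np.array([sd]),
            logL=0.0,
            bic=0.0,
            converged=True,
            n_iter=0,
            seed=seed,
            sigma_floor=sigma_floor,
        )
        fit.logL = log_likelihood(x, fit)
        fit.bic = bic(fit.logL, 1, N)
        fit.assignments = np.zeros(N, dtype=int)
        fit.logL_trace = np.array([fit.logL])
        return fit

    if n_bins is not None and N > n_bins:
        counts, edges = np.histogram(x, bins=n_bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = counts > 0
        xe, we = centers[keep], counts[keep].astype(float)
    else:
        xe, we = x, np.ones(N)

    x_min, x_max = float(x.min()), float(x.max())
    children = np.random.SeedSequence(seed).spawn(n_restarts)
    best = None
    best_ll = -np.inf
    for child in children:
        rng = np.random.default_rng(child)
        res = _weighted_em(xe, we, K, rng, tol, max_iter, sigma_floor, x_min, x_max, sd_all)
        if res is None:
            continue
        alphas, means, sds, trace, converged, it = res
        ll = trace[-1]
        if ll > best_ll:
            best_ll = ll
            best = (alphas, means, sds, trace, converged, it)
    if best is None:
        raise RuntimeError(
            f"all {n_restarts} EM restarts collapsed for K={K}; "
            "the signal may have fewer distinct values than components"
        )
    alphas, means, sds, trace, converged, it = best
    order = np.argsort(means, kind="stable")
    fit = GMMFit(
        K=K,
        weights=alphas[order] / alphas.sum(),
        means=means[order],
        sds=sds[order],
        logL=0.0,
        bic=0.0,
        converged=converged,
        n_iter=it,
        seed=seed,
        sigma_floor=sigma_floor,
        logL_trace=trace,
    )
    fit.logL = log_likelihood(x, fit)
    fit.bic = bic(fit.logL, K, N)
    fit.assignments = map_assign(x, fit)
    return fit


def select_model(
    signal,
    K_min: int = 1,
    K_max: int = 15,
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_bins: int | None = None,
) -> GMMFit:
    """Fit mixtures for K in [K_min, K_max] and return the smallest-BIC fit.

    Ties break toward smaller K.  ``K_max`` is clipped to the number of
    observations.  With ``K_min == K_max`` the search is bypassed (the
    fixed-K mode used for simulated two-population signals).
    """
    x = _as_values(signal)
    if K_min > K_max:
        raise ValueError("K_min must be <= K_max")
    K_max = min(K_max, x.size)
    K_min = min(K_min, K_max)
    best: GMMFit | None = None
    for K in range(K_min, K_max + 1):
        try:
            fit = em_fit(x, K, seed=seed, n_restarts=n_restarts, tol=tol,
                         max_iter=max_iter, n_bins=n_bins)
        except DegenerateDataError:
            if best is not None:
                break
            raise
        except RuntimeError:
            continue  # no viable restart at this K; keep searching
        if best is None or fit.bic < best.bic:
            best = fit
    if best is None:
        raise RuntimeError("no K in the requested range produced a viable fit")
    return best
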