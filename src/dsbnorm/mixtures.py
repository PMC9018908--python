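"""Univariate Gaussian mixture fitting by expectation-maximization.

This is the engine behind the per-cell background estimate (the mean of the
lower, "negative" protein component within each cell) and behind the
automatic cell/empty droplet split on library size. The model is a k-component
mixture with unequal per-component variances:

    f(x) = sum_j  phi_j * N(x | mu_j, sigma_j^2)

fitted by EM with a deterministic quantile initialization, optional seeded
random restarts, and a variance floor so that near-degenerate components
degrade gracefully instead of blowing up the likelihood. Model order is
compared with BIC in the "larger is better" sign convention

    BIC = 2*loglik - p*ln(n),   p = 3k - 1

(k means, k variances, k-1 free weights).

Fitting is exposed in two shapes: a scalar API (`em_fit_1d`, `sweep_k`) for a
single value vector, and a batched API (`fit_cells`, `sweep_cells`) that runs
the same arithmetic in lockstep across many cells sharing an observation
count. The scalar path is literally the batched path with a batch of one, so
the two produce bit-identical parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 200
#: variance floor = VAR_FLOOR_FRAC * sample variance, but never below VAR_FLOOR_MIN
VAR_FLOOR_FRAC = 1e-6
VAR_FLOOR_MIN = 1e-10
#: jitter scale (in sample SDs) applied to the quantile means on restarts > 0
RESTART_JITTER_SD = 0.5


@dataclass
class MixtureFit:
    """Result of a univariate Gaussian mixture fit.

    Components are relabeled so means ascend; ``weights``/``means``/``sds``
    all have length ``k``. ``bic`` uses the larger-is-better convention.
    ``fallback_used`` marks degenerate inputs (zero sample variance with
    k >= 2) where EM is meaningless and a collapsed fit is returned instead.
    """

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    bic: float
    n: int
    converged: bool
    n_iter: int
    fallback_used: bool = False
    loglik_trace: np.ndarray | None = None


def bic(fit: MixtureFit) -> float:
    """mclust-convention BIC: ``2*loglik - (3k-1)*ln(n)``; larger is better."""
    if fit.n <= 1:
        raise ValueError(f"BIC undefined for n={fit.n}")
    p = 3 * fit.k - 1
    return 2.0 * fit.loglik - p * np.log(fit.n)


def derive_seed(master_seed: int, index: int) -> int:
    """Stable per-cell seed from a master seed and a cell index."""
    return int(np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0])


# ---------------------------------------------------------------------------
# batched EM core


def _loglik_terms(x, means, var, weights):
    """Per-point joint log density. x: (B,n); params: (B,k) -> (B,n,k)."""
    d = x[:, :, None] - means[:, None, :]
    return (
        -0.5 * (_LOG2PI + np.log(var))[:, None, :]
        - d * d / (2.0 * var)[:, None, :]
        + np.log(weights)[:, None, :]
    )


def _em_batch(
    X: np.ndarray,
    k: int,
    means_init: np.ndarray,
    var_init: np.ndarray,
    var_floor: np.ndarray,
    tol: float,
    max_iter: int,
    record_trace: bool = False,
):
    """Run EM in lockstep over a batch of value vectors.

    X: (B, n); means_init: (B, k); var_init, var_floor: (B,).
    Returns (weights, means, var, loglik, converged, n_iter, traces).
    Cells are frozen individually once their loglik change drops below tol;
    the reported loglik always matches the reported parameters.
    """
    B, n = X.shape
    means = means_init.astype(float).copy()
    var = np.broadcast_to(np.maximum(var_init, var_floor)[:, None], (B, k)).copy()
    weights = np.full((B, k), 1.0 / k)

    loglik = np.full(B, -np.inf)
    ll_prev = np.full(B, np.nan)
    converged = np.zeros(B, dtype=bool)
    n_iter = np.zeros(B, dtype=int)
    active = np.ones(B, dtype=bool)
    traces: list[list[float]] | None = [[] for _ in range(B)] if record_trace else None

    for it in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        x = X[idx]
        logp = _loglik_terms(x, means[idx], var[idx], weights[idx])
        lse = logsumexp(logp, axis=2)                      # (b, n)
        ll = lse.sum(axis=1)                               # (b,)
        if it > 0:
            prev = ll_prev[idx]
            # EM guarantees monotone loglik; a violation beyond rounding is a bug
            if np.any(ll < prev - 1e-9):
                worst = float(np.min(ll - prev))
                raise AssertionError(f"EM loglik decreased by {-worst:.3e}")
        loglik[idx] = ll
        if traces is not None:
            for b, v in zip(idx, ll):
                traces[b].append(float(v))

        done = np.zeros(idx.size, dtype=bool)
        if it > 0:
            done = np.abs(ll - ll_prev[idx]) < tol
            newly = idx[done]
            converged[newly] = True
            active[newly] = False
        ll_prev[idx] = ll

        upd = idx[~done]
        if upd.size == 0:
            continue
        keep = ~done
        resp = np.exp(logp[keep] - lse[keep][:, :, None])  # (b', n, k)
        xk = x[keep]
        Nk = resp.sum(axis=1)                              # (b', k)
        safe = np.maximum(Nk, 1e-300)
        w_new = np.maximum(Nk / n, 1e-12)
        w_new /= w_new.sum(axis=1, keepdims=True)
        mu_new = (resp * xk[:, :, None]).sum(axis=1) / safe
        mu_new = np.where(Nk > 0, mu_new, means[upd])
        dev = xk[:, :, None] - mu_new[:, None, :]
        v_new = (resp * dev * dev).sum(axis=1) / safe
        v_new = np.where(Nk > 0, v_new, var_floor[upd, None])
        v_new = np.maximum(v_new, var_floor[upd, None])
        weights[upd] = w_new
        means[upd] = mu_new
        var[upd] = v_new
        n_iter[upd] += 1

    # parameters of never-converged cells changed after their last E-step;
    # recompute their loglik so it matches what is returned
    idx = np.flatnonzero(active)
    if idx.size:
        logp = _loglik_terms(X[idx], means[idx], var[idx], weights[idx])
        ll = logsumexp(logp, axis=2).sum(axis=1)
        loglik[idx] = ll
        if traces is not None:
            for b, v in zip(idx, ll):
                traces[b].append(float(v))

    # canonical labels: means ascending
    order = np.argsort(means, axis=1, kind="stable")
    take = np.take_along_axis
    weights = take(weights, order, axis=1)
    means = take(means, order, axis=1)
    var = take(var, order, axis=1)
    return weights, means, var, loglik, converged, n_iter, traces


def _quantile_means(X: np.ndarray, k: int) -> np.ndarray:
    """Deterministic init: component j's mean at the (j - 0.5)/k quantile."""
    q = (np.arange(k) + 0.5) / k
    return np.quantile(X, q, axis=1).T  # (B, k)


def _fit_batch_restarts(
    X: np.ndarray,
    k: int,
    restarts: int,
    seeds: np.ndarray,
    tol: float,
    max_iter: int,
    record_trace: bool = False,
):
    """Best-of-restarts batched fit. seeds: one per batch row."""
    B, n = X.shape
    sample_var = X.var(axis=1, ddof=0)
    sample_sd = np.sqrt(sample_var)
    var_floor = np.maximum(VAR_FLOOR_FRAC * sample_var, VAR_FLOOR_MIN)
    degenerate = sample_var == 0.0

    q_means = _quantile_means(X, k)
    rngs = [np.random.default_rng(int(s)) for s in seeds]

    best = None
    for r in range(restarts):
        if r == 0:
            means_init = q_means
        else:
            jitter = np.stack([rng.normal(size=k) for rng in rngs])
            means_init = np.sort(q_means + jitter * (RESTART_JITTER_SD * sample_sd)[:, None], axis=1)
        out = _em_batch(X, k, means_init, sample_var, var_floor, tol, max_iter,
                        record_trace=record_trace)
        if best is None:
            best = list(out)
            continue
        better = out[3] > best[3]  # strict: ties keep the earlier restart
        for field_i in range(6):
            cur, new = best[field_i], out[field_i]
            if cur.ndim == 2:
                cur[better] = new[better]
            else:
                cur[better] = new[better]
        if record_trace:
            for b in np.flatnonzero(better):
                best[6][b] = out[6][b]
    weights, means, var, loglik, converged, n_iter, traces = best

    if degenerate.any():
        # constant input: EM is meaningless, return a collapsed fit
        warnings.warn(
            f"{int(degenerate.sum())} vector(s) with zero sample variance; "
            "returning degenerate mixture fit(s)",
            RuntimeWarning,
            stacklevel=3,
        )
        d = np.flatnonzero(degenerate)
        const = X[d, 0]
        means[d] = const[:, None]
        var[d] = var_floor[d, None]
        weights[d] = 1.0 / k
        logp = _loglik_terms(X[d], means[d], var[d], weights[d])
        loglik[d] = logsumexp(logp, axis=2).sum(axis=1)
        converged[d] = True
        n_iter[d] = 0
    return weights, means, var, loglik, converged, n_iter, traces, degenerate


@dataclass
class BatchMixtureFit:
    """Per-cell mixture fits stored as arrays (one row per cell)."""

    k: int
    weights: np.ndarray    # (B, k)
    means: np.ndarray      # (B, k), ascending per row
    sds: np.ndarray        # (B, k)
    loglik: np.ndarray     # (B,)
    bic: np.ndarray        # (B,)
    n: int
    converged: np.ndarray  # (B,) bool
    n_iter: np.ndarray     # (B,) int
    fallback_used: np.ndarray  # (B,) bool

    def __len__(self) -> int:
        return self.means.shape[0]

    def __getitem__(self, i: int) -> MixtureFit:
        return MixtureFit(
            k=self.k,
            weights=self.weights[i].copy(),
            means=self.means[i].copy(),
            sds=self.sds[i].copy(),
            loglik=float(self.loglik[i]),
            bic=float(self.bic[i]),
            n=self.n,
            converged=bool(self.converged[i]),
            n_iter=int(self.n_iter[i]),
            fallback_used=bool(self.fallback_used[i]),
        )


def fit_cells(
    X: np.ndarray,
    k: int = 2,
    restarts: int = 3,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    chunk_size: int = 8192,
) -> BatchMixtureFit:
    """Fit a k-component mixture to every row of ``X`` (cells x values).

    Restart jitter for row ``i`` is drawn from ``derive_seed(seed, i)``, so
    results are independent of chunking and identical to fitting each row
    separately with :func:`em_fit_1d`.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (cells x values)")
    B, n = X.shape
    if n < k:
        raise ValueError(f"need at least k={k} observations per row, got {n}")
    if not np.all(np.isfinite(X)):
        raise ValueError("values must be finite")
    seeds = np.array([derive_seed(seed, i) for i in range(B)], dtype=np.uint64)

    parts = []
    for lo in range(0, B, chunk_size):
        hi = min(lo + chunk_size, B)
        parts.append(
            _fit_batch_restarts(X[lo:hi], k, restarts, seeds[lo:hi], tol, max_iter)
        )
    weights = np.concatenate([p[0] for p in parts])
    means = np.concatenate([p[1] for p in parts])
    var = np.concatenate([p[2] for p in parts])
    loglik = np.concatenate([p[3] for p in parts])
    converged = np.concatenate([p[4] for p in parts])
    n_iter = np.concatenate([p[5] for p in parts])
    fallback = np.concatenate([p[7] for p in parts])
    p_free = 3 * k - 1
    bic_arr = 2.0 * loglik - p_free * np.log(n) if n > 1 else np.full(B, np.nan)
    return BatchMixtureFit(
        k=k, weights=weights, means=means, sds=np.sqrt(var), loglik=loglik,
        bic=bic_arr, n=n, converged=converged, n_iter=n_iter, fallback_used=fallback,
    )


def em_fit_1d(
    values: np.ndarray,
    k: int,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    restarts: int = 1,
    seed: int = 0,
) -> MixtureFit:
    """Fit a k-component univariate Gaussian mixture to ``values`` by EM.

    Deterministic quantile initialization on the first start; additional
    restarts jitter the initial means with noise from ``seed`` and the fit
    with the best log-likelihood wins. Per-component variances are unequal
    and floored. Constant input with k >= 2 returns a flagged fallback fit
    (warning, no exception).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < k:
        raise ValueError(f"need at least k={k} observations, got {x.size}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    X = x[None, :]
    weights, means, var, loglik, converged, n_iter, traces, degenerate = (
        _fit_batch_restarts(X, k, restarts, np.array([seed], dtype=np.uint64),
                            tol, max_iter, record_trace=True)
    )
    n = x.size
    fit = MixtureFit(
        k=k,
        weights=weights[0],
        means=means[0],
        sds=np.sqrt(var[0]),
        loglik=float(loglik[0]),
        bic=np.nan,
        n=n,
        converged=bool(converged[0]),
        n_iter=int(n_iter[0]),
        fallback_used=bool(degenerate[0]),
        loglik_trace=np.array(traces[0]) if traces else None,
    )
    fit.bic = bic(fit) if n > 1 else np.nan
    return fit


def sweep_k(
    values: np.ndarray,
    k_max: int = 6,
    restarts: int = 3,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[MixtureFit, list[dict]]:
    """Fit k = 1..k_max and pick the best model by BIC (ties -> smaller k).

    ks exceeding the observation count are skipped and absent from the table.
    Returns ``(best_fit, table)`` with one table row per fitted k.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    x = np.asarray(values, dtype=float).ravel()
    best: MixtureFit | None = None
    table: list[dict] = []
    for k in range(1, k_max + 1):
        if k > x.size:
            break
        fit = em_fit_1d(x, k, tol=tol, max_iter=max_iter, restarts=restarts, seed=seed)
        table.append(
            {"k": k, "bic": fit.bic, "loglik": fit.loglik, "converged": fit.converged}
        )
        if best is None or fit.bic > best.bic:  # strict: ties keep smaller k
            best = fit
    assert best is not None
    return best, table


def sweep_cells(
    X: np.ndarray,
    k_max: int = 6,
    restarts: int = 3,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[np.ndarray, dict[int, BatchMixtureFit]]:
    """Batched BIC sweep over every row of ``X``.

    Returns ``(best_k per row, {k: BatchMixtureFit})``; per-row model choice
    uses the same strict-improvement tie-break toward smaller k as
    :func:`sweep_k`.
    """
    X = np.asarray(X, dtype=float)
    B, n = X.shape
    fits: dict[int, BatchMixtureFit] = {}
    best_k = np.zeros(B, dtype=int)
    best_bic = np.full(B, -np.inf)
    for k in range(1, min(k_max, n) + 1):
        fit = fit_cells(X, k=k, restarts=restarts, seed=seed, tol=tol, max_iter=max_iter)
        fits[k] = fit
        better = fit.bic > best_bic
        best_k[better] = k
        best_bic[better] = fit.bic[better]
    return best_k, fits
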