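"""Conditional Granger causality for multichannel series.

Implements the full inference chain: ordinary-least-squares identification
of the vector autoregression

    Y_n = sum_{k=1..p} A_k Y_{n-k} + U_n,

model-order selection by information criterion, conditional Granger
causality between every ordered channel pair via the state-space
(Riccati-equation) route, pairwise significance by an asymptotic F-test on
full vs. restricted prediction-error variances, and Benjamini-Hochberg FDR
validation of the resulting M x M link matrix.

The state-space route converts the fitted VAR to innovations form

    z_{n+1} = A z_n + K u_n,     y_n = C z_n + u_n,

and obtains the restricted model (driver channel's past excluded) as the
submodel observing only the remaining channels; its innovation covariance
follows from the discrete algebraic Riccati equation.  The conditional GC
from driver i to target j is then

    GC_{i->j | rest} = ln( lambda'_{U_j} / lambda_{U_j} ),

the log-ratio of restricted to full prediction-error variance of the
target.  For testing, the restricted model is an explicit OLS refit
excluding the driver's lags, which makes the classical F statistic on the
residual sums of squares well-defined.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import stats as _stats
from scipy.linalg import solve_discrete_are, LinAlgError
from statsmodels.stats.multitest import multipletests

from .preprocess import WindowedSeries

__all__ = [
    "ConnectivityResult",
    "SingularityError",
    "UnstableModelError",
    "VARModel",
    "conditional_gc_matrix",
    "connectivity",
    "fdr_validate",
    "fit_var",
    "gc_significance",
    "pairwise_gc_matrix",
    "select_order",
]

GC_FLOOR = 1e-12  # values below this are reported as exactly zero


class SingularityError(np.linalg.LinAlgError):
    """Rank-deficient regressor matrix (e.g. duplicated channels)."""


class UnstableModelError(RuntimeError):
    """VAR companion spectral radius >= 1; GC is undefined."""


@dataclasses.dataclass
class VARModel:
    """Least-squares identified VAR(p).

    ``coefficients[k][j, i]`` is the effect of channel i at lag k+1 on
    channel j; ``residual_covariance`` is the maximum-likelihood estimate
    (RSS / N); ``noise_variances`` are its diagonal, the per-channel
    prediction-error variances lambda_{U_m}.
    """

    coefficients: np.ndarray       # (p, M, M)
    residual_covariance: np.ndarray  # (M, M)
    n_samples: int                 # number of regression equations N_eff
    channel_labels: tuple = ()
    mean: np.ndarray | None = None  # removed column means

    @property
    def order(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coefficients.shape[1]

    @property
    def noise_variances(self) -> np.ndarray:
        return np.diag(self.residual_covariance).copy()

    def companion(self) -> np.ndarray:
        p, M, _ = self.coefficients.shape
        comp = np.zeros((M * p, M * p))
        comp[:M, :] = np.hstack(list(self.coefficients))
        if p > 1:
            comp[M:, :-M] = np.eye(M * (p - 1))
        return comp

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    def is_stable(self) -> bool:
        return self.spectral_radius() < 1.0


@dataclasses.dataclass
class ConnectivityResult:
    """Conditional-GC matrix with significance and FDR-validated weights.

    ``gc[i, j]`` is the conditional GC from channel i to channel j
    (diagonal zero); ``weighted`` equals ``gc`` where ``significant`` and
    zero elsewhere.
    """

    labels: tuple
    gc: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    weighted: np.ndarray
    alpha: float
    order: int
    n_samples: int

    def to_dict(self) -> dict:
        def listify(a):
            return [[None if not math.isfinite(v) else float(v) for v in row]
                    for row in np.asarray(a, dtype=float)]
        return {
            "labels": list(self.labels),
            "gc": listify(self.gc),
            "p_values": listify(self.p_values),
            "significant": np.asarray(self.significant, dtype=bool).tolist(),
            "weighted": listify(self.weighted),
            "alpha": float(self.alpha),
            "order": int(self.order),
            "n_samples": int(self.n_samples),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConnectivityResult":
        def arr(rows):
            return np.array([[np.nan if v is None else v for v in row]
                             for row in rows], dtype=float)
        return cls(labels=tuple(d["labels"]), gc=arr(d["gc"]),
                   p_values=arr(d["p_values"]),
                   significant=np.array(d["significant"], dtype=bool),
                   weighted=arr(d["weighted"]), alpha=d["alpha"],
                   order=d["order"], n_samples=d["n_samples"])


def _as_data(series) -> tuple[np.ndarray, int | None]:
    if isinstance(series, WindowedSeries):
        return np.asarray(series.data, dtype=float), series.samples_per_trial
    return np.asarray(series, dtype=float), None


def _design(data: np.ndarray, p: int, samples_per_trial: int | None,
            mask_seams: bool):
    """Lagged design matrix X (N_eff x Mp) and response Y (N_eff x M).

    Column block k (0-based) holds all channels at lag k+1.  With
    ``mask_seams``, regression rows whose lags reach across a trial
    concatenation seam are dropped.
    """
    T, M = data.shape
    if T <= p:
        raise ValueError(f"need more than p={p} samples, got {T}")
    X = np.concatenate([data[p - k:T - k] for k in range(1, p + 1)], axis=1)
    Y = data[p:]
    if mask_seams:
        if samples_per_trial is None:
            raise ValueError("mask_seams requires a trial-concatenated series "
                             "with known samples_per_trial")
        t = np.arange(p, T)
        keep = (t % samples_per_trial) >= p
        if not np.any(keep):
            raise ValueError("mask_seams removed every regression row; "
                             "model order exceeds the per-trial length")
        X, Y = X[keep], Y[keep]
    return X, Y


def fit_var(series, p: int, mask_seams: bool = False) -> VARModel:
    """Identify a VAR(p) by ordinary least squares.

    Accepts a :class:`WindowedSeries` or a plain (T x M) array.  Column
    means are removed before fitting (the VAR has no intercept term).
    """
    data, spt = _as_data(series)
    T, M = data.shape
    if p < 1:
        raise ValueError("model order must be >= 1")
    mean = np.nanmean(data, axis=0)
    if not np.all(np.isfinite(data)):
        raise ValueError("series contains non-finite values; masked channels "
                         "must be dropped before fitting")
    X, Y = _design(data - mean, p, spt, mask_seams)
    n_eff = X.shape[0]
    n_params = M * p
    if n_eff <= n_params + 1:
        raise ValueError(f"insufficient samples: need N_eff > M*p + 1 = "
                         f"{n_params + 1}, got {n_eff}")
    B, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < n_params:
        raise SingularityError(
            "rank-deficient regressor matrix (duplicate or constant "
            f"channels?): rank {rank} < {n_params}")
    resid = Y - X @ B
    sigma = (resid.T @ resid) / n_eff
    coeffs = np.stack([B[k * M:(k + 1) * M].T for k in range(p)])
    labels = tuple(series.labels) if isinstance(series, WindowedSeries) else \
        tuple(str(i) for i in range(M))
    return VARModel(coefficients=coeffs, residual_covariance=sigma,
                    n_samples=n_eff, channel_labels=labels, mean=mean)


def select_order(series, max_order: int = 20, criterion: str = "bic",
                 mask_seams: bool = False) -> int:
    """Model order in 1..max_order minimizing an information criterion.

    All candidate orders are scored on the common sample that drops the
    first ``max_order`` rows, so criteria are comparable.  BIC (default)
    penalizes p * M^2 parameters with ln(N)/N, AIC with 2/N.
    """
    if criterion not in ("bic", "aic"):
        raise ValueError("criterion must be 'bic' or 'aic'")
    data, spt = _as_data(series)
    T, M = data.shape
    if T <= M * max_order + 1:
        raise ValueError(f"insufficient samples for max_order={max_order}: "
                         f"need T > M*max_order + 1 = {M * max_order + 1}")
    if max_order == 1:
        return 1
    mean = data.mean(axis=0)
    X_full, Y = _design(data - mean, max_order, spt, mask_seams)
    n_eff = X_full.shape[0]
    best_p, best_ic = 1, np.inf
    for p in range(1, max_order + 1):
        X = X_full[:, :M * p]
        B, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ B
        sigma = (resid.T @ resid) / n_eff
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue
        penalty = (np.log(n_eff) if criterion == "bic" else 2.0) / n_eff
        ic = logdet + penalty * p * M * M
        if ic < best_ic:
            best_p, best_ic = p, ic
    return best_p


def _innovations_state_space(model: VARModel):
    """(A, C, K) of the innovations form for a fitted VAR."""
    p, M, _ = model.coefficients.shape
    C = np.hstack(list(model.coefficients))     # M x Mp
    A = model.companion()
    K = np.zeros((M * p, M))
    K[:M, :] = np.eye(M)
    return A, C, K


def conditional_gc_matrix(model: VARModel, floor: float = GC_FLOOR) -> np.ndarray:
    """Conditional GC for every ordered channel pair, via state space.

    For each driver i the submodel observing all channels but i is formed
    and its innovation covariance solved from the discrete algebraic
    Riccati equation; ``gc[i, j]`` is the log-ratio of that restricted
    prediction-error variance of target j to the full-model one.  The
    diagonal is zero by convention (self-causality is not defined here).
    """
    if not model.is_stable():
        raise UnstableModelError(
            f"fitted VAR is unstable (spectral radius "
            f"{model.spectral_radius():.4f} >= 1)")
    sigma = np.asarray(model.residual_covariance, dtype=float)
    sigma = 0.5 * (sigma + sigma.T)
    eigmin = float(np.min(np.linalg.eigvalsh(sigma)))
    if eigmin <= 0:
        raise np.linalg.LinAlgError(
            f"residual covariance is not positive definite (min eigenvalue "
            f"{eigmin:.3e}); GC log-ratios are undefined")
    M = model.n_channels
    A, C, K = _innovations_state_space(model)
    Q = K @ sigma @ K.T
    gc = np.zeros((M, M))
    for i in range(M):
        keep = [j for j in range(M) if j != i]
        Cs = C[keep, :]
        R = sigma[np.ix_(keep, keep)]
        S = K @ sigma[:, keep]
        try:
            P = solve_discrete_are(A.T, Cs.T, Q, R, s=S)
        except LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"Riccati solve failed for driver channel {i}: {exc}") from exc
        V = Cs @ P @ Cs.T + R
        for jj, j in enumerate(keep):
            gc[i, j] = np.log(V[jj, jj] / sigma[j, j])
    gc[gc < floor] = 0.0
    return gc


def pairwise_gc_matrix(series, p: int, mask_seams: bool = False) -> np.ndarray:
    """Unconditional (pairwise) GC: each pair fitted as a bivariate VAR.

    Ignores all other channels, so indirect paths leak through; used to
    demonstrate what conditioning removes.
    """
    data, spt = _as_data(series)
    T, M = data.shape
    gc = np.zeros((M, M))
    for i in range(M):
        for j in range(i + 1, M):
            sub = data[:, [i, j]]
            if spt is not None:
                sub_series: object = WindowedSeries(
                    data=sub, window="", component="", labels=(str(i), str(j)),
                    sampling_rate=1.0, samples_per_trial=spt)
            else:
                sub_series = sub
            g = conditional_gc_matrix(fit_var(sub_series, p,
                                              mask_seams=mask_seams))
            gc[i, j], gc[j, i] = g[0, 1], g[1, 0]
    return gc


def gc_significance(series, model: VARModel,
                    mask_seams: bool = False) -> np.ndarray:
    """Asymptotic F-test p-values for every directed pair.

    For each driver i and target j the restricted model refits target j by
    OLS with all of channel i's lags excluded; the statistic

        F = ((RSS_r - RSS_f) / p) / (RSS_f / (N_eff - M p - 1))

    is referred to F(p, N_eff - M p - 1).  The diagonal is NaN (never
    tested).
    """
    data, spt = _as_data(series)
    T, M = data.shape
    p = model.order
    X, Y = _design(data - data.mean(axis=0), p, spt, mask_seams)
    n_eff = X.shape[0]
    dof = n_eff - M * p - 1
    if dof <= 0:
        raise ValueError(f"non-positive denominator degrees of freedom ({dof})")
    B = np.concatenate([model.coefficients[k].T for k in range(p)], axis=0)
    rss_full = np.sum((Y - X @ B) ** 2, axis=0)
    if np.any(rss_full <= 0):
        raise np.linalg.LinAlgError("non-positive full-model residual variance")
    p_values = np.full((M, M), np.nan)
    for i in range(M):
        drop = [k * M + i for k in range(p)]
        Xr = np.delete(X, drop, axis=1)
        Br, _, _, _ = np.linalg.lstsq(Xr, Y, rcond=None)
        rss_r = np.sum((Y - Xr @ Br) ** 2, axis=0)
        fstat = np.clip(rss_r - rss_full, 0.0, None) / p / (rss_full / dof)
        pv = _stats.f.sf(fstat, p, dof)
        for j in range(M):
            if j != i:
                p_values[i, j] = pv[j]
    return p_values


def fdr_validate(p_values: np.ndarray, alpha: float = 0.05,
                 gc: np.ndarray | None = None):
    """Benjamini-Hochberg step-up over the off-diagonal p-values.

    Returns ``(significant, weighted)``: the boolean mask of validated
    links and, if ``gc`` is given, the GC matrix with non-significant
    entries set to zero (else None).
    """
    p_values = np.asarray(p_values, dtype=float)
    M = p_values.shape[0]
    off = ~np.eye(M, dtype=bool)
    pv = p_values[off]
    if np.any(~np.isfinite(pv)) or np.any((pv < 0) | (pv > 1)):
        raise ValueError("off-diagonal p-values must be finite and in [0, 1]")
    significant = np.zeros((M, M), dtype=bool)
    if pv.size:
        reject, _, _, _ = multipletests(pv, alpha=alpha, method="fdr_bh")
        significant[off] = reject
    weighted = None
    if gc is not None:
        weighted = np.where(significant, np.asarray(gc, dtype=float), 0.0)
    return significant, weighted


def connectivity(series, order: int | None = None, max_order: int = 20,
                 criterion: str = "bic", alpha: float = 0.05,
                 mask_seams: bool = False) -> ConnectivityResult:
    """Full per-series analysis: fit, GC, F-test, FDR validation."""
    if order is None:
        order = select_order(series, max_order=max_order, criterion=criterion,
                             mask_seams=mask_seams)
    model = fit_var(series, order, mask_seams=mask_seams)
    gc = conditional_gc_matrix(model)
    p_values = gc_significance(series, model, mask_seams=mask_seams)
    significant, weighted = fdr_validate(p_values, alpha=alpha, gc=gc)
    return ConnectivityResult(labels=model.channel_labels, gc=gc,
                              p_values=p_values, significant=significant,
                              weighted=weighted, alpha=alpha, order=order,
                              n_samples=model.n_samples)
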