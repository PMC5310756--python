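"""Empirical dynamic modeling core: embedding, simplex projection, S-map.

The methods here reconstruct system state from a scalar series via
time-delay (Takens) embedding and forecast one step ahead from the
geometry of the reconstructed attractor:

* **Simplex projection** predicts each point from its ``E + 1`` nearest
  neighbors in lag space, weighted by ``exp(-d_i / d_1)`` where ``d_1`` is
  the distance to the nearest neighbor.  Scanning the embedding dimension
  ``E`` and keeping the best forecast skill estimates the dimensionality
  of the underlying dynamics.
* **S-map** (sequentially locally weighted global linear map) fits, for
  each predictee, a linear regression over *all* library points with
  weights ``exp(-theta * d_i / d_mean)``.  At ``theta = 0`` every point
  gets equal weight and the fit collapses to a single global linear
  autoregression; increasing ``theta`` localizes the fit, allowing
  state-dependent (nonlinear) dynamics.

All forecasts are leave-one-out cross-validated: each predictee's own
(vector, target) pair is withheld from its library, so every prediction is
out-of-sample.  Forecast skill is summarized by rho (Pearson correlation
of observed and predicted), MAE, and RMSE, with a one-sided p-value for
``rho > 0`` from Fisher's z-transformation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import (
    DegenerateGeometryError,
    EmbeddingError,
    NeighborCountError,
    ParameterError,
    SampleSizeError,
)

#: Lower bound on simplex weights, guarding against exp underflow when a
#: neighbor is much farther than the nearest one.
SIMPLEX_WEIGHT_FLOOR = 1e-6

#: Relative singular-value cutoff for the S-map least-squares solve.
SMAP_RCOND = 1e-10


@dataclass(frozen=True)
class EmbeddingConfig:
    """Embedding dimension ``E``, lag ``tau``, and forecast horizon ``tp``.

    Annual data with one-step forecasts uses the defaults ``tau = tp = 1``.
    ``E_max`` bounds the embedding-dimension scan in :func:`select_E`.
    """

    E: int
    tau: int = 1
    tp: int = 1
    E_max: int = 10

    def __post_init__(self) -> None:
        if not 1 <= self.E:
            raise ParameterError(f"E must be >= 1, got {self.E}")
        if self.E > self.E_max:
            raise ParameterError(f"E={self.E} exceeds E_max={self.E_max}")
        if self.tau < 1 or self.tp < 1:
            raise ParameterError("tau and tp must be >= 1")


@dataclass(frozen=True)
class LagLibrary:
    """All valid (lag vector, target) pairs of a series, in time order.

    ``vectors[i] = (y[t], y[t-tau], ..., y[t-(E-1)tau])`` with target
    ``y[t + tp]``, where ``t = time_index[i]`` indexes the prepared series.
    """

    vectors: np.ndarray
    targets: np.ndarray
    time_index: np.ndarray
    tau: int = 1
    tp: int = 1

    @property
    def E(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.targets)


@dataclass(frozen=True)
class ForecastResult:
    """LOOCV predictions and forecast-skill metrics for one series/config."""

    predictions: np.ndarray
    observed: np.ndarray
    rho: float
    mae: float
    rmse: float
    p_rho: float
    E: int
    theta: float
    n_pred: int
    method: str = "simplex"
    saturated: bool = False


def _series_values(series) -> np.ndarray:
    values = getattr(series, "values", series)
    return np.asarray(values, dtype=np.float64)


def embed(series, cfg: EmbeddingConfig) -> LagLibrary:
    """Time-delay embed a prepared series into a lag library.

    A series of length ``n`` yields ``n - (E-1)*tau - tp`` pairs.  The
    forecasting stages additionally need ``E + 2`` pairs (each predictee
    requires ``E + 1`` neighbors after withholding itself) and raise a
    neighbor-count error below that.
    """
    y = _series_values(series)
    n = len(y)
    E, tau, tp = cfg.E, cfg.tau, cfg.tp
    m = n - (E - 1) * tau - tp
    if m < 1:
        raise EmbeddingError(
            f"series of length {n} yields {m} pairs for (E={E}, tau={tau}, "
            f"tp={tp}); need at least 1"
        )
    t = np.arange((E - 1) * tau, n - tp)
    lags = t[:, None] - tau * np.arange(E)[None, :]
    return LagLibrary(
        vectors=y[lags], targets=y[t + tp], time_index=t, tau=tau, tp=tp
    )


def _simplex_weights(d: np.ndarray) -> np.ndarray:
    """Simplex weights for one predictee's sorted-or-not neighbor distances.

    ``u_i = exp(-d_i / d_1)`` with ``d_1 = min(d)``; if the nearest
    neighbor coincides with the predictee (``d_1 = 0``), all zero-distance
    neighbors get weight 1 and the rest weight 0.
    """
    d1 = d.min()
    if d1 == 0.0:
        return (d == 0.0).astype(np.float64)
    return np.maximum(np.exp(-d / d1), SIMPLEX_WEIGHT_FLOOR)


def simplex_forecast_one(
    library: LagLibrary, predictee_index: int, exclusion_radius: int = 0
) -> float:
    """Forecast one library point from the others (the scalar LOOCV step).

    The predictee's own pair — and, if ``exclusion_radius > 0``, all pairs
    within that many time steps — is withheld; the ``E + 1`` nearest
    remaining vectors by Euclidean distance vote with exponentially
    distance-decaying weights.
    """
    X, y, ti = library.vectors, library.targets, library.time_index
    keep = np.abs(ti - ti[predictee_index]) > exclusion_radius
    if exclusion_radius == 0:
        keep = np.arange(len(y)) != predictee_index
    k = library.E + 1
    if keep.sum() < k:
        raise NeighborCountError(
            f"{int(keep.sum())} candidate neighbors < E+1 = {k}"
        )
    d = np.sqrt(((X[keep] - X[predictee_index]) ** 2).sum(axis=1))
    idx = np.argpartition(d, k - 1)[:k]
    w = _simplex_weights(d[idx])
    return float((w * y[keep][idx]).sum() / w.sum())


def _simplex_all(library: LagLibrary, exclusion_radius: int = 0) -> np.ndarray:
    """Vectorized LOOCV simplex predictions for every library point."""
    X, y, ti = library.vectors, library.targets, library.time_index
    m = len(y)
    k = library.E + 1
    D = cdist(X, X)
    excl = np.abs(ti[:, None] - ti[None, :]) <= exclusion_radius
    D[excl] = np.inf
    if m - excl.sum(axis=1).max() < k:
        raise NeighborCountError(
            f"fewer than E+1 = {k} candidate neighbors remain"
        )
    idx = np.argpartition(D, k - 1, axis=1)[:, :k]
    d = np.take_along_axis(D, idx, axis=1)
    d1 = d.min(axis=1, keepdims=True)
    zero_rows = (d1 == 0.0)[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.maximum(np.exp(-d / np.where(d1 > 0, d1, 1.0)), SIMPLEX_WEIGHT_FLOOR)
    if zero_rows.any():
        w[zero_rows] = (d[zero_rows] == 0.0).astype(np.float64)
    t = library.targets[idx]
    return (w * t).sum(axis=1) / w.sum(axis=1)


def _skill(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, float, float]:
    err = predicted - observed
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    so = np.std(observed)
    sp = np.std(predicted)
    if so == 0.0 or sp == 0.0:
        rho = 0.0  # correlation undefined for a constant side
    else:
        rho = float(np.corrcoef(observed, predicted)[0, 1])
        rho = float(np.clip(rho, -1.0, 1.0))
    return rho, mae, rmse


def fisher_z_pvalue(rho: float, n_pred: int) -> float:
    """One-sided p-value for ``rho > 0`` via Fisher's z-transformation.

    ``z = atanh(rho)`` is approximately Normal(atanh(true rho),
    1/(n-3)); the p-value is the upper tail of ``z * sqrt(n_pred - 3)``
    under the null of zero correlation.  ``|rho| = 1`` saturates the
    transform and returns ``p = 0`` (callers flag this).
    """
    if n_pred < 4:
        raise SampleSizeError(f"Fisher z needs n_pred >= 4, got {n_pred}")
    if not -1.0 <= rho <= 1.0:
        raise ParameterError(f"rho must lie in [-1, 1], got {rho}")
    if abs(rho) == 1.0:
        return 0.0
    z = math.atanh(rho) * math.sqrt(n_pred - 3)
    # upper-tail standard normal via erfc (identical to norm.sf)
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def _result(
    observed: np.ndarray,
    predicted: np.ndarray,
    E: int,
    theta: float,
    method: str,
) -> ForecastResult:
    rho, mae, rmse = _skill(observed, predicted)
    saturated = abs(rho) == 1.0
    p_rho = fisher_z_pvalue(rho, len(observed))
    return ForecastResult(
        predictions=predicted,
        observed=observed,
        rho=rho,
        mae=mae,
        rmse=rmse,
        p_rho=p_rho,
        E=E,
        theta=theta,
        n_pred=len(observed),
        method=method,
        saturated=saturated,
    )


def simplex_loocv(
    series, cfg: EmbeddingConfig, exclusion_radius: int = 0
) -> ForecastResult:
    """Simplex projection with leave-one-out cross-validation.

    Every (vector, target) pair is predicted with itself withheld from the
    library; skill metrics are computed over all (observed, predicted)
    pairs.
    """
    library = embed(series, cfg)
    predicted = _simplex_all(library, exclusion_radius)
    return _result(library.targets, predicted, cfg.E, 0.0, "simplex")


def _simplex_E_scan_fast(
    y: np.ndarray, E_range, tp: int, exclusion_radius: int
) -> dict[int, ForecastResult]:
    """Per-E simplex LOOCV sharing one pairwise-difference table (tau=1).

    Squared lag-space distances satisfy
    ``D2_{E+1}(t, s) = D2_E(t, s) + (y_{t-E} - y_{s-E})^2``, so the scan
    accumulates one shifted slice of the pairwise table per dimension
    instead of rebuilding a distance matrix from scratch.
    """
    n = len(y)
    Q = (y[:, None] - y[None, :]) ** 2
    scan: dict[int, ForecastResult] = {}
    E_range = sorted(E_range)
    if not E_range or E_range[0] < 1:
        raise ParameterError("E_range must contain integers >= 1")
    hi = n - tp  # t runs over [E-1, n-1-tp]
    M = Q[:hi, :hi].copy()  # squared distances at E = 1
    for E in range(1, E_range[-1] + 1):
        if E > 1:
            if M.shape[0] <= 1:
                break
            M = M[1:, 1:] + Q[: hi - E + 1, : hi - E + 1]
        if E not in E_range:
            continue
        m = M.shape[0]
        k = E + 1
        t = np.arange(E - 1, n - tp)
        D2 = M.copy()
        if exclusion_radius == 0:
            np.fill_diagonal(D2, np.inf)
            n_excl = 1
        else:
            excl = np.abs(t[:, None] - t[None, :]) <= exclusion_radius
            D2[excl] = np.inf
            n_excl = int(excl.sum(axis=1).max())
        if m - n_excl < k or m < 1:
            continue
        idx = np.argpartition(D2, k - 1, axis=1)[:, :k]
        d = np.sqrt(np.take_along_axis(D2, idx, axis=1))
        d1 = d.min(axis=1, keepdims=True)
        zero_rows = (d1 == 0.0)[:, 0]
        w = np.maximum(
            np.exp(-d / np.where(d1 > 0, d1, 1.0)), SIMPLEX_WEIGHT_FLOOR
        )
        if zero_rows.any():
            w[zero_rows] = (d[zero_rows] == 0.0).astype(np.float64)
        targets = y[t + tp]
        preds = (w * targets[idx]).sum(axis=1) / w.sum(axis=1)
        scan[E] = _result(targets, preds, E, 0.0, "simplex")
    return scan


def select_E(
    series,
    E_range=None,
    tau: int = 1,
    tp: int = 1,
    E_max: int = 10,
    metric: str = "rho",
    exclusion_radius: int = 0,
) -> tuple[int, dict[int, ForecastResult]]:
    """Scan embedding dimensions with simplex LOOCV and pick the best.

    ``metric='rho'`` maximizes forecast correlation (default);
    ``metric='mae'`` minimizes mean absolute error.  Ties go to the
    smaller E (parsimony).  Infeasible dimensions (series too short) are
    skipped; if none is feasible an :class:`EmbeddingError` is raised.
    """
    if metric not in ("rho", "mae"):
        raise ParameterError(f"metric must be 'rho' or 'mae', got {metric!r}")
    if E_range is None:
        E_range = range(1, E_max + 1)
    if tau == 1:
        scan = _simplex_E_scan_fast(
            _series_values(series), list(E_range), tp, exclusion_radius
        )
    else:
        scan = {}
        for E in E_range:
            try:
                scan[E] = simplex_loocv(
                    series,
                    EmbeddingConfig(E=E, tau=tau, tp=tp, E_max=max(E_max, E)),
                    exclusion_radius,
                )
            except (EmbeddingError, NeighborCountError):
                continue
    best_E = None
    for E in sorted(scan):
        if best_E is None:
            best_E = E
        elif metric == "rho" and scan[E].rho > scan[best_E].rho:
            best_E = E
        elif metric == "mae" and scan[E].mae < scan[best_E].mae:
            best_E = E
    if best_E is None:
        raise EmbeddingError("no feasible embedding dimension in range")
    return best_E, scan


def _smap_predictions(
    library: LagLibrary,
    thetas: np.ndarray,
    exclusion_radius: int = 0,
    rcond: float = SMAP_RCOND,
) -> np.ndarray:
    """LOOCV S-map predictions for every theta; shape (n_theta, n_pred).

    For each predictee the targets are regressed on (1, lag vector) with
    weights ``exp(-theta * d_i / d_mean)``; the withheld pairs simply get
    weight zero.  The weighted least-squares problems are solved through
    the eigendecomposition of the normal equations — mathematically the
    truncated-SVD solution — with small components cut off at
    ``max(rcond**2, m*eps)`` relative to the largest eigenvalue, the
    numerically meaningful floor for the squared spectrum.
    """
    X, y, ti = library.vectors, library.targets, library.time_index
    m, E = X.shape
    p = E + 1
    A = np.column_stack([np.ones(m), X])
    D = cdist(X, X)
    excl = np.abs(ti[:, None] - ti[None, :]) <= exclusion_radius
    n_incl = m - excl.sum(axis=1)
    if (n_incl < 2).any():
        raise NeighborCountError("too few library points after exclusion")
    Dm = D.copy()
    Dm[excl] = 0.0
    dbar = Dm.sum(axis=1) / n_incl
    if (dbar == 0.0).any():
        raise DegenerateGeometryError(
            "all library points coincide with a predictee (mean distance 0)"
        )
    thetas = np.asarray(thetas, dtype=np.float64)
    T = len(thetas)
    # all thetas at once: one exp, one GEMM, one batched solve; only the
    # upper triangle of the (symmetric) normal matrix is accumulated
    iu_r, iu_c = np.triu_indices(p)
    Ks = A[:, iu_r] * A[:, iu_c]
    R = D / dbar[:, None]
    W = np.exp(-thetas[:, None, None] * R[None, :, :])
    W[:, excl] = 0.0
    Wf = W.reshape(T * m, m)
    Gs = Wf @ Ks
    G = np.empty((T * m, p, p))
    G[:, iu_r, iu_c] = Gs
    G[:, iu_c, iu_r] = Gs
    c = (Wf * y[None, :]) @ A
    beta = _solve_batched(G, c, m, rcond).reshape(T, m, p)
    return np.einsum("ij,tij->ti", A, beta)


def _solve_batched(
    G: np.ndarray, c: np.ndarray, m: int, rcond: float
) -> np.ndarray:
    """Solve the stacked normal equations ``G beta = c``.

    Fast path: batched LU solve.  If any system is singular or produces
    non-finite output, fall back to the truncated eigendecomposition
    (the pseudo-inverse with relative cutoff), which handles degenerate
    weight geometries.
    """
    try:
        beta = np.linalg.solve(G, c[..., None])[..., 0]
        if np.isfinite(beta).all():
            return beta
    except np.linalg.LinAlgError:
        pass
    eps = np.finfo(np.float64).eps
    lam, V = np.linalg.eigh(G)
    tol = lam[:, -1:] * max(rcond**2, m * eps)
    safe = np.where(lam > 0, lam, 1.0)
    inv = np.where(lam > tol, 1.0 / safe, 0.0)
    beta = V @ (inv[..., None] * (np.swapaxes(V, 1, 2) @ c[..., None]))
    return beta[..., 0]


def smap_forecast(
    series,
    cfg: EmbeddingConfig,
    theta: float,
    exclusion_radius: int = 0,
) -> ForecastResult:
    """S-map forecast with LOOCV at a single theta.

    At ``theta = 0`` this is exactly a global linear autoregression of
    order E (with intercept) refitted under leave-one-out; larger theta
    weights library points by proximity to the predictee, tracking
    state-dependent dynamics.
    """
    if theta < 0:
        raise ParameterError(f"theta must be >= 0, got {theta}")
    library = embed(series, cfg)
    predicted = _smap_predictions(library, np.array([theta]), exclusion_radius)[0]
    return _result(library.targets, predicted, cfg.E, float(theta), "smap")
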