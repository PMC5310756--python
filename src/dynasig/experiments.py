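"""Pipeline orchestration: per-series audit and the added-noise experiment.

``run_series`` chains the whole per-series analysis: prepare (trim,
standardize, difference) -> embedding-dimension selection by simplex LOOCV
-> forecast-skill screen -> S-map theta scan and randomization test.  A
series that cannot be analyzed (too short, constant) yields an excluded
verdict with a reason, never a crash.

``run_noise_experiment`` probes whether smooth model-output-like series
owe their apparent linearity to the absence of observation error: i.i.d.
Gaussian noise (default sd 0.3 on the standardized scale) is added to the
standardized series before differencing, the full analysis is repeated for
each of (default) 100 realizations, and forecast skill / nonlinearity
prevalence are summarized across realizations.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .edm_core import EmbeddingConfig, ForecastResult, select_E, simplex_loocv
from .errors import DynasigError, ParameterError
from .nonlinearity_test import (
    DEFAULT_ALPHA,
    DEFAULT_N_SURROGATES,
    DEFAULT_SURROGATE_SCHEME,
    DEFAULT_THETA_GRID,
    NonlinearityResult,
    nonlinearity_randomization_test,
)
from .series_prep import (
    MIN_USABLE_LENGTH,
    PreparedSeries,
    RawSeries,
    first_difference,
    prepare,
    trim_standardize,
)


@dataclass(frozen=True)
class NoiseConfig:
    """Added-observation-error experiment: N(0, sd^2) noise on the
    standardized scale, repeated over independent realizations."""

    sd: float = 0.3
    n_realizations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ParameterError("noise sd must be >= 0")
        if self.n_realizations < 1:
            raise ParameterError("n_realizations must be >= 1")


@dataclass
class AnalysisConfig:
    """Everything the pipeline needs beyond the input series.

    ``trim`` maps series ids to start years (or (start, end) pairs).
    ``reselect_E`` controls whether each noisy realization re-runs the
    embedding-dimension scan (default) or reuses the base series' E.
    """

    E_max: int = 10
    tau: int = 1
    tp: int = 1
    theta_grid: Sequence[float] = DEFAULT_THETA_GRID
    n_surrogates: int = DEFAULT_N_SURROGATES
    alpha: float = DEFAULT_ALPHA
    selection_metric: str = "rho"
    surrogate_scheme: str = DEFAULT_SURROGATE_SCHEME
    exclusion_radius: int = 0
    reselect_E: bool = True
    surrogate_reselect_E: bool = True
    surrogate_early_stop: bool = False
    min_length: int = MIN_USABLE_LENGTH
    trim: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0
    noise: NoiseConfig | None = None

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        noise = raw.pop("noise", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if noise is not None:
            cfg.noise = NoiseConfig(**noise)
        return cfg


@dataclass(frozen=True)
class NoiseSummary:
    """Across-realization summary of the added-noise experiment."""

    mean_rho: float
    sd_rho: float
    fraction_nonlinear: float
    n_realizations: int
    n_failed: int


@dataclass(frozen=True)
class SeriesVerdict:
    """One row of the audit: skill, nonlinearity, and optional noise summary."""

    series_id: str
    category: str
    n_raw: int
    n_prepared: int
    excluded: bool
    exclude_reason: str | None
    forecast: ForecastResult | None
    nonlinearity: NonlinearityResult | None
    noise_summary: NoiseSummary | None = None


def _series_seed(master_seed: int, series_id: str, salt: int = 0) -> np.random.SeedSequence:
    """Deterministic per-series seed, independent of processing order."""
    return np.random.SeedSequence(
        (master_seed & 0x7FFFFFFF, zlib.crc32(series_id.encode()), salt)
    )


def add_observation_noise(
    standardized: np.ndarray, cfg: NoiseConfig, realization_index: int
) -> np.ndarray:
    """Add i.i.d. Normal(0, sd^2) draws to a standardized series.

    The draw stream is a pure function of ``(cfg.seed,
    realization_index)``: the same pair reproduces identical noise and
    distinct indices give independent draws.
    """
    x = np.asarray(standardized, dtype=np.float64)
    if cfg.sd == 0.0:
        return x.copy()
    rng = np.random.default_rng(
        np.random.SeedSequence((cfg.seed & 0x7FFFFFFF, realization_index))
    )
    return x + rng.normal(0.0, cfg.sd, size=len(x))


def _analyze_prepared(
    ps: PreparedSeries,
    config: AnalysisConfig,
    seed_seq: np.random.SeedSequence,
    fixed_E: int | None = None,
) -> tuple[ForecastResult, NonlinearityResult]:
    if fixed_E is None:
        best_E, _ = select_E(
            ps,
            tau=config.tau,
            tp=config.tp,
            E_max=config.E_max,
            metric=config.selection_metric,
            exclusion_radius=config.exclusion_radius,
        )
    else:
        best_E = fixed_E
    best = simplex_loocv(
        ps,
        EmbeddingConfig(E=best_E, tau=config.tau, tp=config.tp, E_max=config.E_max),
        config.exclusion_radius,
    )
    nl = nonlinearity_randomization_test(
        ps,
        E=best_E,
        theta_grid=config.theta_grid,
        n_surrogates=config.n_surrogates,
        seed=seed_seq,
        alpha=config.alpha,
        screen_result=best,
        scheme=config.surrogate_scheme,
        tau=config.tau,
        tp=config.tp,
        exclusion_radius=config.exclusion_radius,
        reselect_E=config.surrogate_reselect_E,
        E_max=config.E_max,
        selection_metric=config.selection_metric,
        early_stop=config.surrogate_early_stop,
    )
    return best, nl


def run_series(raw: RawSeries, config: AnalysisConfig | None = None) -> SeriesVerdict:
    """Full audit of one series; analysis failures become excluded verdicts."""
    config = config or AnalysisConfig()
    try:
        ps = prepare(raw, trim=config.trim.get(raw.id), min_length=config.min_length)
    except DynasigError as exc:
        return SeriesVerdict(
            series_id=raw.id,
            category=raw.category,
            n_raw=len(raw),
            n_prepared=0,
            excluded=True,
            exclude_reason=f"{type(exc).__name__}: {exc}",
            forecast=None,
            nonlinearity=None,
        )
    try:
        best, nl = _analyze_prepared(
            ps, config, _series_seed(config.seed, raw.id)
        )
    except DynasigError as exc:
        return SeriesVerdict(
            series_id=raw.id,
            category=raw.category,
            n_raw=len(raw),
            n_prepared=ps.n,
            excluded=True,
            exclude_reason=f"{type(exc).__name__}: {exc}",
            forecast=None,
            nonlinearity=None,
        )
    return SeriesVerdict(
        series_id=raw.id,
        category=raw.category,
        n_raw=len(raw),
        n_prepared=ps.n,
        excluded=False,
        exclude_reason=None,
        forecast=best,
        nonlinearity=nl,
    )


def run_noise_experiment(
    raw: RawSeries,
    noise_cfg: NoiseConfig,
    config: AnalysisConfig | None = None,
) -> SeriesVerdict:
    """Noise-free audit plus the added-noise realizations for one series.

    Noise is injected on the standardized (pre-differencing) scale; each
    realization is then differenced (not re-standardized) and analyzed
    end-to-end, re-selecting E per realization unless
    ``config.reselect_E`` is false.  Realizations failing the skill screen
    count as linear in the nonlinear fraction; realizations that fail
    outright are excluded from summaries and counted.
    """
    config = config or AnalysisConfig()
    base = run_series(raw, config)
    if base.excluded:
        return base
    std = trim_standardize(
        raw, trim=config.trim.get(raw.id), min_length=config.min_length
    )
    rhos: list[float] = []
    nonlinear: list[bool] = []
    n_failed = 0
    fixed_E = None if config.reselect_E else base.forecast.E
    for r in range(noise_cfg.n_realizations):
        noisy = add_observation_noise(std, noise_cfg, r)
        ps = PreparedSeries(
            id=f"{raw.id}+noise{r}",
            category=raw.category,
            values=first_difference(noisy),
            provenance={"noise_sd": noise_cfg.sd, "realization": r},
        )
        try:
            best, nl = _analyze_prepared(
                ps,
                config,
                _series_seed(noise_cfg.seed, raw.id, salt=r + 1),
                fixed_E=fixed_E,
            )
        except DynasigError:
            n_failed += 1
            continue
        rhos.append(best.rho)
        nonlinear.append(nl.is_nonlinear)
    if rhos:
        summary = NoiseSummary(
            mean_rho=float(np.mean(rhos)),
            sd_rho=float(np.std(rhos, ddof=1)) if len(rhos) > 1 else 0.0,
            fraction_nonlinear=float(np.mean(nonlinear)),
            n_realizations=len(rhos),
            n_failed=n_failed,
        )
    else:
        summary = NoiseSummary(np.nan, np.nan, np.nan, 0, n_failed)
    return replace(base, noise_summary=summary)


def run_analysis(
    series: Iterable[RawSeries],
    config: AnalysisConfig | None = None,
    noise_categories: Sequence[str] = (),
) -> list[SeriesVerdict]:
    """Audit every series; run the noise experiment for listed categories."""
    config = config or AnalysisConfig()
    verdicts = []
    for raw in series:
        if config.noise is not None and raw.category in noise_categories:
            verdicts.append(run_noise_experiment(raw, config.noise, config))
        else:
            verdicts.append(run_series(raw, config))
    return verdicts


def verdicts_to_frame(verdicts: Iterable[SeriesVerdict]) -> pd.DataFrame:
    """Flatten verdicts to the results table (one row per series)."""
    rows = []
    for v in verdicts:
        f, nl, ns = v.forecast, v.nonlinearity, v.noise_summary
        rows.append(
            {
                "series_id": v.series_id,
                "category": v.category,
                "n_raw": v.n_raw,
                "n_prepared": v.n_prepared,
                "excluded": v.excluded,
                "exclude_reason": v.exclude_reason,
                "E": f.E if f else np.nan,
                "rho": f.rho if f else np.nan,
                "p_rho": f.p_rho if f else np.nan,
                "mae": f.mae if f else np.nan,
                "rmse": f.rmse if f else np.nan,
                "best_theta": nl.scan.best_theta if nl and nl.scan else np.nan,
                "delta_mae": nl.scan.delta_mae if nl and nl.scan else np.nan,
                "p_nonlinear": nl.p_value if nl else np.nan,
                "is_nonlinear": bool(nl.is_nonlinear) if nl else False,
                "screened_out": bool(nl.screened_out) if nl else False,
                "noise_mean_rho": ns.mean_rho if ns else np.nan,
                "noise_sd_rho": ns.sd_rho if ns else np.nan,
                "noise_fraction_nonlinear": ns.fraction_nonlinear if ns else np.nan,
            }
        )
    return pd.DataFrame(rows)


def theta_scans_to_frame(verdicts: Iterable[SeriesVerdict]) -> pd.DataFrame:
    """Long-format table of every stored theta scan."""
    rows = []
    for v in verdicts:
        nl = v.nonlinearity
        if nl is None or nl.scan is None:
            continue
        for th, mae, rho in zip(
            nl.scan.thetas, nl.scan.mae_by_theta, nl.scan.rho_by_theta
        ):
            rows.append(
                {
                    "series_id": v.series_id,
                    "E": nl.E_used,
                    "theta": th,
                    "rho": rho,
                    "mae": mae,
                }
            )
    return pd.DataFrame(rows)
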