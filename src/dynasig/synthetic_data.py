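"""Synthetic time-series generators for testing the dynamical-signature audit.

Real inputs to this kind of analysis — commercial landings, ichthyoplankton
surveys, stock-assessment and ecosystem-model biomass trajectories — are not
redistributable, so the package ships generators that emulate their
statistical structure instead:

* deterministic nonlinear maps (chaotic logistic, Ricker, the Lorenz X
  coordinate) stand in for noisy landings/survey data once observation
  noise is layered on;
* linear-stochastic (AR(1)) and periodic (sine) series stand in for series
  whose dynamics a global linear model captures;
* centered moving averages of any base series stand in for model outputs,
  which are smoother and more predictable than the data feeding them.

Every generator is a pure function of its :class:`GeneratorSpec`, seed
included: identical specs reproduce identical series bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import LengthError, ParameterError
from .series_prep import RawSeries

MAP_KINDS = frozenset({"logistic_map", "ricker_map", "ar1", "ar2", "sine"})
KINDS = MAP_KINDS | {"lorenz_x", "smoothed"}

#: Category assigned to each generator kind.
_KIND_CATEGORY = {
    "logistic_map": "synthetic_nonlinear",
    "ricker_map": "synthetic_nonlinear",
    "lorenz_x": "synthetic_nonlinear",
    "ar1": "synthetic_linear",
    "ar2": "synthetic_linear",
    "sine": "synthetic_linear",
}

#: First synthesized year for generated series.
START_YEAR = 1950


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic series.

    Parameters
    ----------
    kind
        Generator family; one of ``logistic_map``, ``ricker_map``, ``ar1``,
        ``sine``, ``lorenz_x`` (``smoothed`` series are made by
        :func:`generate_smoothed_series` from a base series).
    params
        Named real parameters.  Unspecified parameters take the defaults
        below, chosen so the nonlinear kinds sit in a chaotic regime and
        the linear kinds have realistic persistence at series lengths of
        50–200 years:

        * ``logistic_map``: ``r=3.8``, ``x0`` drawn uniform(0.05, 0.95)
        * ``ricker_map``: ``r=3.0``, ``x0`` drawn uniform(0.1, 2.0)
        * ``ar1``: ``phi=0.5``, ``innovation_sd=1.0``
        * ``ar2``: a Gaussian stochastic cycle — an AR(2) with complex
          roots, ``period=20.0`` years, ``damp=0.95`` (root modulus),
          ``innovation_sd=1.0``.  Unlike AR(1) persistence, its
          pseudo-cyclic autocorrelation survives first differencing, which
          makes it the reference *linear* stand-in for smooth model-output
          trajectories.
        * ``sine``: ``period=20.0``, ``amplitude=1.0``, ``phase`` drawn
          uniform(0, 2*pi).  Note that a noisy deterministic oscillation
          is *not* a linear-stochastic process (recovering phase from
          noisy lags is a nonlinear filter), so noisy sines can be
          legitimately classified nonlinear downstream; use ``ar2`` when a
          genuinely linear oscillatory series is required.
        * ``lorenz_x``: ``sigma=10``, ``b=8/3``, ``r=26``, ``step=0.01``,
          ``subsample=10``
    n
        Series length in years, after discarding ``burn_in`` steps.
    obs_noise_sd
        Standard deviation of i.i.d. Gaussian observation noise added to
        the trajectory after generation (0 disables it).  The noise is on
        the trajectory's own scale; generators here produce O(1) values.
    seed
        Seeds the random draws (initial conditions, innovations, noise).
    burn_in
        Transient steps generated and discarded before the ``n`` kept
        values, so kept values sit on the attractor / stationary
        distribution.
    """

    kind: str
    n: int
    params: Mapping[str, float] = field(default_factory=dict)
    obs_noise_sd: float = 0.0
    seed: int = 0
    burn_in: int = 0
    id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ParameterError(f"unknown generator kind {self.kind!r}")
        if self.n < 1:
            raise LengthError("n must be >= 1")
        if self.obs_noise_sd < 0:
            raise ParameterError("obs_noise_sd must be >= 0")
        if self.burn_in < 0:
            raise ParameterError("burn_in must be >= 0")
        object.__setattr__(self, "params", dict(self.params))


def _finish(spec: GeneratorSpec, traj: np.ndarray, rng: np.random.Generator) -> RawSeries:
    values = traj[spec.burn_in :]
    if spec.obs_noise_sd > 0:
        values = values + rng.normal(0.0, spec.obs_noise_sd, size=len(values))
    years = np.arange(START_YEAR, START_YEAR + spec.n)
    sid = spec.id or f"{spec.kind}-{spec.seed}"
    return RawSeries(
        id=sid, category=_KIND_CATEGORY[spec.kind], years=years, values=values
    )


def generate_map_series(spec: GeneratorSpec) -> RawSeries:
    """Generate a discrete-map, AR(1), or sine series.

    The trajectory has ``burn_in + n`` steps; the first ``burn_in`` are
    discarded and observation noise, if any, is added afterwards.
    """
    if spec.kind not in MAP_KINDS:
        raise ParameterError(
            f"generate_map_series handles {sorted(MAP_KINDS)}, not {spec.kind!r}"
        )
    rng = np.random.default_rng(spec.seed)
    total = spec.burn_in + spec.n
    p = spec.params

    if spec.kind == "logistic_map":
        r = float(p.get("r", 3.8))
        if not 0.0 < r <= 4.0:
            raise ParameterError(f"logistic map needs 0 < r <= 4, got {r}")
        x0 = float(p.get("x0", rng.uniform(0.05, 0.95)))
        if not 0.0 < x0 < 1.0:
            raise ParameterError(f"logistic map needs 0 < x0 < 1, got {x0}")
        traj = np.empty(total)
        x = x0
        traj[0] = x
        for t in range(1, total):
            x = r * x * (1.0 - x)
            traj[t] = x
    elif spec.kind == "ricker_map":
        r = float(p.get("r", 3.0))
        if r <= 0:
            raise ParameterError(f"Ricker map needs r > 0, got {r}")
        x0 = float(p.get("x0", rng.uniform(0.1, 2.0)))
        if x0 <= 0:
            raise ParameterError(f"Ricker map needs x0 > 0, got {x0}")
        traj = np.empty(total)
        x = x0
        traj[0] = x
        for t in range(1, total):
            x = x * np.exp(r * (1.0 - x))
            traj[t] = x
    elif spec.kind == "ar2":
        period = float(p.get("period", 20.0))
        damp = float(p.get("damp", 0.95))
        if period <= 2:
            raise ParameterError("ar2 period must exceed 2 years")
        if not 0.0 < damp < 1.0:
            raise ParameterError(f"stationary ar2 needs 0 < damp < 1, got {damp}")
        sd = float(p.get("innovation_sd", 1.0))
        if sd < 0:
            raise ParameterError("innovation_sd must be >= 0")
        a1 = 2.0 * damp * np.cos(2.0 * np.pi / period)
        a2 = -(damp**2)
        eps = rng.normal(0.0, sd, size=total)
        traj = np.zeros(total)
        for t in range(2, total):
            traj[t] = a1 * traj[t - 1] + a2 * traj[t - 2] + eps[t]
    elif spec.kind == "ar1":
        phi = float(p.get("phi", 0.5))
        if not abs(phi) < 1.0:
            raise ParameterError(f"stationary AR(1) needs |phi| < 1, got {phi}")
        sd = float(p.get("innovation_sd", 1.0))
        if sd < 0:
            raise ParameterError("innovation_sd must be >= 0")
        eps = rng.normal(0.0, sd, size=total)
        traj = np.empty(total)
        # start at the stationary distribution so burn_in is not critical
        stat_sd = sd / np.sqrt(1.0 - phi**2) if sd > 0 else 0.0
        traj[0] = rng.normal(0.0, stat_sd) if stat_sd > 0 else 0.0
        for t in range(1, total):
            traj[t] = phi * traj[t - 1] + eps[t]
    else:  # sine
        period = float(p.get("period", 20.0))
        if period <= 0:
            raise ParameterError("sine period must be > 0")
        amplitude = float(p.get("amplitude", 1.0))
        phase = float(p.get("phase", rng.uniform(0.0, 2.0 * np.pi)))
        t = np.arange(total, dtype=np.float64)
        traj = amplitude * np.sin(2.0 * np.pi * t / period + phase)

    return _finish(spec, traj, rng)


def _lorenz_rk4(state: np.ndarray, dt: float, sigma: float, b: float, r: float,
                nsteps: int, keep_every: int) -> np.ndarray:
    """Fixed-step RK4 integration of the Lorenz system; returns kept X values."""

    def deriv(s):
        x, y, z = s
        return np.array([sigma * (y - x), x * (r - z) - y, x * y - b * z])

    kept = np.empty(nsteps // keep_every + 1)
    kept[0] = state[0]
    k = 1
    s = state.astype(np.float64).copy()
    for i in range(1, nsteps + 1):
        k1 = deriv(s)
        k2 = deriv(s + 0.5 * dt * k1)
        k3 = deriv(s + 0.5 * dt * k2)
        k4 = deriv(s + dt * k3)
        s = s + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if i % keep_every == 0:
            kept[k] = s[0]
            k += 1
    return kept[:k]


def generate_lorenz_series(spec: GeneratorSpec) -> RawSeries:
    """X coordinate of the Lorenz system (defaults sigma=10, b=8/3, r=26).

    Integrated with fixed-step fourth-order Runge–Kutta (default step
    0.01), with 1000 integration steps of transient discarded before
    sampling and the trajectory subsampled every ``subsample``-th step
    (default 10) so consecutive kept points decorrelate enough to act as
    yearly observations.  ``burn_in`` adds further *kept-sample* burn-in on
    top of the integration transient.
    """
    if spec.kind != "lorenz_x":
        raise ParameterError("generate_lorenz_series requires kind='lorenz_x'")
    p = spec.params
    sigma = float(p.get("sigma", 10.0))
    b = float(p.get("b", 8.0 / 3.0))
    r = float(p.get("r", 26.0))
    dt = float(p.get("step", 0.01))
    keep_every = int(p.get("subsample", 10))
    transient = int(p.get("transient_steps", 1000))
    if dt <= 0:
        raise ParameterError(f"step size must be positive, got {dt}")
    if keep_every < 1:
        raise ParameterError("subsample must be >= 1")

    rng = np.random.default_rng(spec.seed)
    if "x0" in p or "y0" in p or "z0" in p:
        state = np.array(
            [float(p.get("x0", 0.0)), float(p.get("y0", 0.0)), float(p.get("z0", 0.0))]
        )
    else:
        # random point near the attractor; exact origin is a fixed point
        state = rng.normal(0.0, 1.0, size=3) + np.array([1.0, 1.0, 20.0])

    total_kept = spec.burn_in + spec.n
    nsteps = transient + total_kept * keep_every
    kept = _lorenz_rk4(state, dt, sigma, b, r, nsteps, keep_every)
    traj = kept[-total_kept:]
    return _finish(spec, traj, rng)


def generate_smoothed_series(base: RawSeries, window: int) -> RawSeries:
    """Centered moving average of ``base``; the model-output stand-in.

    Assessment and ecosystem models act as smoothers of their noisy
    inputs; a centered moving average reproduces that signature (reduced
    variance, higher predictability, more linear dynamics) without
    simulating any actual model.  Length is preserved: at the edges the
    window shrinks symmetrically.  Even windows are widened to the next
    odd integer so the average stays centered.
    """
    n = len(base)
    if window < 1:
        raise ParameterError("window must be >= 1")
    if window > n:
        raise LengthError(f"window {window} exceeds series length {n}")
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = base.values[i - k : i + k + 1].mean()
    return RawSeries(
        id=f"{base.id}-sm{window}",
        category="synthetic_smoothed",
        years=base.years,
        values=out,
    )


def generate(spec: GeneratorSpec) -> RawSeries:
    """Dispatch on ``spec.kind`` (``smoothed`` is not handled here)."""
    if spec.kind == "lorenz_x":
        return generate_lorenz_series(spec)
    return generate_map_series(spec)


def simulate_table(entries, master_seed: int = 0) -> list[RawSeries]:
    """Build a list of series from config entries.

    Each entry is a mapping with ``kind``, ``n``, and optionally ``count``
    (default 1), ``params``, ``obs_noise_sd``, ``burn_in``, ``id_prefix``,
    ``category`` (override), and ``smooth_window`` (post-smooth the series,
    making it ``synthetic_smoothed``).  Per-series seeds are spawned
    deterministically from ``master_seed``.
    """
    out: list[RawSeries] = []
    ss = np.random.SeedSequence(master_seed)
    total = sum(int(e.get("count", 1)) for e in entries)
    children = ss.spawn(total)
    idx = 0
    for e in entries:
        count = int(e.get("count", 1))
        prefix = e.get("id_prefix", e["kind"])
        for j in range(count):
            seed = int(children[idx].generate_state(1)[0] % (2**31))
            idx += 1
            spec = GeneratorSpec(
                kind=e["kind"],
                n=int(e["n"]),
                params=e.get("params", {}),
                obs_noise_sd=float(e.get("obs_noise_sd", 0.0)),
                seed=seed,
                burn_in=int(e.get("burn_in", 0)),
                id=f"{prefix}-{j:03d}",
            )
            series = generate(spec)
            if "smooth_window" in e:
                series = generate_smoothed_series(series, int(e["smooth_window"]))
                series = RawSeries(
                    id=f"{prefix}-{j:03d}",
                    category=series.category,
                    years=series.years,
                    values=series.values,
                )
            if "category" in e:
                series = RawSeries(
                    id=series.id,
                    category=e["category"],
                    years=series.years,
                    values=series.values,
                )
            out.append(series)
    return out
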