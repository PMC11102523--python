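"""Calibration of the model to daily view-count series.

The observable is the daily view count ``g_i`` of a video on day i.  Its
prefix sum ``<R>_i = sum_{k<=i} g_k`` is identified with the recovered class
R(t) of the model (everyone who has watched).  Parameters are estimated by
normalized ordinary least squares::

    Er(theta) = sum_i [<R>_i - R(t_i; theta)]^2 / ((max_i <R>_i)^2 * t_max)

minimized with the Nelder-Mead simplex over a feasibility-preserving
reparameterization: log-space for (beta, alpha, gamma, b) enforces
positivity, and beta1 = beta * sigmoid(u) enforces 0 < beta1 < beta.  The
simplex search is initialization-sensitive, so the fit runs a small number
of jittered restarts and keeps the best.

The interface follows the Model/Results convention: build a
:class:`ViewCountModel` from a :class:`ViewSeries`, call :meth:`~ViewCountModel.fit`,
inspect the returned :class:`ViewCountResults` (``.params``, ``.er``,
``.summary()``, ``.fitted_cumulative()``, ``.daily_views()``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize

from .dynamics import ModelState, Trajectory, integrate
from .params import ModelParams

__all__ = [
    "ViewSeries",
    "FitConfig",
    "ViewCountModel",
    "ViewCountResults",
    "cumulative_from_daily",
    "model_daily_views",
    "cost_Er",
    "fit",
]

PARAM_NAMES = ("beta", "beta1", "alpha", "gamma", "b")


@dataclass(frozen=True)
class ViewSeries:
    """Daily views g_i on integer days 0..n and their exact prefix sums."""

    days: np.ndarray
    daily: np.ndarray
    cumulative: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "days", np.asarray(self.days))
        object.__setattr__(self, "daily", np.asarray(self.daily, dtype=float))
        object.__setattr__(self, "cumulative", np.asarray(self.cumulative, dtype=float))
        if not (len(self.days) == len(self.daily) == len(self.cumulative)):
            raise ValueError("days, daily, cumulative must have equal length")
        if np.any(self.daily < 0):
            raise ValueError("daily view counts must be nonnegative")
        if not np.allclose(self.cumulative, np.cumsum(self.daily)):
            raise ValueError("cumulative must be the prefix sum of daily")

    @property
    def t_max(self) -> float:
        """Largest day index of the series."""
        return float(self.days[-1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"day": self.days, "views": self.daily})


def cumulative_from_daily(daily) -> ViewSeries:
    """Build a :class:`ViewSeries` from daily counts on days 0..n."""
    daily = np.asarray(daily, dtype=float)
    if daily.ndim != 1 or len(daily) == 0:
        raise ValueError("daily must be a nonempty 1-D sequence")
    if np.any(daily < 0):
        raise ValueError("daily view counts must be nonnegative")
    days = np.arange(len(daily))
    return ViewSeries(days=days, daily=daily, cumulative=np.cumsum(daily))


def model_daily_views(trajectory: Trajectory, days=None) -> np.ndarray:
    """Model daily views G(i) = R(i) - R(i-1) on integer days, G(0) := 0."""
    if days is None:
        days = np.arange(int(np.floor(trajectory.times[-1])) + 1)
    days = np.asarray(days, dtype=float)
    R = np.interp(days, trajectory.times, trajectory.R)
    G = np.empty_like(R)
    G[0] = 0.0
    G[1:] = np.diff(R)
    return G


@dataclass(frozen=True)
class FitConfig:
    """Settings of the least-squares fit.

    The audience size is not observable, so S0 defaults to 2e9 (the platform's
    public active-user figure) and I0 to a token 100 initial sharers; R0 = 0.
    """

    free_params: tuple[str, ...] = PARAM_NAMES
    theta0: ModelParams | None = None
    S0: float = 2e9
    I0: float = 100.0
    max_iter: int = 4000
    tolerance: float = 1e-10
    n_restarts: int = 5
    seed: int = 0
    jitter: float = 0.35  # restart spread in transformed space
    early_stop_er: float = 1e-9
    ode_rtol: float = 1e-7

    def __post_init__(self) -> None:
        unknown = set(self.free_params) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown free parameters: {sorted(unknown)}")
        if not self.free_params:
            raise ValueError("free_params must not be empty")


DEFAULT_THETA0 = ModelParams(beta=0.5, beta1=0.05, alpha=0.05, b=1e-3, gamma=1e-5)


def _predict_R(params: ModelParams, S0: float, I0: float, days: np.ndarray, rtol: float) -> np.ndarray:
    """R(t) at the requested days from the reduced 2-D system.

    R follows from the linear first integral R = S0+I0 + b*N*t - S - I, which
    halves the ODE dimension inside the optimizer's inner loop.
    """
    N = S0 + I0
    p = params

    def rhs(t, y):
        S, I = y
        adv = p.gamma * N * N / (I + N)
        contact = I * S / N
        return (-p.beta * contact - adv + p.b * N, p.beta1 * contact + adv - p.alpha * I)

    sol = solve_ivp(
        rhs, (0.0, float(days[-1])), (S0, I0),
        method="LSODA", t_eval=days, rtol=rtol, atol=1e-8 * N,
    )
    if not sol.success or sol.y.shape[1] != len(days):
        raise FloatingPointError(f"trajectory evaluation failed: {sol.message}")
    S, I = sol.y
    return N + p.b * N * days - S - I


def cost_Er(series: ViewSeries, params: ModelParams, config: FitConfig) -> float:
    """Normalized least-squares cost Er of ``params`` against the series."""
    r_max = float(series.cumulative.max())
    if r_max <= 0:
        raise ValueError("all-zero view series: the normalization max<R> is undefined")
    if series.t_max <= 0:
        raise ValueError("series must span at least one day (t_max > 0)")
    days = series.days.astype(float)
    R_model = _predict_R(params, config.S0, config.I0, days, config.ode_rtol)
    resid = series.cumulative - R_model
    return float(np.sum(resid**2) / (r_max**2 * series.t_max))


# --- feasibility-preserving reparameterization ------------------------------

def _sigmoid(u: float) -> float:
    return 1.0 / (1.0 + np.exp(-u))


def _logit(r: float) -> float:
    r = min(max(r, 1e-12), 1.0 - 1e-12)
    return float(np.log(r / (1.0 - r)))


def _pack(theta: ModelParams, free: tuple[str, ...]) -> np.ndarray:
    x = []
    for name in free:
        if name == "beta1":
            x.append(_logit(theta.beta1 / theta.beta))
        elif name == "beta" and "beta1" not in free:
            # beta1 fixed: parameterize the positive gap beta - beta1
            x.append(np.log(max(theta.beta - theta.beta1, 1e-300)))
        else:
            x.append(np.log(max(getattr(theta, name), 1e-300)))
    return np.array(x)


def _unpack(x: np.ndarray, theta0: ModelParams, free: tuple[str, ...]) -> ModelParams:
    values = theta0.as_dict()
    pos = {name: i for i, name in enumerate(free)}
    if "beta" in pos:
        if "beta1" in pos:
            values["beta"] = float(np.exp(x[pos["beta"]]))
        else:
            values["beta"] = values["beta1"] + float(np.exp(x[pos["beta"]]))
    for name in ("alpha", "gamma", "b"):
        if name in pos:
            values[name] = float(np.exp(x[pos[name]]))
    if "beta1" in pos:
        values["beta1"] = values["beta"] * _sigmoid(float(x[pos["beta1"]]))
    return ModelParams(**values)


class ViewCountModel:
    """The sharing-plus-advertising model posed against a view-count series.

    Parameters
    ----------
    series
        Observed daily views (day 0..n) with cumulative prefix sums.
    s0, i0
        Initial susceptible pool and initial active sharers; R0 = 0 and the
        reference population is N = s0 + i0.
    free_params
        Names of the rates to estimate; the rest are pinned at ``theta0``.
    theta0
        Starting parameter values (also supplies pinned values).
    """

    def __init__(
        self,
        series: ViewSeries,
        s0: float = 2e9,
        i0: float = 100.0,
        free_params: tuple[str, ...] = PARAM_NAMES,
        theta0: ModelParams | None = None,
    ):
        self.series = series
        self.config = FitConfig(
            free_params=tuple(free_params),
            theta0=theta0,
            S0=float(s0),
            I0=float(i0),
        )

    @classmethod
    def from_dataframe(cls, frame, day_col: str = "day", views_col: str = "views", **kwargs):
        """Build from a DataFrame with day-index and daily-views columns."""
        for col in (day_col, views_col):
            if col not in frame.columns:
                raise ValueError(f"missing column {col!r} in view-count data")
        frame = frame.sort_values(day_col)
        return cls(cumulative_from_daily(frame[views_col].to_numpy()), **kwargs)

    def cost(self, params: ModelParams) -> float:
        return cost_Er(self.series, params, self.config)

    def fit(
        self,
        seed: int | None = None,
        n_restarts: int | None = None,
        max_iter: int | None = None,
        tolerance: float | None = None,
    ) -> "ViewCountResults":
        """Minimize Er by Nelder-Mead with jittered multi-start.

        Deterministic given (series, config, seed).  Restart 0 starts exactly
        at theta0; later restarts jitter the transformed coordinates.  Stops
        early once a restart reaches the near-zero cost floor.
        """
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        n_restarts = cfg.n_restarts if n_restarts is None else n_restarts
        max_iter = cfg.max_iter if max_iter is None else max_iter
        tolerance = cfg.tolerance if tolerance is None else tolerance
        theta0 = cfg.theta0 or DEFAULT_THETA0
        free = cfg.free_params
        rng = np.random.default_rng(seed)
        x0 = _pack(theta0, free)

        def objective(x):
            try:
                return self.cost(_unpack(x, theta0, free))
            except (FloatingPointError, OverflowError, ValueError):
                return 1e12

        best = None
        restart_costs = []
        total_iters = 0
        for j in range(n_restarts):
            start = x0 if j == 0 else x0 + cfg.jitter * rng.standard_normal(len(x0))
            res = minimize(
                objective,
                start,
                method="Nelder-Mead",
                options={
                    "maxiter": max_iter,
                    "maxfev": max_iter,
                    "xatol": 1e-8,
                    "fatol": tolerance,
                    "adaptive": True,
                },
            )
            restart_costs.append(float(res.fun))
            total_iters += int(res.nit)
            if best is None or res.fun < best.fun:
                best = res
            if best.fun < cfg.early_stop_er:
                break

        theta_hat = _unpack(best.x, theta0, free)
        return ViewCountResults(
            model=self,
            params=theta_hat,
            er=float(best.fun),
            converged=bool(best.success),
            iterations=total_iters,
            restart_costs=restart_costs,
            seed=seed,
        )


@dataclass
class ViewCountResults:
    """Estimates and diagnostics of a :class:`ViewCountModel` fit."""

    model: ViewCountModel = field(repr=False)
    params: ModelParams
    er: float
    converged: bool
    iterations: int
    restart_costs: list[float]
    seed: int

    @property
    def beta_ratio(self) -> float:
        """beta1/beta — the per-contact probability of creating a sharer."""
        return self.params.beta_ratio

    def fitted_trajectory(self, t_end: float | None = None, output_grid: float = 1.0) -> Trajectory:
        cfg = self.model.config
        init = ModelState.initial(cfg.S0, cfg.I0)
        if t_end is None:
            t_end = self.model.series.t_max
        return integrate(self.params, init, t_end=t_end, output_grid=output_grid)

    def fitted_cumulative(self) -> np.ndarray:
        """Model R(t_i) on the observed day grid."""
        cfg = self.model.config
        return _predict_R(self.params, cfg.S0, cfg.I0,
                          self.model.series.days.astype(float), cfg.ode_rtol)

    def daily_views(self) -> np.ndarray:
        """Model daily views G(i) on the observed day grid."""
        R = self.fitted_cumulative()
        G = np.empty_like(R)
        G[0] = 0.0
        G[1:] = np.diff(R)
        return G

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Sharing-plus-advertising SIR fit to daily views",
            "=" * 48,
            f"observations: {len(self.model.series.days)} days "
            f"(t_max = {self.model.series.t_max:g})",
            f"S0 = {cfg.S0:g}, I0 = {cfg.I0:g}, N = {cfg.S0 + cfg.I0:g}",
            f"free parameters: {', '.join(cfg.free_params)}",
            "-" * 48,
        ]
        for name in PARAM_NAMES:
            tag = "" if name in cfg.free_params else "  (fixed)"
            lines.append(f"  {name:<6} = {getattr(self.params, name):.6g}{tag}")
        lines += [
            f"  beta1/beta = {self.beta_ratio:.4f}",
            "-" * 48,
            f"Er = {self.er:.6g}   converged = {self.converged}   "
            f"iterations = {self.iterations}   restarts = {len(self.restart_costs)}",
        ]
        return "\n".join(lines)


def fit(series: ViewSeries, config: FitConfig) -> ViewCountResults:
    """Functional wrapper over :class:`ViewCountModel` for a full FitConfig."""
    model = ViewCountModel(
        series,
        s0=config.S0,
        i0=config.I0,
        free_params=config.free_params,
        theta0=config.theta0,
    )
    model.config = config
    return model.fit()
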