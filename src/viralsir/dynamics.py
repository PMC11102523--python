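"""Deterministic dynamics: full 3-D system, reduced 2-D system, fraction form.

The full system, with N held constant at the initial total population::

    S' = -beta*I*S/N - gamma*N^2/(I+N) + b*N
    I' =  beta1*I*S/N + gamma*N^2/(I+N) - alpha*I
    R' =  (beta-beta1)*I*S/N + alpha*I

The component sum is exactly ``b*N``, so ``S+I+R = N0 + b*N*t`` is a linear
first integral (N0 the initial total).  Because R feeds back on nothing, the
(S, I) subsystem is autonomous and is what the equilibrium theory analyses.

The fraction form divides through by a time-varying total population N(t)
growing at rate b, giving an autonomous system in (s, i, r) = (S, I, R)/N
with dilution terms; it is exposed as a right-hand side only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .params import ModelParams

__all__ = [
    "ModelState",
    "FractionState",
    "Trajectory",
    "advertising_load",
    "rhs_full",
    "rhs_reduced",
    "rhs_fractions",
    "integrate",
]


@dataclass(frozen=True)
class ModelState:
    """Compartment sizes (individuals) plus the constant reference population N."""

    S: float
    I: float
    R: float
    N: float

    def __post_init__(self) -> None:
        if min(self.S, self.I, self.R) < 0:
            raise ValueError(f"compartments must be >= 0, got {(self.S, self.I, self.R)}")
        if self.N <= 0:
            raise ValueError(f"N must be > 0, got {self.N}")

    @classmethod
    def initial(cls, S0: float, I0: float, R0: float = 0.0) -> "ModelState":
        """Initial state with N fixed at the starting total S0+I0+R0."""
        return cls(S0, I0, R0, S0 + I0 + R0)


@dataclass(frozen=True)
class FractionState:
    """Compartment fractions s, i, r of the (time-varying) total population."""

    s: float
    i: float
    r: float

    def __post_init__(self) -> None:
        if min(self.s, self.i, self.r) < 0:
            raise ValueError(f"fractions must be >= 0, got {(self.s, self.i, self.r)}")


def advertising_load(gamma: float, N: float, I: float) -> float:
    """Instantaneous advertising recruitment rate ``gamma*N^2/(N+I)``.

    Equals ``gamma*N`` when there are no active sharers and decays to zero as
    sharers proliferate: advertising spend is front-loaded where organic
    sharing cannot yet sustain the spread.
    """
    if N <= 0:
        raise ValueError(f"N must be > 0, got {N}")
    if I < 0:
        raise ValueError(f"I must be >= 0, got {I}")
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    return gamma * N * N / (N + I)


def rhs_full(state: ModelState, params: ModelParams) -> tuple[float, float, float]:
    """Time derivatives (dS/dt, dI/dt, dR/dt) of the full system.

    The components sum to ``b*N`` exactly.
    """
    S, I, N = state.S, state.I, state.N
    p = params
    adv = p.gamma * N * N / (I + N)
    contact = I * S / N
    dS = -p.beta * contact - adv + p.b * N
    dI = p.beta1 * contact + adv - p.alpha * I
    dR = (p.beta - p.beta1) * contact + p.alpha * I
    return dS, dI, dR


def rhs_reduced(S: float, I: float, params: ModelParams, N: float) -> tuple[float, float]:
    """First two components of :func:`rhs_full`: the autonomous (S, I) subsystem."""
    p = params
    adv = p.gamma * N * N / (I + N)
    contact = I * S / N
    return (-p.beta * contact - adv + p.b * N, p.beta1 * contact + adv - p.alpha * I)


def rhs_fractions(frac: FractionState, params: ModelParams) -> tuple[float, float, float]:
    """Right-hand side of the fraction-form system with growing total population.

    The component sum equals ``b*(1 - s - i - r)``, so the simplex
    ``s + i + r = 1`` is invariant.
    """
    s, i, r = frac.s, frac.i, frac.r
    p = params
    adv = p.gamma / (i + 1.0)
    ds = -p.beta * i * s - adv + p.b - p.b * s
    di = p.beta1 * i * s + adv - p.alpha * i - p.b * i
    dr = (p.beta - p.beta1) * i * s + p.alpha * i - r * p.b
    return ds, di, dr


@dataclass
class Trajectory:
    """A sampled deterministic solution of the full system."""

    times: np.ndarray
    S: np.ndarray
    I: np.ndarray
    R: np.ndarray
    N: float
    params: ModelParams | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if not (len(self.times) == len(self.S) == len(self.I) == len(self.R)):
            raise ValueError("times, S, I, R must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def conservation_residual(self) -> np.ndarray:
        """``S+I+R - (N0 + b*N*t)`` at every grid point; zero up to solver tolerance."""
        if self.params is None:
            raise ValueError("trajectory carries no parameters")
        n0 = self.S[0] + self.I[0] + self.R[0]
        return self.S + self.I + self.R - (n0 + self.params.b * self.N * self.times)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.times, "S": self.S, "I": self.I, "R": self.R})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails to produce a solution."""


def integrate(
    params: ModelParams,
    init: ModelState,
    t_end: float,
    output_grid: float = 0.1,
    rtol: float = 1e-8,
    atol: float | None = None,
) -> Trajectory:
    """Integrate the full system with an adaptive 4/5-order Runge-Kutta scheme.

    Parameters
    ----------
    params, init
        Rates and initial compartments; N is taken from ``init.N`` and held
        constant throughout (the constant-N model).
    t_end
        Final time in days (> 0).
    output_grid
        Sampling spacing of the returned grid in days; the solver's internal
        steps remain adaptive.
    rtol, atol
        Solver tolerances; ``atol`` defaults to ``1e-10 * N0``.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    if output_grid <= 0:
        raise ValueError(f"output_grid must be > 0, got {output_grid}")
    n0 = init.S + init.I + init.R
    if atol is None:
        atol = 1e-10 * n0
    N = init.N

    def rhs(t, y):
        S, I = y[0], y[1]
        p = params
        adv = p.gamma * N * N / (I + N)
        contact = I * S / N
        dS = -p.beta * contact - adv + p.b * N
        dI = p.beta1 * contact + adv - p.alpha * I
        dR = (p.beta - p.beta1) * contact + p.alpha * I
        return (dS, dI, dR)

    n_out = int(round(t_end / output_grid))
    t_eval = np.linspace(0.0, t_end, n_out + 1)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        (init.S, init.I, init.R),
        method="RK45",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"solver failed: {sol.message} (params={params}, init={init}, t_end={t_end})"
        )
    S, I, R = sol.y
    # the exact dynamics preserve nonnegativity; clip solver-level undershoot only
    tiny = 10 * atol
    if min(S.min(), I.min(), R.min()) < -tiny:
        raise IntegrationError(
            f"negative path beyond tolerance: min(S,I,R)="
            f"{(S.min(), I.min(), R.min())}"
        )
    return Trajectory(sol.t, np.maximum(S, 0.0), np.maximum(I, 0.0), np.maximum(R, 0.0), N, params)
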