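"""Interior equilibrium and stability of the reduced (S, I) system.

Setting the reduced right-hand side to zero and eliminating S yields a
quadratic in the sharer count I::

    f(I) = A*I**2 + B*I + C,
    A = alpha,
    B = (alpha - (beta1/beta)*b) * N,
    C = -(1 - beta1/beta)*gamma*N**2 - (beta1/beta)*b*N**2.

Because ``beta1 < beta`` forces ``C < 0`` while ``A > 0``, f has exactly one
positive root I*; in the theory regime (``alpha > b > gamma``) that root lies
in (0, N), the susceptible equilibrium S* = S1(I*) = S2(I*) lies between
``S_- = (b - gamma/2) N / beta`` and ``S^- = (alpha - gamma/2) N / beta1``,
and the Jacobian at (S*, I*) has characteristic polynomial
``lambda^2 + B_bar*lambda + C_bar`` with ``B_bar, C_bar > 0`` — both
eigenvalues have negative real part and the equilibrium is globally
asymptotically stable on the open positive quadrant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams

__all__ = [
    "QuadraticCoefficients",
    "EquilibriumReport",
    "StabilityReport",
    "TheoryRegimeError",
    "quadratic_coefficients",
    "interior_equilibrium",
    "stability_report",
    "equilibrium_vs_gamma",
]


class TheoryRegimeError(ValueError):
    """Parameters violate the hypotheses under which the equilibrium theory holds."""


@dataclass(frozen=True)
class QuadraticCoefficients:
    """Coefficients of f(I) = A I^2 + B I + C whose positive root is I*."""

    A: float
    B: float
    C: float

    def __call__(self, I: float) -> float:
        return self.A * I * I + self.B * I + self.C


@dataclass(frozen=True)
class EquilibriumReport:
    """The unique interior equilibrium with its theoretical bracket."""

    S_star: float
    I_star: float
    S_lower: float  # (b - gamma/2) N / beta, infimum of the S1 branch
    S_upper: float  # (alpha - gamma/2) N / beta1, supremum of the S2 branch
    f_at_N: float  # f evaluated at I = N; > 0 certifies I* < N
    coefficients: QuadraticCoefficients
    N: float


@dataclass(frozen=True)
class StabilityReport:
    """Local-stability certificate at the interior equilibrium."""

    jacobian: np.ndarray
    B_bar: float
    C_bar: float
    eigenvalues: tuple[complex, complex]
    stable: bool


def quadratic_coefficients(params: ModelParams, N: float) -> QuadraticCoefficients:
    """Coefficients (A, B, C) of the equilibrium quadratic f(I)."""
    if params.beta <= 0:
        raise ValueError("beta must be > 0 to form the equilibrium quadratic")
    if N <= 0:
        raise ValueError(f"N must be > 0, got {N}")
    ratio = params.beta1 / params.beta
    A = params.alpha
    B = (params.alpha - ratio * params.b) * N
    C = -(1.0 - ratio) * params.gamma * N * N - ratio * params.b * N * N
    return QuadraticCoefficients(A, B, C)


def _require_theory_regime(params: ModelParams) -> None:
    if not params.theory_regime:
        raise TheoryRegimeError(
            "equilibrium theory requires alpha > b > gamma (got "
            f"alpha={params.alpha}, b={params.b}, gamma={params.gamma}); "
            "existence, uniqueness and stability are not established outside "
            "this ordering, so no root is returned"
        )


def interior_equilibrium(params: ModelParams, N: float) -> EquilibriumReport:
    """The unique interior equilibrium (S*, I*) of the reduced system.

    I* is the positive root of f; S* follows from the S-nullcline branch
    ``S1(I) = (N / (beta I)) (bN - gamma N^2 / (N + I))``.  Refuses outside
    the theory regime.
    """
    _require_theory_regime(params)
    coeff = quadratic_coefficients(params, N)
    A, B, C = coeff.A, coeff.B, coeff.C
    disc = B * B - 4.0 * A * C
    # C < 0 (since beta1 < beta) makes the discriminant strictly positive
    assert disc > 0.0, f"discriminant {disc} not positive: C={C}"
    I_star = (-B + np.sqrt(disc)) / (2.0 * A)
    S_star = (N / (params.beta * I_star)) * (params.b * N - params.gamma * N * N / (N + I_star))
    S_lower = (params.b - params.gamma / 2.0) * N / params.beta
    S_upper = (params.alpha - params.gamma / 2.0) * N / params.beta1
    return EquilibriumReport(
        S_star=float(S_star),
        I_star=float(I_star),
        S_lower=float(S_lower),
        S_upper=float(S_upper),
        f_at_N=float(coeff(N)),
        coefficients=coeff,
        N=float(N),
    )


def S1_branch(I: float, params: ModelParams, N: float) -> float:
    """S-nullcline solved for S as a function of I."""
    return (N / (params.beta * I)) * (params.b * N - params.gamma * N * N / (N + I))


def S2_branch(I: float, params: ModelParams, N: float) -> float:
    """I-nullcline solved for S as a function of I."""
    return (N / (params.beta1 * I)) * (params.alpha * I - params.gamma * N * N / (N + I))


def stability_report(params: ModelParams, N: float, eq: EquilibriumReport) -> StabilityReport:
    """Jacobian, characteristic coefficients and eigenvalues at (S*, I*).

    ``B_bar = -trace(J)`` and ``C_bar = det(J)``; both are provably positive
    in the theory regime, so ``stable`` is True there.
    """
    p = params
    S, I = eq.S_star, eq.I_star
    G = p.gamma * N * N / (N + I) ** 2  # derivative magnitude of the advertising term
    J = np.array(
        [
            [-p.beta * I / N, -p.beta * S / N + G],
            [p.beta1 * I / N, p.beta1 * S / N - G - p.alpha],
        ]
    )
    B_bar = p.beta * I / N + p.alpha + G - p.beta1 * S / N
    C_bar = (p.beta - p.beta1) * p.gamma * N * I / (N + I) ** 2 + p.beta * p.alpha * I / N
    eigs = np.roots([1.0, B_bar, C_bar])
    eig_pair = (complex(eigs[0]), complex(eigs[1]))
    stable = all(ev.real < 0 for ev in eig_pair)
    return StabilityReport(
        jacobian=J,
        B_bar=float(B_bar),
        C_bar=float(C_bar),
        eigenvalues=eig_pair,
        stable=stable,
    )


def equilibrium_vs_gamma(params: ModelParams, N: float, gamma_grid):
    """Equilibrium (S*, I*, S*+I*) as the advertising rate gamma is varied.

    Returns a DataFrame with columns ``gamma, S_star, I_star, S_plus_I, in_regime``.
    Grid points that leave the theory regime (gamma >= b) are flagged with
    ``in_regime=False`` and NaN values rather than computed.

    S* decreases and I* increases monotonically in gamma — heavier advertising
    shrinks the steady pool of unaware users and enlarges the pool of active
    sharers — while their sum S*+I* is generally non-monotone, so the
    advertising level that maximises eventual total viewership is interior.
    """
    import pandas as pd

    rows = []
    for g in np.asarray(gamma_grid, dtype=float):
        trial = params.replace(gamma=float(g))
        if not trial.theory_regime:
            rows.append({"gamma": g, "S_star": np.nan, "I_star": np.nan,
                         "S_plus_I": np.nan, "in_regime": False})
            continue
        eq = interior_equilibrium(trial, N)
        rows.append({"gamma": g, "S_star": eq.S_star, "I_star": eq.I_star,
                     "S_plus_I": eq.S_star + eq.I_star, "in_regime": True})
    return pd.DataFrame(rows)
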