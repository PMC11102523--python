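"""Synthetic daily-view series with the statistical structure the fit assumes.

Real view-count series for the calibration case studies exist only as
published figures, so testable inputs are generated here: the deterministic
model supplies the noiseless daily views G(i) = R(i) - R(i-1), and per-day
multiplicative observation noise produces the observed series.

The default noise model is mean-preserving log-normal,
``g_i = G(i) * exp(eps_i - sigma^2/2)`` with ``eps_i ~ Normal(0, sigma^2)``,
so ``E[g_i] = G(i)`` exactly; daily views span orders of magnitude over a
video's lifetime, which makes multiplicative noise the natural choice.  A
Poisson alternative (``g_i ~ Poisson(G(i))``, integer counts) is available
for small-count regimes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import ViewSeries, cumulative_from_daily, model_daily_views
from .dynamics import ModelState, integrate
from .params import ModelParams

__all__ = ["SynthConfig", "generate_view_series"]


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth parameters and observation-noise settings."""

    true_params: ModelParams
    S0: float = 1e6
    I0: float = 100.0
    n_days: int = 200
    noise_sigma: float = 0.05
    seed: int = 0
    noise: str = "lognormal"  # or "poisson"

    def __post_init__(self) -> None:
        if self.n_days < 2:
            raise ValueError(f"n_days must be >= 2, got {self.n_days}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.noise not in ("lognormal", "poisson"):
            raise ValueError(f"noise must be 'lognormal' or 'poisson', got {self.noise!r}")


def generate_view_series(config: SynthConfig) -> tuple[ViewSeries, ViewSeries]:
    """(noisy series, noiseless truth) on days 0..n_days; seeded and repeatable."""
    init = ModelState.initial(config.S0, config.I0)
    traj = integrate(
        config.true_params, init, t_end=float(config.n_days), output_grid=1.0, rtol=1e-9
    )
    G = np.maximum(model_daily_views(traj), 0.0)  # clip integrator-level undershoot
    truth = cumulative_from_daily(G)
    rng = np.random.default_rng(config.seed)
    sigma = config.noise_sigma
    if config.noise == "poisson":
        noisy = rng.poisson(G).astype(float)
    elif sigma == 0:
        noisy = G.copy()
    else:
        eps = rng.normal(0.0, sigma, size=len(G))
        noisy = G * np.exp(eps - sigma * sigma / 2.0)
    return cumulative_from_daily(noisy), truth
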