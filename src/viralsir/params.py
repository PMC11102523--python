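"""Model parameterization for the sharing-plus-advertising SIR system.

The model splits a video's potential audience into susceptibles S (unaware),
infecteds I (active sharers) and recovereds R (watched, stopped sharing).
Five nonnegative daily rates govern the dynamics:

* ``beta`` — contact rate between sharers and susceptibles; every contact
  removes the susceptible from S,
* ``beta1`` — the fraction ``beta1/beta`` of contacts that produce a new
  active sharer (the rest go straight to R), so ``beta > beta1`` is required,
* ``alpha`` — rate at which sharers lose interest and recover,
* ``b`` — inflow of new susceptibles (new platform users), at rate ``b*N``,
* ``gamma`` — advertising investment; advertising recruits susceptibles at
  rate ``gamma*N**2/(N + I)``, maximal (``gamma*N``) when nobody is sharing.

The equilibrium theory (existence, uniqueness, global stability of the
interior fixed point) is proven under the ordering ``alpha > b > gamma``,
exposed here as :attr:`ModelParams.theory_regime`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ModelParams"]


@dataclass(frozen=True)
class ModelParams:
    """The five rates of the sharing-plus-advertising SIR model (per day)."""

    beta: float
    beta1: float
    alpha: float
    b: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("beta", "beta1", "alpha", "b", "gamma"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
        if not self.beta > self.beta1:
            raise ValueError(
                f"beta must exceed beta1 (contacts cannot create sharers at a "
                f"higher rate than they occur); got beta={self.beta}, beta1={self.beta1}"
            )

    @property
    def theory_regime(self) -> bool:
        """True iff ``alpha > b`` and ``b > gamma``.

        This is the parameter ordering under which the interior equilibrium
        exists, is unique, and is globally asymptotically stable.  Equilibrium
        computations refuse to run outside it.
        """
        return self.alpha > self.b and self.b > self.gamma

    @property
    def beta_ratio(self) -> float:
        """``beta1/beta`` — the probability a contact yields an active sharer."""
        return self.beta1 / self.beta

    def as_dict(self) -> dict[str, float]:
        return {
            "beta": self.beta,
            "beta1": self.beta1,
            "alpha": self.alpha,
            "b": self.b,
            "gamma": self.gamma,
        }

    def replace(self, **changes: float) -> "ModelParams":
        return ModelParams(**{**self.as_dict(), **changes})
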