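"""Stochastic agent-based realization of the sharing-plus-advertising model.

Each agent is susceptible, infected (an active sharer) or recovered, and every
viewer carries a *lineage* label tracing how their chain of conversions was
seeded:

* lineage A — the chain roots in one of the initially infected agents,
* lineage B — the chain roots in an agent recruited directly by advertising.

A conversion through person-to-person contact inherits the sharer's lineage
and increments its generation; advertising conversions start a fresh
generation-1, lineage-B chain.  Counting agents by lineage ("Type A" vs
"Type B" viewers) therefore attributes every view to sharing or advertising
through the full transmission tree, not just the direct recruitment event.

One step of length ``tau`` executes four phases with all intensities frozen
at start-of-step values, so the expected one-step increment equals
``tau * rhs_full`` up to O(tau^2):

1. contact — ``P(t)`` draws of an infected agent (uniform, with
   replacement); each draw converts one uniformly chosen susceptible with
   probability ``tau*beta*O(t)/N``; the convert becomes infected with
   probability ``beta1/beta``, else recovered, inheriting lineage and
   generation+1;
2. advertising — ``K ~ Poisson(tau*gamma*N^2/(N+P(t)))``, capped at the
   susceptibles still available, uniformly chosen susceptibles become
   infected with lineage B, generation 1;
3. arrivals — ``floor(b*N*tau + carry)`` new susceptibles (fractional
   remainder carried forward, so cumulative inflow matches the ODE exactly);
4. recovery — each start-of-step infected independently recovers with
   probability ``tau*alpha``.

N in every rate is the *initial* total population, mirroring the constant-N
mean-field model even as arrivals grow the agent count.  In particular the
contact phase uses conversion probability ``tau*beta*O(t)/N`` rather than
"hit a uniformly random member of the grown population", which would dilute
the effective contact rate by the ratio of current to initial population and
drift away from the mean-field solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams

__all__ = [
    "SUSCEPTIBLE",
    "INFECTED",
    "RECOVERED",
    "LINEAGE_NONE",
    "LINEAGE_A",
    "LINEAGE_B",
    "ABMConfig",
    "AgentPopulation",
    "ABMResult",
    "EnsembleResult",
    "StepConfigError",
    "step",
    "run_realization",
    "run_ensemble",
    "child_seed",
]

SUSCEPTIBLE, INFECTED, RECOVERED = 0, 1, 2
LINEAGE_NONE, LINEAGE_A, LINEAGE_B = 0, 1, 2


class StepConfigError(ValueError):
    """A per-draw probability exceeded 1; a smaller tau is required."""


@dataclass(frozen=True)
class ABMConfig:
    """Configuration of a stochastic run."""

    params: ModelParams
    O0: int
    P0: int
    Q0: int = 0
    tau: float = 1.0
    n_steps: int = 100
    seed: int = 0
    realizations: int = 1

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if min(self.O0, self.P0, self.Q0) < 0:
            raise ValueError("initial agent counts must be >= 0")
        if self.n_steps < 0 or self.realizations < 1:
            raise ValueError("n_steps must be >= 0 and realizations >= 1")
        for name, rate in (("beta", self.params.beta), ("alpha", self.params.alpha)):
            if self.tau * rate > 1.0:
                raise StepConfigError(
                    f"tau*{name} = {self.tau * rate:.4g} > 1: per-draw probabilities "
                    f"exceed 1; choose a step length tau < {1.0 / rate:.4g}"
                )

    @property
    def N(self) -> float:
        """Reference population, fixed at the initial agent count."""
        return float(self.O0 + self.P0 + self.Q0)


class AgentPopulation:
    """Flat per-agent arrays (state, lineage, generation) with amortized growth."""

    def __init__(self, O0: int, P0: int, Q0: int, capacity: int | None = None):
        n = O0 + P0 + Q0
        if capacity is None or capacity < n:
            capacity = max(n, 16)
        self.state = np.empty(capacity, dtype=np.int8)
        self.lineage = np.empty(capacity, dtype=np.int8)
        self.generation = np.empty(capacity, dtype=np.int32)
        self.n = n
        self.N_ref = float(n)
        self.carry = 0.0
        # layout: susceptibles first, then initial sharers, then initial recovereds;
        # initial sharers and recovereds root lineage-A chains at generation 1
        self.state[:O0] = SUSCEPTIBLE
        self.lineage[:O0] = LINEAGE_NONE
        self.generation[:O0] = 0
        self.state[O0:O0 + P0] = INFECTED
        self.state[O0 + P0:n] = RECOVERED
        self.lineage[O0:n] = LINEAGE_A
        self.generation[O0:n] = 1

    def _grow_to(self, needed: int) -> None:
        cap = len(self.state)
        if needed <= cap:
            return
        new_cap = max(needed, 2 * cap)
        for name in ("state", "lineage", "generation"):
            old = getattr(self, name)
            fresh = np.empty(new_cap, dtype=old.dtype)
            fresh[: self.n] = old[: self.n]
            setattr(self, name, fresh)

    def add_susceptibles(self, k: int) -> None:
        self._grow_to(self.n + k)
        self.state[self.n:self.n + k] = SUSCEPTIBLE
        self.lineage[self.n:self.n + k] = LINEAGE_NONE
        self.generation[self.n:self.n + k] = 0
        self.n += k

    def counts(self) -> tuple[int, int, int, int, int]:
        """(O, P, Q, typeA, typeB) over the live agents."""
        st = self.state[: self.n]
        li = self.lineage[: self.n]
        O = int(np.count_nonzero(st == SUSCEPTIBLE))
        P = int(np.count_nonzero(st == INFECTED))
        Q = self.n - O - P
        typeA = int(np.count_nonzero(li == LINEAGE_A))
        typeB = int(np.count_nonzero(li == LINEAGE_B))
        return O, P, Q, typeA, typeB


@dataclass
class ABMResult:
    """Per-step compartment and lineage counts of one realization."""

    times: np.ndarray
    O: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    typeA: np.ndarray
    typeB: np.ndarray
    seed: object = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.times, "O": self.O, "P": self.P, "Q": self.Q,
             "typeA": self.typeA, "typeB": self.typeB}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class EnsembleResult:
    """Element-wise ensemble means plus the individual realizations."""

    times: np.ndarray
    O_mean: np.ndarray
    P_mean: np.ndarray
    Q_mean: np.ndarray
    typeA_mean: np.ndarray
    typeB_mean: np.ndarray
    realizations: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.times, "O": self.O_mean, "P": self.P_mean, "Q": self.Q_mean,
             "typeA": self.typeA_mean, "typeB": self.typeB_mean}
        )


def step(pop: AgentPopulation, params: ModelParams, tau: float, rng: np.random.Generator) -> AgentPopulation:
    """Advance the population in place from t to t+tau (four frozen phases)."""
    N = pop.N_ref
    state = pop.state
    live = state[: pop.n]
    inf_idx = np.flatnonzero(live == INFECTED)
    sus_idx = np.flatnonzero(live == SUSCEPTIBLE)
    O, P = len(sus_idx), len(inf_idx)

    p_recover = tau * params.alpha
    p_contact = tau * params.beta * O / N
    if p_contact > 1.0 or p_recover > 1.0:
        raise StepConfigError(
            f"per-draw probability exceeds 1 (tau*beta*O/N={p_contact:.4g}, "
            f"tau*alpha={p_recover:.4g}); choose a smaller tau"
        )

    # phase 1: contact
    if P > 0 and O > 0:
        sharer_draws = rng.integers(0, P, size=P)  # indices into inf_idx
        converting = np.flatnonzero(rng.random(P) < p_contact)
        k = min(len(converting), O)
        if k > 0:
            sharers = inf_idx[sharer_draws[converting[:k]]]
            targets = rng.choice(sus_idx, size=k, replace=False)
            to_infected = rng.random(k) < params.beta1 / params.beta
            state[targets] = np.where(to_infected, INFECTED, RECOVERED)
            pop.lineage[targets] = pop.lineage[sharers]
            pop.generation[targets] = pop.generation[sharers] + 1

    # phase 2: advertising, intensity frozen at start-of-step P
    mean_adv = tau * params.gamma * N * N / (N + P)
    if mean_adv > 0:
        still_sus = sus_idx[state[sus_idx] == SUSCEPTIBLE]
        K = min(int(rng.poisson(mean_adv)), len(still_sus))
        if K > 0:
            recruits = rng.choice(still_sus, size=K, replace=False)
            state[recruits] = INFECTED
            pop.lineage[recruits] = LINEAGE_B
            pop.generation[recruits] = 1

    # phase 3: arrivals with fractional carry
    inflow = params.b * N * tau + pop.carry
    n_new = int(np.floor(inflow))
    pop.carry = inflow - n_new
    if n_new > 0:
        pop.add_susceptibles(n_new)

    # phase 4: recovery of start-of-step infecteds only
    if P > 0 and p_recover > 0:
        recovering = inf_idx[rng.random(P) < p_recover]
        pop.state[recovering] = RECOVERED

    return pop


def run_realization(config: ABMConfig, seed=None) -> ABMResult:
    """One seeded realization; bit-identical for identical (config, seed)."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    per_step_cap = int(np.ceil(config.params.b * config.N * config.tau)) + 1
    pop = AgentPopulation(
        config.O0, config.P0, config.Q0,
        capacity=config.O0 + config.P0 + config.Q0 + per_step_cap * config.n_steps,
    )
    n_rec = config.n_steps + 1
    O = np.empty(n_rec, dtype=np.int64)
    P = np.empty(n_rec, dtype=np.int64)
    Q = np.empty(n_rec, dtype=np.int64)
    tA = np.empty(n_rec, dtype=np.int64)
    tB = np.empty(n_rec, dtype=np.int64)
    O[0], P[0], Q[0], tA[0], tB[0] = pop.counts()
    for k in range(config.n_steps):
        step(pop, config.params, config.tau, rng)
        O[k + 1], P[k + 1], Q[k + 1], tA[k + 1], tB[k + 1] = pop.counts()
    times = config.tau * np.arange(n_rec)
    return ABMResult(times, O, P, Q, tA, tB, seed=seed)


def child_seed(master_seed: int, k: int) -> np.random.SeedSequence:
    """Seed of realization k: the pair (master_seed, k) fed to a SeedSequence."""
    return np.random.SeedSequence([int(master_seed), int(k)])


def run_ensemble(config: ABMConfig) -> EnsembleResult:
    """Average ``config.realizations`` identically-prepared realizations.

    Realization k runs with :func:`child_seed`(config.seed, k), so the
    ensemble is reproducible from the master seed alone and individual
    realizations can be re-run in isolation.
    """
    runs = [
        run_realization(config, seed=child_seed(config.seed, k))
        for k in range(config.realizations)
    ]
    times = runs[0].times
    stack = lambda attr: np.mean([getattr(r, attr) for r in runs], axis=0)  # noqa: E731
    return EnsembleResult(
        times=times,
        O_mean=stack("O"),
        P_mean=stack("P"),
        Q_mean=stack("Q"),
        typeA_mean=stack("typeA"),
        typeB_mean=stack("typeB"),
        realizations=runs,
    )
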