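"""Subtraction-average-based optimizer (SABO).

A population metaheuristic for box-constrained minimization.  Each
agent's displacement is the arithmetic mean of signed "v-subtractions"
against every other agent,

    A -v B = sign(F(A) - F(B)) * (A - v * B),

and a proposal is accepted only if it strictly improves the objective,
so the best-so-far fitness is non-increasing by construction.  Bound
dimensions may be flagged log10-scaled; all displacement arithmetic and
clamping then happen in log space, which is the natural geometry for
multiplicative parameters such as penalty weights and kernel widths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["SearchBounds", "SearchAgent", "SABOConfig", "initialize_population",
           "v_subtraction", "propose_positions", "greedy_accept", "optimize"]


@dataclass
class SearchBounds:
    """Box bounds with optional per-dimension log10 scaling."""

    lower: np.ndarray
    upper: np.ndarray
    scale: list[str] = None

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=float).ravel()
        self.upper = np.asarray(self.upper, dtype=float).ravel()
        if self.lower.size != self.upper.size:
            raise ValueError("lower and upper bounds differ in length")
        if np.any(self.lower > self.upper):
            raise ValueError("lower bound exceeds upper bound")
        if self.scale is None:
            self.scale = ["linear"] * self.lower.size
        if len(self.scale) != self.lower.size:
            raise ValueError("scale list length mismatch")
        for s in self.scale:
            if s not in ("linear", "log10"):
                raise ValueError(f"unknown scale {s!r}")
        self._log = np.array([s == "log10" for s in self.scale])
        if np.any(self._log & (self.lower <= 0)):
            raise ValueError("log10-scaled dimensions need positive bounds")

    @property
    def ndim(self) -> int:
        return self.lower.size

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Natural units -> search space (log10 where flagged)."""
        z = np.array(x, dtype=float)
        z[..., self._log] = np.log10(z[..., self._log])
        return z

    def inverse(self, z: np.ndarray) -> np.ndarray:
        x = np.array(z, dtype=float)
        x[..., self._log] = 10.0 ** x[..., self._log]
        return x

    def clamp(self, x: np.ndarray) -> np.ndarray:
        """Clamp a natural-units position into the box."""
        return np.clip(x, self.lower, self.upper)


@dataclass
class SearchAgent:
    position: np.ndarray
    fitness: float = np.inf


@dataclass
class SABOConfig:
    n_agents: int = 20
    n_iterations: int = 50
    seed: int = 0
    v_choices: tuple = (1.0, 2.0)   # v components drawn uniformly from this set
    v_continuous: bool = False      # alternatively v ~ Uniform[1, 2]

    def __post_init__(self):
        if self.n_agents < 1 or self.n_iterations < 1:
            raise ValueError("n_agents and n_iterations must be >= 1")


def initialize_population(bounds: SearchBounds, config: SABOConfig,
                          rng: np.random.Generator) -> list[SearchAgent]:
    """x_d = lb_d + r_d (ub_d - lb_d), r ~ U[0,1]; log dims sampled in
    log10 space then exponentiated."""
    lo = bounds.transform(bounds.lower)
    hi = bounds.transform(bounds.upper)
    r = rng.uniform(size=(config.n_agents, bounds.ndim))
    z = lo + r * (hi - lo)
    x = bounds.inverse(z)
    return [SearchAgent(position=x[i]) for i in range(config.n_agents)]


def v_subtraction(A, B, fA: float, fB: float, v) -> np.ndarray:
    """sign(fA - fB) * (A - v * B), with elementwise product."""
    A = np.asarray(A, dtype=float).ravel()
    B = np.asarray(B, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if A.size != B.size or v.size != A.size:
        raise ValueError("v_subtraction operands differ in length")
    return np.sign(fA - fB) * (A - v * B)


def _draw_v(rng: np.random.Generator, shape, config: SABOConfig) -> np.ndarray:
    if config.v_continuous:
        return rng.uniform(1.0, 2.0, size=shape)
    return rng.choice(np.asarray(config.v_choices, dtype=float), size=shape)


def propose_positions(agents: list[SearchAgent], rng: np.random.Generator,
                      bounds: SearchBounds | None = None,
                      config: SABOConfig | None = None) -> list[np.ndarray]:
    """New positions X_i + r_i * mean_j (X_i -v X_j), clamped to bounds.

    A fresh v vector is drawn per (i, j) pair and a fresh r per agent.
    When bounds carry log10 dimensions the arithmetic runs in transformed
    space; returned positions are in natural units.
    """
    if config is None:
        config = SABOConfig()
    N = len(agents)
    d = agents[0].position.size
    if bounds is not None:
        pos = np.stack([bounds.transform(a.position) for a in agents])
    else:
        pos = np.stack([np.asarray(a.position, dtype=float) for a in agents])
    fit = np.array([a.fitness for a in agents])
    v = _draw_v(rng, (N, N, d), config)
    r = rng.uniform(size=(N, d))
    sign = np.sign(fit[:, None] - fit[None, :])            # (i, j)
    diff = sign[:, :, None] * (pos[:, None, :] - v * pos[None, :, :])
    disp = diff.mean(axis=1)                               # average over j
    newz = pos + r * disp
    if bounds is not None:
        lo = bounds.transform(bounds.lower)
        hi = bounds.transform(bounds.upper)
        newz = np.clip(newz, lo, hi)
        new = bounds.inverse(newz)
    else:
        new = newz
    return [new[i] for i in range(N)]


def greedy_accept(agents: list[SearchAgent], proposals: list[np.ndarray],
                  fitness_fn) -> list[SearchAgent]:
    """Replace agent i by its proposal iff the proposal's fitness is
    strictly smaller; each proposal is evaluated exactly once."""
    if len(agents) != len(proposals):
        raise ValueError("agents and proposals differ in length")
    out = []
    for agent, prop in zip(agents, proposals):
        try:
            f = float(fitness_fn(prop))
        except Exception as err:  # failed evaluation -> rejected proposal
            logger.warning("fitness evaluation failed at %s: %s", prop, err)
            f = np.inf
        if not np.isfinite(f):
            f = np.inf
        if f < agent.fitness:
            out.append(SearchAgent(position=np.asarray(prop, dtype=float),
                                   fitness=f))
        else:
            out.append(agent)
    return out


def optimize(fitness_fn, bounds: SearchBounds, config: SABOConfig):
    """Run SABO and return (best_position, best_fitness, history).

    ``history`` holds the best-so-far fitness after each of the T
    iterations and is non-increasing.  The total fitness budget is
    N*(T+1): N at initialization plus N per iteration.
    """
    rng = np.random.default_rng(config.seed)
    agents = initialize_population(bounds, config, rng)
    for a in agents:
        try:
            a.fitness = float(fitness_fn(a.position))
        except Exception as err:
            logger.warning("fitness evaluation failed at %s: %s",
                           a.position, err)
            a.fitness = np.inf
        if not np.isfinite(a.fitness):
            a.fitness = np.inf
    best = min(agents, key=lambda a: a.fitness)
    best_pos, best_fit = best.position.copy(), best.fitness
    history = np.empty(config.n_iterations)
    for t in range(config.n_iterations):
        proposals = propose_positions(agents, rng, bounds, config)
        agents = greedy_accept(agents, proposals, fitness_fn)
        cur = min(agents, key=lambda a: a.fitness)
        if cur.fitness < best_fit:
            best_pos, best_fit = cur.position.copy(), cur.fitness
        history[t] = best_fit
    if not np.isfinite(best_fit):
        raise RuntimeError("every SABO fitness evaluation failed")
    return best_pos, best_fit, history
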