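"""Particle swarm optimizer with fitness-adaptive chaotic inertia.

The inertia weight ω multiplies a particle's previous velocity and sets
the exploration/exploitation balance.  Besides the classical choices —
a constant, a linearly decreasing schedule, and two concave decreasing
schedules — this module implements an *improved* scheme that picks the
inertia per particle each iteration from its fitness relative to the
swarm mean:

* a particle doing better than average (q_i < q_avg) follows the concave
  schedule ω = ω_min (ω_max/ω_min)^(1/(1 + 10 k/k_max)), steep early
  (global search) and flat late (fine search), which brakes premature
  convergence of the leaders;
* a particle doing worse than average gets a chaotic inertia
  ω = α + (1 - α) L with α annealed linearly from α_max to α_min and L
  advanced through the logistic map L <- r L (1 - L) (r = 4, fully
  chaotic), kicking laggards out of local optima.

Velocity/position updates follow the standard two-attractor rule with
per-dimension velocity clamping:

    v <- ω v + c1 r1 (pbest - x) + c2 r2 (gbest - x),   x <- x + v.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SwarmConfig",
    "Particle",
    "SwarmState",
    "FitResult",
    "SCHEMES",
    "logistic_step",
    "inertia_concave1",
    "inertia_concave2",
    "inertia_linear",
    "inertia_chaotic",
    "select_inertia",
    "update_particle",
    "run_pso",
]

logger = logging.getLogger(__name__)

SCHEMES = ("improved", "constant", "linear", "concave1", "concave2")

#: logistic-map points with eventually-fixed orbits at r = 4, avoided when
#: seeding the map
_LOGISTIC_BAD = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm hyperparameters and search-space geometry.

    lo/hi are per-dimension position bounds; v_max defaults to 20% of the
    box width per dimension.  ``omega`` is the constant-scheme inertia;
    (omega_min, omega_max) bound the scheduled inertias and
    (alpha_min, alpha_max) bound the chaotic adjustment factor α.
    ``q_stop`` terminates the run early once the global best fitness
    drops below it (0 disables early stopping).
    """

    lo: Sequence[float]
    hi: Sequence[float]
    n_particles: int = 30
    c1: float = 2.0
    c2: float = 2.0
    omega: float = 0.7
    omega_max: float = 0.9
    omega_min: float = 0.4
    alpha_max: float = 0.8
    alpha_min: float = 0.2
    k_max: int = 100
    q_stop: float = 0.0
    scheme: str = "improved"
    logistic_r: float = 4.0
    v_max: Sequence[float] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        lo = np.asarray(self.lo, dtype=float)
        hi = np.asarray(self.hi, dtype=float)
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("lo and hi must be 1-D arrays of equal length")
        if not np.all(lo < hi):
            raise ValueError("require lo < hi elementwise")
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if not 0 < self.omega_min < self.omega_max:
            raise ValueError("require 0 < omega_min < omega_max")
        if not 0 <= self.alpha_min <= self.alpha_max <= 1:
            raise ValueError("require 0 <= alpha_min <= alpha_max <= 1")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; choose from {SCHEMES}")
        if not 0 < self.logistic_r <= 4:
            raise ValueError("logistic_r must lie in (0, 4]")
        v_max = (
            0.2 * (hi - lo)
            if self.v_max is None
            else np.asarray(self.v_max, dtype=float)
        )
        if v_max.shape != lo.shape or np.any(v_max <= 0):
            raise ValueError("v_max must be positive per dimension")
        object.__setattr__(self, "v_max", v_max)

    @property
    def dim(self) -> int:
        return len(self.lo)


@dataclass
class Particle:
    """One swarm member: position, velocity, and its personal best."""

    x: np.ndarray
    v: np.ndarray
    pbest_x: np.ndarray
    pbest_q: float = np.inf


@dataclass
class SwarmState:
    """Mutable swarm state threaded through the iteration loop."""

    k: int
    particles: list[Particle]
    gbest_x: np.ndarray
    gbest_q: float
    logistic_l: float
    q_avg: float = np.inf
    branch_counts: dict = field(default_factory=lambda: {"concave": 0, "chaotic": 0})


@dataclass
class FitResult:
    """Outcome of one optimizer run."""

    best_x: np.ndarray
    best_q: float
    history: list  # (k, gbest_q, gbest_x) per iteration
    iterations_used: int
    termination: str  # "threshold" | "max_iter"
    n_rejected: int = 0  # non-finite objective evaluations
    e_t: float | None = None

    def history_frame(self):
        import pandas as pd

        rows = [
            {"k": k, "gbest_q": q, **{f"gbest_x_{d + 1}": x[d] for d in range(len(x))}}
            for k, q, x in self.history
        ]
        return pd.DataFrame(rows)

    def history_to_csv(self, path: str | Path) -> None:
        self.history_frame().to_csv(Path(path), index=False)

    def to_json(self, path: str | Path) -> None:
        d = {
            "best_x": np.asarray(self.best_x).tolist(),
            "best_q": self.best_q,
            "iterations_used": self.iterations_used,
            "termination": self.termination,
            "n_rejected": self.n_rejected,
            "e_t": self.e_t,
        }
        Path(path).write_text(json.dumps(d, indent=1))


def logistic_step(l: float, r: float = 4.0) -> float:
    """One iterate of the logistic map, L <- r L (1 - L); maps [0,1] into
    itself for r <= 4."""
    if not 0 <= l <= 1:
        raise ValueError(f"logistic state must lie in [0, 1], got {l}")
    return r * l * (1.0 - l)


def inertia_linear(k: int, k_max: int, omega_min: float, omega_max: float) -> float:
    """Linearly decreasing inertia: ω_max at k = 0 down to ω_min at k_max."""
    return omega_max - (omega_max - omega_min) * (k / k_max)


def inertia_concave1(k: int, k_max: int, omega_min: float, omega_max: float) -> float:
    """First concave schedule ω = ω_min (ω_max/ω_min)^(1/(1 + 10 k/k_max)).

    Starts at ω_max and decreases steeply, flattening toward (but not
    reaching) ω_min.
    """
    if k_max == 0:
        raise ValueError("k_max must be positive")
    return omega_min * (omega_max / omega_min) ** (1.0 / (1.0 + 10.0 * k / k_max))


def inertia_concave2(k: int, k_max: int, omega_min: float, omega_max: float) -> float:
    """Second concave schedule, the quadratic
    ω = (ω_max - ω_min)(k/k_max)² + 2(ω_min - ω_max)(k/k_max) + ω_max,
    decreasing from ω_max to ω_min with zero slope at k_max."""
    u = k / k_max
    return (omega_max - omega_min) * u**2 + 2.0 * (omega_min - omega_max) * u + omega_max


def inertia_chaotic(
    k: int, k_max: int, alpha_max: float, alpha_min: float, l: float
) -> float:
    """Chaotic inertia ω = α + (1 - α) L with α annealed from α_max to
    α_min over the run; ω lies in [α, 1]."""
    if not 0 <= l <= 1:
        raise ValueError("logistic value must lie in [0, 1]")
    alpha = alpha_max - (alpha_max - alpha_min) * (k / k_max)
    if not 0 <= alpha <= 1:
        raise ValueError(f"adjustment factor outside [0, 1]: {alpha}")
    return alpha + (1.0 - alpha) * l


def select_inertia(
    q_id: float, q_avg: float, state: SwarmState, cfg: SwarmConfig
) -> float:
    """Improved-scheme inertia for one particle.

    Better-than-average particles (q_id <= q_avg; ties go to the
    conservative branch) take the concave schedule; worse-than-average
    particles take the chaotic inertia, advancing the shared logistic
    map by one step per invocation.
    """
    if q_id <= q_avg:
        state.branch_counts["concave"] += 1
        return inertia_concave1(state.k, cfg.k_max, cfg.omega_min, cfg.omega_max)
    state.branch_counts["chaotic"] += 1
    state.logistic_l = logistic_step(state.logistic_l, cfg.logistic_r)
    return inertia_chaotic(
        state.k, cfg.k_max, cfg.alpha_max, cfg.alpha_min, state.logistic_l
    )


def update_particle(
    p: Particle,
    gbest_x: np.ndarray,
    omega: float,
    cfg: SwarmConfig,
    rng: np.random.Generator,
) -> None:
    """In-place velocity/position update with clamping.

    Fresh uniform r1, r2 are drawn per dimension.  Velocity components
    are clamped to ±v_max; positions are clamped to [lo, hi] with the
    velocity zeroed on any clamped dimension.
    """
    d = cfg.dim
    r1 = rng.uniform(size=d)
    r2 = rng.uniform(size=d)
    p.v = (
        omega * p.v
        + cfg.c1 * r1 * (p.pbest_x - p.x)
        + cfg.c2 * r2 * (gbest_x - p.x)
    )
    np.clip(p.v, -cfg.v_max, cfg.v_max, out=p.v)
    p.x = p.x + p.v
    hit = (p.x < cfg.lo) | (p.x > cfg.hi)
    if np.any(hit):
        np.clip(p.x, cfg.lo, cfg.hi, out=p.x)
        p.v[hit] = 0.0


def _scheduled_inertia(scheme: str, k: int, cfg: SwarmConfig) -> float:
    if scheme == "constant":
        return cfg.omega
    if scheme == "linear":
        return inertia_linear(k, cfg.k_max, cfg.omega_min, cfg.omega_max)
    if scheme == "concave1":
        return inertia_concave1(k, cfg.k_max, cfg.omega_min, cfg.omega_max)
    if scheme == "concave2":
        return inertia_concave2(k, cfg.k_max, cfg.omega_min, cfg.omega_max)
    raise ValueError(scheme)


def _seed_logistic(rng: np.random.Generator) -> float:
    l = rng.uniform()
    while any(abs(l - b) < 1e-6 for b in _LOGISTIC_BAD):
        l = rng.uniform()
    return l


def run_pso(
    objective: Callable[[np.ndarray], float],
    cfg: SwarmConfig,
    callback: Callable[[SwarmState], None] | None = None,
) -> FitResult:
    """Minimize ``objective`` over the box [lo, hi] with the configured
    inertia scheme.

    Positions start uniform in the box and velocities uniform in
    ±v_max.  Each iteration evaluates every particle once, updates
    personal/global bests, then moves the swarm; the run stops at
    ``k_max`` iterations or as soon as the global best fitness drops
    below ``q_stop``.  Non-finite objective values are treated as +inf
    (the position is rejected) and counted.  Fully reproducible per
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    d = cfg.dim
    particles = [
        Particle(
            x=rng.uniform(cfg.lo, cfg.hi),
            v=rng.uniform(-cfg.v_max, cfg.v_max),
            pbest_x=np.zeros(d),
        )
        for _ in range(cfg.n_particles)
    ]
    for p in particles:
        p.pbest_x = p.x.copy()
    state = SwarmState(
        k=0,
        particles=particles,
        gbest_x=particles[0].x.copy(),
        gbest_q=np.inf,
        logistic_l=_seed_logistic(rng),
    )
    history: list = []
    n_rejected = 0
    termination = "max_iter"
    iterations = 0
    for k in range(cfg.k_max):
        state.k = k
        qs = np.empty(cfg.n_particles)
        for i, p in enumerate(particles):
            q = float(objective(p.x))
            if not np.isfinite(q):
                n_rejected += 1
                logger.debug("rejected non-finite fitness at x=%s", p.x)
                q = np.inf
            qs[i] = q
            if q < p.pbest_q:
                p.pbest_q = q
                p.pbest_x = p.x.copy()
            if q < state.gbest_q:
                state.gbest_q = q
                state.gbest_x = p.x.copy()
        finite = qs[np.isfinite(qs)]
        state.q_avg = float(finite.mean()) if len(finite) else np.inf
        iterations = k + 1
        history.append((k, state.gbest_q, state.gbest_x.copy()))
        if callback is not None:
            callback(state)
        logger.debug(
            "k=%d gbest_q=%.6g q_avg=%.6g branches=%s",
            k, state.gbest_q, state.q_avg, state.branch_counts,
        )
        if state.gbest_q < cfg.q_stop:
            termination = "threshold"
            break
        if cfg.scheme == "improved":
            omegas = [select_inertia(q, state.q_avg, state, cfg) for q in qs]
        else:
            omegas = [_scheduled_inertia(cfg.scheme, k, cfg)] * cfg.n_particles
        for p, omega in zip(particles, omegas):
            update_particle(p, state.gbest_x, omega, cfg, rng)
    return FitResult(
        best_x=state.gbest_x.copy(),
        best_q=state.gbest_q,
        history=history,
        iterations_used=iterations,
        termination=termination,
        n_rejected=n_rejected,
    )
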