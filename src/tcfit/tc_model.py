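"""Single-compartment conductance-based thalamocortical (TC) relay neuron.

The model carries four intrinsic currents — leak, transient sodium,
potassium, and a low-threshold T-type calcium current — plus a constant
pallidal drive ``i_gi`` and an applied sensorimotor input ``i_sm``:

    C_m dV/dt = -I_L - I_Na - I_K - I_T  (± i_gi) (± i_sm)

with I_L = g_L (V - E_L), I_Na = g_Na m∞³ h (V - E_Na),
I_K = g_K · 0.75 (1 - h)⁴ (V - E_K) and I_T = g_T p∞² r (V - E_T).
Sodium activation ``m`` and calcium activation ``p`` are instantaneous;
``h`` and ``r`` relax toward voltage-dependent steady states.

The three "key" parameters of interest for thalamic relay fidelity are
``i_gi``, ``g_t`` and ``e_t``; the remaining parameters are background
constants (standard reduced-TC-model values) that every routine accepts
as overrides.

Sign conventions: the dynamic equation subtracts both external currents.
With the shipped values (``i_gi`` negative, pulse amplitude positive) the
literal subtraction makes the pallidal term depolarizing and the pulse
train hyperpolarizing; ``SimConfig.flip_sign_sm`` (default True) restores
a depolarizing pulse input so that relay means one spike per input pulse.
Both flags are explicit so either reading can be run.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np

from ._kernels import rk4_integrate

if TYPE_CHECKING:  # pragma: no cover
    from .stimuli import CurrentTrace

__all__ = [
    "TCParams",
    "TCState",
    "SimConfig",
    "SimulationResult",
    "IntegrationError",
    "GateExcursionWarning",
    "gating_steady_states",
    "gating_time_constants",
    "ionic_currents",
    "derivatives",
    "steady_gates",
    "simulate",
]

#: abort threshold for the divergence guard, mV
V_ABORT = 200.0

#: numeric tolerance for gate excursions outside [0, 1]
GATE_TOL = 1e-6

KEY_PARAM_NAMES = ("i_gi", "g_t", "e_t")


class IntegrationError(RuntimeError):
    """Voltage diverged (|V| > 200 mV) during integration."""


class GateExcursionWarning(UserWarning):
    """A gating variable left [0, 1] by more than the numeric tolerance."""


@dataclass(frozen=True)
class TCParams:
    """Model parameters (conductances mS/cm²-scale model units, potentials mV).

    ``i_gi`` is the constant inhibitory current from the internal globus
    pallidus; negative values follow the convention of the fitting
    experiment.  ``i_gi``, ``g_t``, ``e_t`` are the fitted key parameters.
    """

    i_gi: float = -3.5
    g_t: float = 3.0
    e_t: float = 120.0
    c_m: float = 1.0
    g_l: float = 0.05
    e_l: float = -70.0
    g_na: float = 3.0
    e_na: float = 50.0
    g_k: float = 5.0
    e_k: float = -75.0

    def __post_init__(self) -> None:
        for name in ("g_l", "g_na", "g_k", "g_t"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if self.c_m <= 0:
            raise ValueError(f"c_m must be positive, got {self.c_m}")
        if not self.e_na > self.e_k:
            raise ValueError("e_na must exceed e_k")

    @property
    def key_parameters(self) -> np.ndarray:
        """The fitted triple (i_gi, g_t, e_t)."""
        return np.array([self.i_gi, self.g_t, self.e_t])

    def with_key_parameters(self, triple) -> "TCParams":
        """Return a copy with (i_gi, g_t, e_t) replaced."""
        i_gi, g_t, e_t = (float(x) for x in triple)
        return dataclasses.replace(self, i_gi=i_gi, g_t=g_t, e_t=e_t)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TCParams":
        return cls(**d)


@dataclass(frozen=True)
class TCState:
    """Instantaneous model state: membrane potential and the two slow gates."""

    v: float
    h: float
    r: float

    def __post_init__(self) -> None:
        if not (-GATE_TOL <= self.h <= 1 + GATE_TOL):
            raise ValueError(f"h outside [0, 1]: {self.h}")
        if not (-GATE_TOL <= self.r <= 1 + GATE_TOL):
            raise ValueError(f"r outside [0, 1]: {self.r}")


@dataclass(frozen=True)
class SimConfig:
    """Integration settings.

    dt : integration step, ms (fixed-step 4th-order Runge-Kutta).
    t_total : simulated duration, ms.
    t_discard : initial transient excluded from spike analysis, ms.
    v0 : initial membrane potential, mV; gates start at their steady
        state for ``v0``.
    flip_sign_sm / flip_sign_gi : add instead of subtract the respective
        external current (see module docstring).
    """

    dt: float = 0.01
    t_total: float = 1000.0
    t_discard: float = 100.0
    v0: float = -65.0
    method: str = "rk4"
    flip_sign_sm: bool = True
    flip_sign_gi: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 <= self.t_discard < self.t_total:
            raise ValueError("require 0 <= t_discard < t_total")
        if self.method != "rk4":
            raise ValueError(f"unknown integrator {self.method!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.t_total / self.dt)) + 1

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class SimulationResult:
    """Sampled trajectory of one simulation run."""

    times: np.ndarray
    voltage: np.ndarray
    h: np.ndarray
    r: np.ndarray
    applied_current: np.ndarray
    params: TCParams | None = None
    config: SimConfig | None = None

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("voltage", "h", "r", "applied_current"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from times")

    def to_csv(self, path: str | Path) -> None:
        """Write trace as CSV plus a JSON metadata sidecar (<path>.json)."""
        import pandas as pd

        path = Path(path)
        pd.DataFrame(
            {
                "time_ms": self.times,
                "v_mv": self.voltage,
                "h": self.h,
                "r": self.r,
                "i_sm": self.applied_current,
            }
        ).to_csv(path, index=False)
        meta = {
            "params": self.params.to_dict() if self.params else None,
            "config": self.config.to_dict() if self.config else None,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SimulationResult":
        import pandas as pd

        path = Path(path)
        df = pd.read_csv(path)
        params = config = None
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            if meta.get("params"):
                params = TCParams.from_dict(meta["params"])
            if meta.get("config"):
                config = SimConfig.from_dict(meta["config"])
        return cls(
            times=df["time_ms"].to_numpy(),
            voltage=df["v_mv"].to_numpy(),
            h=df["h"].to_numpy(),
            r=df["r"].to_numpy(),
            applied_current=df["i_sm"].to_numpy(),
            params=params,
            config=config,
        )


def _check_finite(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("membrane potential must be finite")
    return v


def gating_steady_states(v):
    """Steady-state activation/inactivation curves (m∞, p∞, h∞, r∞) at ``v`` mV.

    m∞ (sodium activation) and p∞ (calcium activation) increase with
    voltage; h∞ and r∞ (inactivation-style gates) decrease.
    """
    v = _check_finite(v)
    m_inf = 1.0 / (1.0 + np.exp(-(v + 37.0) / 7.0))
    p_inf = 1.0 / (1.0 + np.exp(-(v + 60.0) / 6.2))
    h_inf = 1.0 / (1.0 + np.exp((v + 41.0) / 4.0))
    r_inf = 1.0 / (1.0 + np.exp((v + 84.0) / 4.0))
    return m_inf, p_inf, h_inf, r_inf


def gating_time_constants(v):
    """Relaxation time constants (τ_h, τ_r) in ms at ``v`` mV."""
    v = _check_finite(v)
    a_h = 0.128 * np.exp(-(v + 46.0) / 18.0)
    b_h = 4.0 / (1.0 + np.exp(-(v + 23.0) / 5.0))
    tau_h = 1.0 / (a_h + b_h)
    tau_r = 28.0 + np.exp(-(v + 25.0) / 10.5)
    return tau_h, tau_r


def ionic_currents(state: TCState, params: TCParams):
    """Intrinsic current densities (I_L, I_Na, I_K, I_T) for a state."""
    m_inf, p_inf, _, _ = gating_steady_states(state.v)
    i_l = params.g_l * (state.v - params.e_l)
    i_na = params.g_na * m_inf**3 * state.h * (state.v - params.e_na)
    i_k = params.g_k * 0.75 * (1.0 - state.h) ** 4 * (state.v - params.e_k)
    i_t = params.g_t * p_inf**2 * state.r * (state.v - params.e_t)
    return i_l, i_na, i_k, i_t


def derivatives(
    state: TCState,
    i_sm: float,
    params: TCParams,
    *,
    flip_sign_sm: bool = True,
    flip_sign_gi: bool = False,
):
    """Time derivatives (dV/dt, dh/dt, dr/dt) of the TC model.

    ``i_sm`` is the applied current at the current instant.  The external
    currents are subtracted (literal convention) unless the corresponding
    flip flag adds them instead; defaults match :class:`SimConfig`.
    """
    i_l, i_na, i_k, i_t = ionic_currents(state, params)
    _, _, h_inf, r_inf = gating_steady_states(state.v)
    tau_h, tau_r = gating_time_constants(state.v)
    sgn_sm = 1.0 if flip_sign_sm else -1.0
    sgn_gi = 1.0 if flip_sign_gi else -1.0
    dv = (-i_l - i_na - i_k - i_t + sgn_gi * params.i_gi + sgn_sm * i_sm) / params.c_m
    dh = (h_inf - state.h) / tau_h
    dr = 2.5 * (r_inf - state.r) / tau_r
    return dv, dh, dr


def steady_gates(v: float) -> tuple[float, float]:
    """Steady-state (h, r) used to initialize the slow gates at ``v``."""
    _, _, h_inf, r_inf = gating_steady_states(v)
    return float(h_inf), float(r_inf)


def simulate(
    params: TCParams,
    stimulus: "CurrentTrace",
    cfg: SimConfig | None = None,
) -> SimulationResult:
    """Integrate the TC model under a sampled applied current.

    The stimulus must be sampled on the integration grid (``cfg.times``);
    its value is held constant across each step.  Deterministic: identical
    inputs give bit-identical traces.

    Raises :class:`IntegrationError` naming the step if |V| exceeds 200 mV,
    and warns (:class:`GateExcursionWarning`) if a gate leaves [0, 1] by
    more than 1e-6.
    """
    cfg = cfg or SimConfig()
    i_app = np.asarray(stimulus.values, dtype=float)
    if len(i_app) != cfg.n_samples:
        raise ValueError(
            f"stimulus has {len(i_app)} samples; config grid needs {cfg.n_samples}"
        )
    h0, r0 = steady_gates(cfg.v0)
    v, h, r, bad_step, gmin, gmax = rk4_integrate(
        cfg.v0, h0, r0, i_app, cfg.dt,
        params.c_m, params.g_l, params.e_l, params.g_na, params.e_na,
        params.g_k, params.e_k, params.g_t, params.e_t, params.i_gi,
        1.0 if cfg.flip_sign_gi else -1.0,
        1.0 if cfg.flip_sign_sm else -1.0,
        V_ABORT,
    )
    if bad_step >= 0:
        raise IntegrationError(
            f"voltage diverged (|V| > {V_ABORT} mV) at step {bad_step}"
            f" (t = {bad_step * cfg.dt:.3f} ms)"
        )
    if gmin < -GATE_TOL or gmax > 1 + GATE_TOL:
        warnings.warn(
            f"gating variable left [0, 1]: range [{gmin:.3g}, {gmax:.3g}]",
            GateExcursionWarning,
            stacklevel=2,
        )
    return SimulationResult(
        times=cfg.times,
        voltage=v,
        h=h,
        r=r,
        applied_current=i_app,
        params=params,
        config=cfg,
    )
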