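"""End-to-end parameter-recovery experiments.

The inverse problem: simulate the TC model at a *given* key-parameter
triple (i_gi, g_t, e_t) under a pulse stimulus, extract the reference
spike features, then recover the triple by minimizing the spike-feature
fitness with the particle swarm optimizer.  The quality of a recovered
triple is its squared parameter error e_T against the truth, reported as
ln e_T.

``run_comparison`` repeats the fit under the five inertia schemes over a
common set of replicate seeds and tabulates final triples, fitness and
ln e_T, supporting the ordering claim that the adaptive concave+chaotic
scheme recovers parameters with the smallest error.

Default experiment conditions: truth triple (-3.5, 3, 120) — a
parkinsonian relay regime — under the standard square-wave protocol
(A = 5, ρ = 25 ms, δ = 5 ms); dt = 0.05 ms over 500 ms with the first
100 ms discarded; 20 particles and 50 iterations per fit.

The fitness sums over several stimulus trials: the square-wave standard
plus ``n_poisson_trials`` Poisson-train probes.  The square-wave trial
alone cannot pin three parameters from four summary features (two of
which saturate or quantize); a g_T-(V-E_T) compensation ridge leaves
the calcium reversal E_T essentially free.  Irregular probe trains
break that degeneracy (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pso_core import SCHEMES, FitResult, SwarmConfig, run_pso
from .spike_metrics import (
    DEFAULT_THRESHOLD,
    DegenerateTraceError,
    FitnessWeights,
    SpikeFeatures,
    classify_relay,
    detect_spikes,
    extract_features,
    fitness,
    log_parameter_error,
    parameter_error,
)
from .stimuli import CurrentTrace, StimulusSpec, render_trace
from .tc_model import IntegrationError, SimConfig, SimulationResult, TCParams, simulate

__all__ = [
    "ExperimentConfig",
    "ComparisonReport",
    "experiment_traces",
    "build_reference",
    "make_objective",
    "fit_key_parameters",
    "reconstruct_and_compare",
    "run_comparison",
    "replicate_seeds",
]

logger = logging.getLogger(__name__)

#: search box for the key parameters (i_gi, g_t, e_t): brackets the truth
#: and every mis-converged baseline value with room to spare
DEFAULT_LO = (-10.0, 0.0, 90.0)
DEFAULT_HI = (0.0, 10.0, 140.0)


@dataclass(frozen=True)
class ExperimentConfig:
    """Complete description of one recovery experiment."""

    given_params: tuple = (-3.5, 3.0, 120.0)
    normal_params: tuple = (-0.5, 1.0, 120.0)
    base_params: TCParams = field(default_factory=TCParams)
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    sim: SimConfig = field(
        default_factory=lambda: SimConfig(dt=0.05, t_total=500.0, t_discard=100.0)
    )
    threshold: float = DEFAULT_THRESHOLD
    relay_window: float | None = None  # None -> stimulus period
    n_poisson_trials: int = 3
    weights: str = "scaled"  # "scaled" | "unit"
    lo: tuple = DEFAULT_LO
    hi: tuple = DEFAULT_HI
    n_particles: int = 20
    k_max: int = 50
    q_stop: float = 1e-8
    schemes: tuple = SCHEMES
    replicates: int = 5
    master_seed: int = 0
    output_dir: str = "tcfit_out"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.schemes:
            raise ValueError("schemes must be nonempty")
        for s in self.schemes:
            if s not in SCHEMES:
                raise ValueError(f"unknown scheme {s!r}")
        if self.weights not in ("scaled", "unit"):
            raise ValueError("weights must be 'scaled' or 'unit'")
        if self.n_poisson_trials < 0:
            raise ValueError("n_poisson_trials must be >= 0")

    @property
    def window(self) -> float:
        return self.relay_window if self.relay_window is not None else self.stimulus.rho_sm

    def swarm_config(self, scheme: str, seed: int | None) -> SwarmConfig:
        return SwarmConfig(
            lo=self.lo,
            hi=self.hi,
            n_particles=self.n_particles,
            k_max=self.k_max,
            q_stop=self.q_stop,
            scheme=scheme,
            seed=seed,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["base_params"] = self.base_params.to_dict()
        d["stimulus"] = self.stimulus.to_dict()
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "base_params" in d:
            d["base_params"] = TCParams.from_dict(d["base_params"])
        if "stimulus" in d:
            d["stimulus"] = StimulusSpec.from_dict(d["stimulus"])
        if "sim" in d:
            d["sim"] = SimConfig.from_dict(d["sim"])
        for key in ("given_params", "normal_params", "lo", "hi", "schemes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def replicate_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-replicate seeds (< 2^31), shared across schemes so
    scheme comparisons are paired."""
    state = np.random.SeedSequence(master_seed).generate_state(n)
    return [int(s) % (2**31) for s in state]


def _features_of(
    cfg: ExperimentConfig, result: SimulationResult, onsets
) -> SpikeFeatures:
    spikes = detect_spikes(result, cfg.threshold, t_min=cfg.sim.t_discard)
    keep = np.asarray(onsets) >= cfg.sim.t_discard
    relay = classify_relay(spikes, np.asarray(onsets)[keep], window=cfg.window)
    return extract_features(
        result, spikes, relay, threshold=cfg.threshold, t_min=cfg.sim.t_discard
    )


def experiment_traces(cfg: ExperimentConfig) -> list[CurrentTrace]:
    """The stimulus trials of one experiment: the configured (square-wave)
    stimulus first, then the Poisson probe trains.

    Probe seeds derive deterministically from ``cfg.master_seed`` so a
    whole experiment — reference and every candidate evaluation — shares
    one fixed trial set.
    """
    traces = [render_trace(cfg.stimulus, cfg.sim)]
    for i in range(cfg.n_poisson_trials):
        spec = dataclasses.replace(
            cfg.stimulus,
            kind="poisson",
            seed=(cfg.master_seed * 1000 + 7 * i + 1) % (2**31),
        )
        traces.append(render_trace(spec, cfg.sim))
    return traces


def build_reference(
    cfg: ExperimentConfig, params: TCParams | None = None
) -> tuple[list[SpikeFeatures], SimulationResult, list[CurrentTrace]]:
    """Simulate the model at the given triple under every trial stimulus
    and extract the reference ("standard") spike features the fit targets.

    Returns (per-trial features, square-trial simulation, trial traces).
    """
    if params is None:
        params = cfg.base_params.with_key_parameters(cfg.given_params)
    traces = experiment_traces(cfg)
    results = [simulate(params, tr, cfg.sim) for tr in traces]
    features = [
        _features_of(cfg, res, tr.pulse_onsets) for res, tr in zip(results, traces)
    ]
    return features, results[0], traces


def make_objective(
    cfg: ExperimentConfig,
    reference: list[SpikeFeatures],
    traces: list[CurrentTrace],
):
    """Objective q(x): simulate the candidate triple x under the reference
    trials and score its features against the reference.

    Candidate triples whose simulation diverges or degenerates get +inf
    (the swarm rejects them).  Returns (objective, weights).
    """
    weights = (
        FitnessWeights.from_reference(reference[0])
        if cfg.weights == "scaled"
        else FitnessWeights.unit()
    )

    def objective(x: np.ndarray) -> float:
        params = cfg.base_params.with_key_parameters(x)
        try:
            candidate = [
                _features_of(cfg, simulate(params, tr, cfg.sim), tr.pulse_onsets)
                for tr in traces
            ]
        except (IntegrationError, DegenerateTraceError):
            return np.inf
        return fitness(candidate, reference, weights)

    return objective, weights


def fit_key_parameters(
    cfg: ExperimentConfig, scheme: str = "improved", seed: int | None = None
) -> FitResult:
    """Recover the key-parameter triple with the named inertia scheme.

    The returned result carries e_t, the squared error of the recovered
    triple against the configured truth.
    """
    reference, _, traces = build_reference(cfg)
    objective, _ = make_objective(cfg, reference, traces)
    result = run_pso(objective, cfg.swarm_config(scheme, seed))
    result.e_t = parameter_error(result.best_x, cfg.given_params)
    logger.info(
        "scheme=%s seed=%s best_x=%s q=%.3g ln_e_t=%.3f iters=%d",
        scheme, seed, np.round(result.best_x, 4), result.best_q,
        np.log(result.e_t), result.iterations_used,
    )
    return result


def _point_report(
    cfg: ExperimentConfig,
    original: TCParams,
    reconstructed: TCParams | None,
    stimulus: StimulusSpec,
) -> dict:
    trace = render_trace(stimulus, cfg.sim)
    out: dict = {"stimulus_kind": stimulus.kind}
    res_o = simulate(original, trace, cfg.sim)
    feat_o = _features_of(cfg, res_o, trace.pulse_onsets)
    out["original"] = dataclasses.asdict(feat_o)
    out["_traces"] = {"times": res_o.times, "original_v": res_o.voltage,
                      "i_sm": res_o.applied_current}
    if reconstructed is not None:
        res_r = simulate(reconstructed, trace, cfg.sim)
        feat_r = _features_of(cfg, res_r, trace.pulse_onsets)
        out["reconstructed"] = dataclasses.asdict(feat_r)
        out["feature_delta"] = (feat_r.as_array() - feat_o.as_array()).tolist()
        out["_traces"]["reconstructed_v"] = res_r.voltage
    return out


def reconstruct_and_compare(
    cfg: ExperimentConfig,
    fit: FitResult,
    normal_fit: FitResult | None = None,
) -> dict:
    """Overlay report: re-simulate original vs reconstructed (fitted)
    models under both square-wave and Poisson inputs, at the parkinsonian
    operating point and at the configured normal-state point.

    The normal point's reconstruction uses ``normal_fit`` when supplied;
    otherwise only the original normal-state features are reported.
    """
    square = (
        cfg.stimulus
        if cfg.stimulus.kind == "square"
        else dataclasses.replace(cfg.stimulus, kind="square")
    )
    poisson = dataclasses.replace(
        cfg.stimulus, kind="poisson",
        seed=cfg.stimulus.seed if cfg.stimulus.seed is not None else cfg.master_seed,
    )
    park_orig = cfg.base_params.with_key_parameters(cfg.given_params)
    park_rec = cfg.base_params.with_key_parameters(fit.best_x)
    norm_orig = cfg.base_params.with_key_parameters(cfg.normal_params)
    norm_rec = (
        cfg.base_params.with_key_parameters(normal_fit.best_x)
        if normal_fit is not None
        else None
    )
    report = {
        "fitted_triple": np.asarray(fit.best_x).tolist(),
        "ln_e_t": float(np.log(fit.e_t)) if fit.e_t else None,
        "parkinsonian": {
            "square": _point_report(cfg, park_orig, park_rec, square),
            "poisson": _point_report(cfg, park_orig, park_rec, poisson),
        },
        "normal": {
            "square": _point_report(cfg, norm_orig, norm_rec, square),
            "poisson": _point_report(cfg, norm_orig, norm_rec, poisson),
        },
    }
    return report


@dataclass
class ComparisonReport:
    """Tabulated five-scheme comparison over replicate seeds."""

    rows: list  # dict per (scheme, seed)
    curves: dict  # (scheme, seed) -> list of (k, gbest_q)

    def frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows)

    def median_ln_e_t(self) -> dict:
        df = self.frame()
        return df.groupby("scheme")["ln_e_t"].median().to_dict()

    def to_json(self, path: str | Path) -> None:
        d = {
            "rows": self.rows,
            "median_ln_e_t": self.median_ln_e_t(),
            "curves": {f"{s}/{seed}": c for (s, seed), c in self.curves.items()},
        }
        Path(path).write_text(json.dumps(d, indent=1))

    def to_csv(self, path: str | Path) -> None:
        self.frame().to_csv(Path(path), index=False)


def run_comparison(cfg: ExperimentConfig) -> ComparisonReport:
    """Fit the triple with every configured scheme over shared replicate
    seeds; tabulate final triples, fitness, ln e_T and fitness curves."""
    seeds = replicate_seeds(cfg.master_seed, cfg.replicates)
    rows = []
    curves = {}
    for scheme in cfg.schemes:
        for seed in seeds:
            fit = fit_key_parameters(cfg, scheme, seed)
            rows.append(
                {
                    "scheme": scheme,
                    "seed": seed,
                    "i_gi": float(fit.best_x[0]),
                    "g_t": float(fit.best_x[1]),
                    "e_t_reversal": float(fit.best_x[2]),
                    "q": fit.best_q,
                    "e_t_err": fit.e_t,
                    "ln_e_t": float(np.log(fit.e_t)),
                    "iterations": fit.iterations_used,
                    "termination": fit.termination,
                }
            )
            curves[(scheme, seed)] = [(k, q) for k, q, _ in fit.history]
    return ComparisonReport(rows=rows, curves=curves)
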