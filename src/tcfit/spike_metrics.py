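"""Spike detection, relay-reliability scoring, and the fitting objective.

Relay fidelity of a thalamocortical neuron is scored per input pulse:
an input that elicits no spike in its response window is *missed*, one
that elicits two or more is a *bad* relay (burst), and

    error index = (missed + bad) / total inputs,      RI = 1 - error index.

RI > 0.9 is conventionally a normal relay; RI < 0.5 a parkinsonian one.

Parameter fitting compares four spike-train features between a candidate
("reconstructed") model and the reference: RI, total spike count N, mean
spike peak PK, and mean subthreshold voltage ST.  The fitness is the
weighted sum of squared feature differences, summed over stimulus trials:

    q = w1 Σ(RI_rec - RI_ori)² + w2 Σ(N_rec - N_ori)²
      + w3 Σ(PK_rec - PK_ori)² + w4 Σ(ST_rec - ST_ori)².

The parameter error of a fitted key-parameter triple against the truth is
e_T = Σᵢ (fittedᵢ - givenᵢ)², reported on the natural-log scale.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .tc_model import SimulationResult

__all__ = [
    "SpikeTrain",
    "RelayReport",
    "SpikeFeatures",
    "FitnessWeights",
    "DegenerateTraceError",
    "DEFAULT_THRESHOLD",
    "detect_spikes",
    "classify_relay",
    "classify_state",
    "extract_features",
    "fitness",
    "parameter_error",
    "log_parameter_error",
]

#: default spike-detection threshold, mV
DEFAULT_THRESHOLD = -25.0


class DegenerateTraceError(ValueError):
    """Trace has no subthreshold samples; features are undefined."""


@dataclass
class SpikeTrain:
    """Detected spikes: times (ms, strictly increasing) and peak voltages."""

    times: np.ndarray
    peaks: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.peaks = np.asarray(self.peaks, dtype=float)
        if len(self.times) != len(self.peaks):
            raise ValueError("times and peaks must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"time_ms": self.times, "peak_mv": self.peaks}).to_csv(
            Path(path), index=False
        )


@dataclass(frozen=True)
class RelayReport:
    """Per-input relay classification counts."""

    total_inputs: int
    missed: int
    bad: int

    def __post_init__(self) -> None:
        if not 0 <= self.missed + self.bad <= self.total_inputs:
            raise ValueError("missed + bad must lie in [0, total_inputs]")

    @property
    def error_index(self) -> float:
        return (self.missed + self.bad) / self.total_inputs

    @property
    def ri(self) -> float:
        return 1.0 - self.error_index

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["error_index"] = self.error_index
        d["ri"] = self.ri
        Path(path).write_text(json.dumps(d, indent=1))


@dataclass(frozen=True)
class SpikeFeatures:
    """The four-feature summary entering the fitness: (RI, N, PK, ST)."""

    ri: float
    n: int
    pk: float
    st: float

    def __post_init__(self) -> None:
        if not 0 <= self.ri <= 1:
            raise ValueError("ri must lie in [0, 1]")
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        if self.n > 0 and self.pk < self.st:
            raise ValueError("pk must be >= st when spikes exist")

    def as_array(self) -> np.ndarray:
        return np.array([self.ri, self.n, self.pk, self.st])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SpikeFeatures":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class FitnessWeights:
    """Nonnegative weights of the four fitness terms (RI, N, PK, ST)."""

    w_ri: float = 1.0
    w_n: float = 1.0
    w_pk: float = 1.0
    w_st: float = 1.0

    def __post_init__(self) -> None:
        w = self.as_array()
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if not np.any(w > 0):
            raise ValueError("at least one weight must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_ri, self.w_n, self.w_pk, self.w_st])

    @classmethod
    def unit(cls) -> "FitnessWeights":
        return cls()

    @classmethod
    def from_reference(cls, ref: SpikeFeatures) -> "FitnessWeights":
        """Scale-normalized weights: 1/scale² per feature, so each term is
        O(1) for an O(scale) mismatch.  Scale = max(|feature|, 1); RI is
        already O(1), spike counts and voltages are not."""
        scale = np.maximum(np.abs(ref.as_array()), 1.0)
        w = 1.0 / scale**2
        return cls(*w)


def detect_spikes(
    result: SimulationResult,
    threshold: float = DEFAULT_THRESHOLD,
    t_min: float = 0.0,
) -> SpikeTrain:
    """Threshold-crossing spike detection on a voltage trace.

    Samples before ``t_min`` (the discarded transient) are ignored.  Each
    maximal contiguous run of samples with V >= threshold yields one
    spike at the run's voltage maximum, with that maximum as its peak.
    A trace that never reaches threshold yields an empty train.
    """
    keep = result.times >= t_min
    t = result.times[keep]
    v = result.voltage[keep]
    if len(v) == 0:
        return SpikeTrain(times=np.empty(0), peaks=np.empty(0))
    above = v >= threshold
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(v)]
    times, peaks = [], []
    for a, b in zip(starts, ends):
        j = a + int(np.argmax(v[a:b]))
        times.append(t[j])
        peaks.append(v[j])
    return SpikeTrain(times=np.asarray(times), peaks=np.asarray(peaks))


def classify_relay(
    spikes: SpikeTrain,
    pulse_onsets,
    window: float = 25.0,
    orphans_are_bad: bool = False,
) -> RelayReport:
    """Score each input pulse by the spike count in its response window.

    The window for onset k is [onset_k, onset_k + window), truncated at
    the next onset (with a warning) when windows would overlap.  0 spikes
    marks the input missed, >= 2 marks it bad; each input contributes at
    most one error.  With ``orphans_are_bad``, a spike falling between
    windows additionally marks the preceding input bad (strict mode; by
    default orphan spikes are ignored).
    """
    onsets = np.asarray(pulse_onsets, dtype=float)
    if len(onsets) == 0:
        raise ValueError("pulse_onsets must be nonempty")
    if window <= 0:
        raise ValueError("window must be positive")
    gaps = np.diff(onsets)
    if len(gaps) and window > gaps.min():
        warnings.warn(
            f"window {window} ms exceeds the minimum onset gap"
            f" ({gaps.min():.3g} ms); windows truncated at the next onset",
            stacklevel=2,
        )
    ends = np.minimum(onsets + window, np.r_[onsets[1:], np.inf])
    missed = bad = 0
    for k, (onset, end) in enumerate(zip(onsets, ends)):
        count = int(np.sum((spikes.times >= onset) & (spikes.times < end)))
        if count == 0:
            missed += 1
        elif count >= 2:
            bad += 1
        elif orphans_are_bad:
            # spike(s) after the window but before the next onset burst-ify
            # the relay of this input
            nxt = onsets[k + 1] if k + 1 < len(onsets) else np.inf
            orphan = int(np.sum((spikes.times >= end) & (spikes.times < nxt)))
            if orphan:
                bad += 1
    return RelayReport(total_inputs=len(onsets), missed=missed, bad=bad)


def classify_state(ri: float) -> str:
    """Map a reliability index to {"normal", "parkinsonian", "indeterminate"}.

    RI > 0.9 is a normal relay, RI < 0.5 parkinsonian; between the two
    there is no accepted boundary.
    """
    if not 0 <= ri <= 1:
        raise ValueError(f"ri must lie in [0, 1], got {ri}")
    if ri > 0.9:
        return "normal"
    if ri < 0.5:
        return "parkinsonian"
    return "indeterminate"


def extract_features(
    result: SimulationResult,
    spikes: SpikeTrain,
    relay: RelayReport,
    threshold: float = DEFAULT_THRESHOLD,
    t_min: float = 0.0,
) -> SpikeFeatures:
    """Assemble the four-feature vector from one simulation.

    ST averages voltage samples strictly below the threshold (from
    ``t_min`` on).  A spikeless candidate gets PK = threshold as a
    sentinel so the fitness stays defined during swarm exploration.
    """
    keep = result.times >= t_min
    v = result.voltage[keep]
    sub = v[v < threshold]
    if len(sub) == 0:
        raise DegenerateTraceError("no subthreshold samples below threshold")
    n = len(spikes)
    pk = float(np.mean(spikes.peaks)) if n > 0 else float(threshold)
    return SpikeFeatures(ri=relay.ri, n=n, pk=pk, st=float(np.mean(sub)))


def _as_trials(x) -> Sequence[SpikeFeatures]:
    if isinstance(x, SpikeFeatures):
        return (x,)
    return tuple(x)


def fitness(rec, ori, weights: FitnessWeights = FitnessWeights()) -> float:
    """Weighted squared-feature-difference fitness q between candidate and
    reference features.

    ``rec``/``ori`` are single :class:`SpikeFeatures` or equal-length
    sequences of them (one per stimulus trial); sums run over trials.
    q >= 0 with equality iff the features match on every trial wherever
    the weight is positive.
    """
    rec_t, ori_t = _as_trials(rec), _as_trials(ori)
    if len(rec_t) != len(ori_t):
        raise ValueError(
            f"trial-count mismatch: {len(rec_t)} candidate vs {len(ori_t)} reference"
        )
    w = weights.as_array()
    q = 0.0
    for fr, fo in zip(rec_t, ori_t):
        q += float(np.sum(w * (fr.as_array() - fo.as_array()) ** 2))
    return q


def parameter_error(fitted, given) -> float:
    """Squared parameter error e_T = Σ (fitted_i - given_i)² over the
    key-parameter triple (i_gi, g_t, e_t)."""
    fitted = np.asarray(fitted, dtype=float)
    given = np.asarray(given, dtype=float)
    if fitted.shape != given.shape:
        raise ValueError("fitted and given must have the same shape")
    return float(np.sum((fitted - given) ** 2))


def log_parameter_error(fitted, given) -> float:
    """Natural log of the squared parameter error, ln e_T."""
    return float(np.log(parameter_error(fitted, given)))
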