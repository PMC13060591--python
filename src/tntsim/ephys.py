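"""Electrophysiology and functional-outcome metrics.

Implements the outcome computations used to track nerve regeneration:

* CMAP amplitude (baseline-to-peak or peak-to-peak) from an EMG trace;
* average SMUP from successive differences of incremental submaximal
  responses, and MUNE = max CMAP (peak-to-peak) / average SMUP;
* peak twitch and tetanic torque (150 Hz x 1 s trains), with the tetanic
  plateau mean reported alongside;
* grip strength as the mean of (nominally three) trials;
* recovery percentage, 100 x injured-treated / healthy-control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError

__all__ = [
    "Waveform",
    "IncrementSeries",
    "MUNEResult",
    "cmap_amplitude",
    "smup_average",
    "smup_summary",
    "mune",
    "mune_result",
    "peak_torque",
    "tetanic_plateau",
    "grip_strength",
    "recovery_percent",
]


@dataclass
class Waveform:
    """Uniformly sampled trace (mV for EMG, mN*m for torque)."""

    samples: np.ndarray
    sampling_rate: float  # Hz
    stimulus_times: list[float] = field(default_factory=list)  # ms
    units: str = "mV"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 2:
            raise AnalysisError("waveform needs at least 2 samples")
        if self.sampling_rate <= 0:
            raise AnalysisError("sampling_rate must be > 0")

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) * 1e3 / self.sampling_rate


@dataclass
class IncrementSeries:
    """Response amplitudes (mV) at increasing submaximal stimulus intensity."""

    amplitudes: np.ndarray
    n_increments: int = 10

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)


@dataclass
class MUNEResult:
    """Motor unit number estimate and its ingredients."""

    max_cmap_pp: float
    avg_smup: float
    mune: float
    mune_rounded: int


def _windows(w: Waveform, baseline_ms: float, response_ms: float):
    stim = w.stimulus_times[0] if w.stimulus_times else 0.0
    t = w.times_ms
    pre = (t >= stim - baseline_ms) & (t < stim)
    post = (t >= stim) & (t <= stim + response_ms)
    if not post.any():
        raise AnalysisError("waveform has no post-stimulus response window")
    baseline = float(w.samples[pre].mean()) if pre.any() else 0.0
    return baseline, w.samples[post]


def cmap_amplitude(
    w: Waveform,
    mode: str = "baseline_to_peak",
    baseline_ms: float = 5.0,
    response_ms: float = 50.0,
) -> float:
    """CMAP amplitude in mV.

    ``baseline_to_peak``: largest absolute deviation from the pre-stimulus
    baseline (mean of the ``baseline_ms`` window before the stimulus).
    ``peak_to_peak``: max minus min within the response window.
    """
    baseline, resp = _windows(w, baseline_ms, response_ms)
    if mode == "baseline_to_peak":
        return float(np.max(np.abs(resp - baseline)))
    if mode == "peak_to_peak":
        return float(resp.max() - resp.min())
    raise AnalysisError(f"unknown amplitude mode {mode!r}")


def smup_average(series: IncrementSeries, include_zero_baseline: bool = False) -> float:
    """Average single-motor-unit potential (mV).

    Mean of successive differences between consecutive submaximal response
    levels.  With ``include_zero_baseline`` the sub-recruitment zero level
    is prepended, so the first response counts as an increment (needed when
    the series holds only one response).  Negative differences (alternation
    noise) are floored at zero with a warning rather than discarded.
    """
    amps = series.amplitudes
    if include_zero_baseline:
        amps = np.concatenate([[0.0], amps])
    if amps.size < 2:
        raise AnalysisError("need at least 2 response levels to form increments")
    diffs = np.diff(amps)
    if np.any(diffs < 0):
        warnings.warn(
            "negative amplitude increments floored at 0 (alternation noise)",
            stacklevel=2,
        )
        diffs = np.maximum(diffs, 0.0)
    return float(diffs.mean())


def smup_summary(series: IncrementSeries, include_zero_baseline: bool = False) -> dict:
    """Both SMUP readings: floored successive-difference mean and the
    telescoped (last - first)/n value, which differ only when increments
    go negative."""
    amps = series.amplitudes
    if include_zero_baseline:
        amps = np.concatenate([[0.0], amps])
    if amps.size < 2:
        raise AnalysisError("need at least 2 response levels to form increments")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        successive = smup_average(series, include_zero_baseline)
    telescoped = float((amps[-1] - amps[0]) / (amps.size - 1))
    return {"successive": successive, "telescoped": telescoped}


def mune(max_cmap_pp: float, avg_smup: float) -> float:
    """Motor unit number estimate: max CMAP (peak-to-peak) / average SMUP."""
    if avg_smup <= 0:
        raise AnalysisError("average SMUP must be > 0 for MUNE")
    return max_cmap_pp / avg_smup


def mune_result(max_cmap_pp: float, avg_smup: float) -> MUNEResult:
    """MUNE with its inputs; the real-valued estimate is primary and the
    rounded integer is provided alongside."""
    est = mune(max_cmap_pp, avg_smup)
    return MUNEResult(
        max_cmap_pp=max_cmap_pp,
        avg_smup=avg_smup,
        mune=est,
        mune_rounded=int(round(est)),
    )


def peak_torque(
    w: Waveform,
    kind: str = "twitch",
    baseline_ms: float = 5.0,
    response_ms: float | None = None,
) -> float:
    """Peak torque (mN*m) of a twitch or tetanic response.

    Twitch: maximum of the single-stimulus response above baseline.
    Tetanic: maximum over the 1-s train window (default response window
    1100 ms to cover the full train).
    """
    if kind not in ("twitch", "tetanic"):
        raise AnalysisError(f"unknown torque kind {kind!r}")
    if response_ms is None:
        response_ms = 300.0 if kind == "twitch" else 1100.0
    baseline, resp = _windows(w, baseline_ms, response_ms)
    return float(np.max(resp - baseline))


def tetanic_plateau(
    w: Waveform, train_ms: float = 1000.0, window_ms: float = 200.0
) -> float:
    """Mean torque over the final ``window_ms`` of the stimulus train."""
    stim = w.stimulus_times[0] if w.stimulus_times else 0.0
    t = w.times_ms
    sel = (t >= stim + train_ms - window_ms) & (t <= stim + train_ms)
    if not sel.any():
        raise AnalysisError("trace does not cover the plateau window")
    return float(w.samples[sel].mean())


def grip_strength(trials: list[float]) -> float:
    """Mean grip force across trials; the protocol calls for three."""
    if len(trials) == 0:
        raise AnalysisError("no grip trials provided")
    if len(trials) != 3:
        warnings.warn(
            f"grip strength averaged over {len(trials)} trials (protocol uses 3)",
            stacklevel=2,
        )
    return float(np.mean(trials))


def recovery_percent(treated: float, healthy: float) -> float:
    """Recovery = 100 x injured-treated / healthy-control (may exceed 100)."""
    if healthy <= 0:
        raise AnalysisError("healthy-control reference must be > 0")
    return 100.0 * treated / healthy
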