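"""Single-sensillum recording support: spike detection and rate summaries.

The preparation is assumed single-unit (one functional neuron per
sensillum), so no sorting is attempted: detection is threshold crossing on
a high-pass-filtered trace, with the threshold set as a multiple of the
robust noise scale (median absolute deviation).  Rates are summarized two
ways: instantaneous frequency (reciprocal inter-spike interval, sampled on
a time grid) and mean stimulus-evoked rate (stimulus-window count rate
minus baseline-window count rate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "SpikeTrain",
    "detect_spikes",
    "instantaneous_frequency",
    "mean_response_rate",
    "read_spike_csv",
    "write_spike_csv",
]


@dataclass
class SpikeTrain:
    """Sorted spike times (seconds) within one recording."""

    times: np.ndarray
    duration: float
    stimulus_interval: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.times.size:
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.times[0] < 0 or self.times[-1] > self.duration:
                raise ValueError("spike times must lie within [0, duration]")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def count(self, window: tuple[float, float]) -> int:
        a, b = window
        return int(np.sum((self.times >= a) & (self.times < b)))


def detect_spikes(
    trace: np.ndarray,
    fs: float,
    threshold_k: float = 5.0,
    highpass_hz: float | None = 300.0,
    refractory_s: float = 0.002,
    stimulus_interval: tuple[float, float] | None = None,
) -> SpikeTrain:
    """Threshold-crossing spike detection on a voltage-like trace.

    The trace is high-pass filtered (``highpass_hz``, zero-phase; skipped
    when None), the noise scale estimated as MAD/0.6745, and upward
    crossings of ``threshold_k × scale`` counted as one spike each, merged
    within the refractory window and timed at the local maximum.  On a
    noiseless trace the MAD is zero and half the peak amplitude is used as
    the threshold instead; an all-flat trace yields an empty train with a
    warning.
    """
    x = np.asarray(trace, dtype=float)
    duration = len(x) / fs
    if np.ptp(x) == 0:
        warnings.warn("flat trace: no spikes detectable", stacklevel=2)
        return SpikeTrain(times=np.empty(0), duration=duration, stimulus_interval=stimulus_interval)
    if highpass_hz is not None and 0 < highpass_hz < fs / 2:
        sos = butter(2, highpass_hz, btype="highpass", fs=fs, output="sos")
        x = sosfiltfilt(sos, x)
    mad = float(np.median(np.abs(x - np.median(x))))
    scale = mad / 0.6745
    peak = float(np.max(np.abs(x)))
    # (near-)noiseless traces: the MAD reflects filter ripple, not noise —
    # fall back to half the peak amplitude
    threshold = threshold_k * scale if scale > 1e-3 * peak else 0.5 * peak

    above = x > threshold
    onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    refractory = int(round(refractory_s * fs))
    peaks = []
    last = -refractory - 1
    for i in onsets:
        if i - last <= refractory:
            continue
        j = i
        while j + 1 < len(x) and above[j + 1]:
            j += 1
        peaks.append(i + int(np.argmax(x[i : j + 1])))
        last = peaks[-1]
    times = np.unique(np.asarray(peaks, dtype=float) / fs)
    return SpikeTrain(times=times, duration=duration, stimulus_interval=stimulus_interval)


def instantaneous_frequency(train: SpikeTrain, grid: np.ndarray) -> np.ndarray:
    """Reciprocal-ISI firing rate sampled on a time grid (spikes/s).

    Each inter-spike interval [t_i, t_{i+1}) carries the rate 1/ISI; grid
    points outside any spiking epoch (before the first or after the last
    spike) read zero.  Fewer than two spikes give an all-zero series.
    """
    grid = np.asarray(grid, dtype=float)
    out = np.zeros(grid.shape)
    t = train.times
    if t.size < 2:
        return out
    isi = np.diff(t)
    idx = np.searchsorted(t, grid, side="right") - 1
    inside = (idx >= 0) & (idx < t.size - 1)
    out[inside] = 1.0 / isi[idx[inside]]
    return out


def mean_response_rate(
    train: SpikeTrain,
    stimulus_window: tuple[float, float],
    baseline_window: tuple[float, float] | None = None,
    subtract_baseline: bool = True,
) -> float:
    """Stimulus-evoked firing rate (spikes/s), baseline-subtracted by default.

    Rate = spike count in the stimulus window divided by its length, minus
    the same quantity over the baseline window (skipped when
    ``subtract_baseline`` is False or no baseline window is given).
    """
    def rate(window):
        a, b = window
        if not (0 <= a < b <= train.duration):
            raise ValueError(f"window {window} invalid for duration {train.duration}")
        return train.count(window) / (b - a)

    r = rate(stimulus_window)
    if subtract_baseline and baseline_window is not None:
        r -= rate(baseline_window)
    return float(r)


def read_spike_csv(path) -> SpikeTrain:
    """Two-column CSV (time, unit) with duration in a '# duration=' header or inferred."""
    df = pd.read_csv(path, comment="#")
    times = np.sort(df.iloc[:, 0].to_numpy(dtype=float))
    duration = float(times[-1]) if times.size else 1.0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "duration=" in line:
                duration = float(line.split("duration=")[1])
            if not line.startswith("#"):
                break
    return SpikeTrain(times=times, duration=duration)


def write_spike_csv(train: SpikeTrain, path, unit: int = 1) -> None:
    with open(path, "w") as fh:
        fh.write(f"# duration={train.duration}\n")
        pd.DataFrame({"time": train.times, "unit": unit}).to_csv(fh, index=False)
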