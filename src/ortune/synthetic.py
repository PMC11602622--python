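"""Synthetic recordings with known ground truth.

Every generator emulates the acquisition design of the imaging experiments
the pipeline targets — 100-frame recordings at 5 Hz with a 1 s odor
stimulus at frames 15–20, monotone photobleaching, stimulus-locked calcium
transients, dual-wavelength anti-correlated Fura-2 channels, replicate
structure over animals, a logarithmic dose ladder from 0.1 to 1000 μg, and
stimulus-driven spike trains — and returns the planted parameters in a
:class:`GroundTruth` record so every downstream stage can be tested for
exact or statistical recovery without any external data.

Determinism: each generator derives all randomness from an integer seed via
:func:`substream`, a counter-based spawn of ``numpy.random.SeedSequence``;
identical (config, seed) gives byte-identical output, and replicate ``i``
is unchanged when the replicate count grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging_io import AcquisitionProtocol, FrameStack, PROTOCOL_PRESETS, ROISet
from ._frames import window_slice, validate_window

__all__ = [
    "BleachModel",
    "TransientShape",
    "SimulationConfig",
    "GroundTruth",
    "substream",
    "simulate_trace",
    "simulate_ratiometric_stack",
    "simulate_response_panel",
    "block_spectra",
    "simulate_dose_series",
    "simulate_spike_train",
    "render_spike_trace",
]


def substream(seed: int, *counters: int) -> np.random.Generator:
    """Independent generator for replicate ``counters`` under a master seed.

    Spawning through ``SeedSequence(seed, spawn_key=counters)`` makes stream
    ``i`` a pure function of (seed, i): adding replicates never reshuffles
    earlier ones.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(c) for c in counters))
    )


@dataclass(frozen=True)
class BleachModel:
    """Multiplicative photobleaching profile b(t), t = 0-based frame index.

    kind "none": b ≡ 1; "log": b = a + b·ln(t+1) (the same family the
    correction step fits); "exp": b = a·exp(−t/τ).
    """

    kind: str = "log"
    a: float = 1.0
    b: float = -0.02
    tau: float = 100.0

    def profile(self, n_frames: int) -> np.ndarray:
        t = np.arange(n_frames, dtype=float)
        if self.kind == "none":
            return np.ones(n_frames)
        if self.kind == "log":
            out = self.a + self.b * np.log(t + 1.0)
        elif self.kind == "exp":
            out = self.a * np.exp(-t / self.tau)
        else:
            raise ValueError(f"unknown bleach kind {self.kind!r}")
        if np.any(out <= 0):
            raise ValueError("bleach profile must stay positive over the recording")
        return out


@dataclass(frozen=True)
class TransientShape:
    """Stimulus-locked response kernel, unit peak.

    Linear rise over ``rise_frames`` from stimulus onset, a plateau of
    ``hold_frames`` (calcium indicators report a sustained response during
    and after a 1 s stimulus), then an exponential decay with time constant
    ``decay_frames``.  Defaults keep the kernel exactly 1 across both
    amplitude-measurement windows (frames 17–19 and 17–31 at the default
    onset, frame 15).
    """

    rise_frames: int = 2
    hold_frames: int = 15
    decay_frames: float = 3.0

    def kernel(self, n_frames: int, onset_frame: int) -> np.ndarray:
        """Kernel over the recording; ``onset_frame`` is 1-based."""
        k = np.zeros(n_frames)
        start = onset_frame - 1
        for j in range(self.rise_frames):
            if start + j < n_frames:
                k[start + j] = (j + 1) / self.rise_frames
        hold_end = start + self.rise_frames + self.hold_frames
        plateau = slice(start + self.rise_frames, min(hold_end, n_frames))
        k[plateau] = 1.0
        if hold_end < n_frames:
            j = np.arange(n_frames - hold_end, dtype=float)
            k[hold_end:] = np.exp(-j / self.decay_frames)
        return k


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition design of one synthetic recording."""

    n_frames: int = 100
    frame_rate: float = 5.0  # Hz
    stim_window: tuple[int, int] = (15, 20)  # 1-based inclusive, 1 s at 5 Hz
    bleach: BleachModel = field(default_factory=BleachModel)
    transient: TransientShape = field(default_factory=TransientShape)
    baseline_f: float = 1000.0  # raw fluorescence baseline, a.u.
    noise_sd: float = 5.0  # additive Gaussian SD on raw fluorescence, a.u.
    noise_model: str = "gaussian"  # "gaussian" | "poisson"
    n_replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        validate_window(self.stim_window, self.n_frames, "stim_window")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.baseline_f <= 0:
            raise ValueError("baseline_f must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def protocol(self, convention: str = "bee") -> AcquisitionProtocol:
        """Acquisition protocol matching this design (bee or fly preset windows)."""
        base = PROTOCOL_PRESETS[convention]
        return replace(base, frame_rate=self.frame_rate, n_frames=self.n_frames)


@dataclass
class GroundTruth:
    """Planted parameters paired with one synthetic artifact."""

    amplitude: float | None = None  # ΔF/F0 or ΔR/R fraction of one trace
    amplitudes: dict[str, float] | None = None  # per ROI
    spectra: pd.DataFrame | None = None  # receptor × stimulus planted means
    cluster_labels: dict[str, int] | None = None
    ec50: float | None = None  # μg
    hill: float | None = None
    top: float | None = None
    bottom: float | None = None
    baseline_rate: float | None = None  # spikes/s
    stim_rate: float | None = None
    spike_times: np.ndarray | None = None  # s


def _noise(rng: np.random.Generator, clean: np.ndarray, config: SimulationConfig) -> np.ndarray:
    if config.noise_sd == 0 and config.noise_model == "gaussian":
        return clean
    if config.noise_model == "poisson":
        # shot noise: scale so that the SD at baseline matches noise_sd
        if config.noise_sd == 0:
            return clean
        gain = config.noise_sd**2 / config.baseline_f
        return rng.poisson(clean / gain) * gain
    return clean + rng.normal(0.0, config.noise_sd, size=clean.shape)


# ---------------------------------------------------------------------------
# Single-ROI traces


def simulate_trace(
    config: SimulationConfig,
    true_amplitude: float,
    replicate: int = 0,
    convention: str = "fly",
):
    """One raw fluorescence trace with a planted relative amplitude.

    The clean signal is ``baseline_f · bleach(t) · (1 + A·kernel(t))`` with
    the kernel zero before stimulus onset, plus noise.  Amplitudes below −1
    would drive fluorescence negative and are rejected.
    """
    if true_amplitude < -1:
        raise ValueError(f"amplitude {true_amplitude} < -1 implies negative fluorescence")
    from .traces import FluorescenceTrace  # local import to avoid a cycle

    kernel = config.transient.kernel(config.n_frames, config.stim_window[0])
    clean = config.baseline_f * config.bleach.profile(config.n_frames) * (
        1.0 + true_amplitude * kernel
    )
    rng = substream(config.seed, replicate)
    values = _noise(rng, clean, config)
    trace = FluorescenceTrace(values=values, protocol=config.protocol(convention))
    return trace, GroundTruth(amplitude=true_amplitude)


def simulate_blank_trace(config: SimulationConfig, replicate: int = 0, convention: str = "fly"):
    """Stimulus-free recording (bleach decay only), for blank subtraction."""
    return simulate_trace(config, 0.0, replicate=replicate, convention=convention)


# ---------------------------------------------------------------------------
# Ratiometric stacks


def simulate_ratiometric_stack(
    config: SimulationConfig,
    rois: ROISet,
    true_amplitudes: Mapping[str, float],
    image_shape: tuple[int, int] = (48, 64),
    baseline_f340: float = 800.0,
    baseline_f380: float = 1000.0,
):
    """Dual-wavelength Fura-2 stacks with planted per-ROI ΔR/R amplitudes.

    Inside each ROI, F340 rises and F380 falls during the transient by a
    common factor α = A/(2 + A), chosen so the excitation ratio change
    (1+α)/(1−α) − 1 equals the planted amplitude A at the kernel plateau.
    Both channels share the same bleach profile, which therefore cancels in
    the ratio.  Overlapping ROIs are rejected.
    """
    masks = rois.masks(image_shape)
    names = list(masks)
    for name in names:
        if not masks[name].any():
            raise ValueError(f"ROI {name!r} lies outside the {image_shape} image")
    cover = np.zeros(image_shape, dtype=int)
    for m in masks.values():
        cover += m
    if np.any(cover > 1):
        raise ValueError("ROIs overlap; planted amplitudes would be ambiguous")
    unknown = set(true_amplitudes) - set(names)
    if unknown:
        raise ValueError(f"amplitudes given for unknown ROIs {sorted(unknown)}")

    kernel = config.transient.kernel(config.n_frames, config.stim_window[0])
    bleach = config.bleach.profile(config.n_frames)
    alpha = np.zeros(image_shape)
    for name, amp in true_amplitudes.items():
        if amp <= -1:
            raise ValueError(f"ROI {name!r}: amplitude {amp} <= -1 is non-physical")
        alpha[masks[name]] = amp / (2.0 + amp)

    tk = kernel[:, None, None] * alpha[None, :, :]
    f340 = baseline_f340 * bleach[:, None, None] * (1.0 + tk)
    f380 = baseline_f380 * bleach[:, None, None] * (1.0 - tk)
    rng = substream(config.seed, 0)
    f340 = _noise(rng, f340, config)
    f380 = _noise(rng, f380, config)
    stack340 = FrameStack(np.clip(f340, 0, None), wavelength_label="340", frame_rate=config.frame_rate)
    stack380 = FrameStack(np.clip(f380, 0, None), wavelength_label="380", frame_rate=config.frame_rate)
    truth = GroundTruth(amplitudes={n: float(true_amplitudes.get(n, 0.0)) for n in names})
    return stack340, stack380, rois, truth


# ---------------------------------------------------------------------------
# Response panels


def simulate_response_panel(
    planted_spectra: pd.DataFrame,
    noise_sd: float,
    n_animals: int = 12,
    seed: int = 0,
    solvent_label: str = "solvent",
    cluster_labels: Mapping[str, int] | None = None,
):
    """Per-animal amplitude rows drawn around planted receptor spectra.

    ``planted_spectra`` is receptors × stimuli (nonnegative mean amplitudes,
    %).  A solvent column with planted mean 0 is appended when absent.
    Returns a long-format table (animal, receptor, stimulus, amplitude) and
    the planted truth.  Fewer than 2 animals leaves all per-stimulus
    statistics undefined and is rejected.
    """
    if n_animals < 2:
        raise ValueError("n_animals must be >= 2")
    spectra = planted_spectra.copy().astype(float)
    if (spectra.values < 0).any():
        raise ValueError("planted spectra must be nonnegative")
    if solvent_label not in spectra.columns:
        spectra[solvent_label] = 0.0
    rows = []
    for i_rec, receptor in enumerate(spectra.index):
        means = spectra.loc[receptor].to_numpy()
        for animal in range(n_animals):
            rng = substream(seed, i_rec, animal)
            amps = means + rng.normal(0.0, noise_sd, size=means.size)
            for stim, amp in zip(spectra.columns, amps):
                rows.append((f"animal{animal + 1}", str(receptor), str(stim), amp))
    panel = pd.DataFrame(rows, columns=["animal", "receptor", "stimulus", "amplitude"])
    truth = GroundTruth(
        spectra=spectra,
        cluster_labels=dict(cluster_labels) if cluster_labels else None,
    )
    return panel, truth


def block_spectra(
    n_per_group: int = 2,
    n_stimuli: int = 22,
    signal: float = 1.0,
    group_fraction: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Two planted receptor groups responding to disjoint stimulus blocks.

    Group A responds with ``signal`` to the first half of the panel, group B
    to the second half; used for clustering-separation tests.  Returns the
    spectra and the planted group label of each receptor.
    """
    stimuli = [f"odorant{j + 1}" for j in range(n_stimuli)]
    half = int(round(n_stimuli * group_fraction))
    data, labels = {}, {}
    for g, (lo, hi) in enumerate([(0, half), (half, n_stimuli)]):
        for i in range(n_per_group):
            name = f"receptor_{'AB'[g]}{i + 1}"
            spec = np.zeros(n_stimuli)
            spec[lo:hi] = signal
            data[name] = spec
            labels[name] = g
    spectra = pd.DataFrame(data, index=stimuli).T
    return spectra, labels


# ---------------------------------------------------------------------------
# Dose series

DOSE_LADDER_UG = (0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0)
"""The 9-step logarithmic dose ladder (μg on filter paper) of the study."""

EC50_PRESETS_UG = {
    "AcerOR11": 174.8,
    "AdorOR11": 173.4,
    "AmelOR11": 160.5,
    "AflorOR11": 175.8,
}
"""Reported 9-ODA EC₅₀ values (μg) per receptor ortholog."""


def hill_response(dose, ec50: float, hill: float, top: float, bottom: float):
    """Four-parameter logistic response; dose 0 returns the bottom asymptote."""
    dose = np.asarray(dose, dtype=float)
    out = np.full(dose.shape, float(bottom))
    pos = dose > 0
    out[pos] = bottom + (top - bottom) / (1.0 + (ec50 / dose[pos]) ** hill)
    return out


def simulate_dose_series(
    doses: Sequence[float] = DOSE_LADDER_UG,
    ec50: float = 174.8,
    hill: float = 4.71,
    top: float = 1.0,
    bottom: float = 0.0,
    noise_sd: float = 0.15,
    n_animals: int = 12,
    seed: int = 0,
    include_solvent: bool = True,
):
    """Per-animal Hill-model dose-response replicates with planted parameters.

    Defaults follow the study conditions: the 9-dose ladder, EC₅₀ ≈ 175 μg,
    a steep Hill slope, n = 12 animals, and per-measurement Gaussian noise
    with SD 15% of the dynamic range.  A 0 μg solvent point drawn around
    the bottom asymptote is included by default.
    """
    doses = np.asarray(sorted(doses), dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive (the solvent 0 dose is added separately)")
    if hill <= 0:
        raise ValueError("hill coefficient must be positive")
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    all_doses = np.concatenate([[0.0], doses]) if include_solvent else doses
    mean_resp = hill_response(all_doses, ec50, hill, top, bottom)
    rows = []
    for animal in range(n_animals):
        rng = substream(seed, animal)
        resp = mean_resp + rng.normal(0.0, noise_sd * abs(top - bottom) if top != bottom else noise_sd,
                                      size=mean_resp.size)
        if noise_sd == 0:
            resp = mean_resp
        for d, r in zip(all_doses, resp):
            rows.append((f"animal{animal + 1}", d, r))
    series = pd.DataFrame(rows, columns=["animal", "dose", "amplitude"])
    truth = GroundTruth(ec50=ec50, hill=hill, top=top, bottom=bottom)
    return series, truth


# ---------------------------------------------------------------------------
# Spike trains


def simulate_spike_train(
    baseline_rate: float,
    stim_rate: float,
    stim_interval: tuple[float, float],
    duration: float,
    seed: int = 0,
    regular: bool = False,
    refractory_s: float = 0.003,
):
    """Inhomogeneous-Poisson spike times with a stimulus-driven rate step.

    The rate is ``baseline_rate`` outside ``stim_interval`` (seconds) and
    ``stim_rate`` inside.  Spikes falling within the absolute refractory
    period ``refractory_s`` of the previous spike are dropped, as in a real
    neuron.  ``regular=True`` instead emits perfectly periodic trains at
    each rate, for deterministic frequency tests.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if baseline_rate < 0 or stim_rate < 0:
        raise ValueError("rates must be >= 0")
    t0, t1 = stim_interval
    if not (0 <= t0 < t1 <= duration):
        raise ValueError(f"stim_interval {stim_interval} must lie inside [0, {duration}]")
    segments = [(0.0, t0, baseline_rate), (t0, t1, stim_rate), (t1, duration, baseline_rate)]
    rng = substream(seed, 0)
    times = []
    for a, b, rate in segments:
        if b <= a or rate == 0:
            continue
        if regular:
            times.append(np.arange(a + 1.0 / rate, b + 1e-12, 1.0 / rate))
        else:
            n = rng.poisson(rate * (b - a))
            times.append(np.sort(rng.uniform(a, b, size=n)))
    spike_times = np.unique(np.concatenate(times)) if times else np.empty(0)
    if refractory_s > 0 and spike_times.size:
        kept = [spike_times[0]]
        for t in spike_times[1:]:
            if t - kept[-1] >= refractory_s:
                kept.append(t)
        spike_times = np.asarray(kept)
    from .spikes import SpikeTrain  # local import to avoid a cycle

    train = SpikeTrain(times=spike_times, duration=duration, stimulus_interval=(t0, t1))
    truth = GroundTruth(baseline_rate=baseline_rate, stim_rate=stim_rate, spike_times=spike_times)
    return train, truth


def spike_waveform(fs: float, amplitude: float = 1.0) -> np.ndarray:
    """Biphasic extracellular spike template, ~2 ms, unit positive peak."""
    t = np.arange(0, 0.002, 1.0 / fs)
    w = np.exp(-((t - 0.0005) / 0.0002) ** 2) - 0.5 * np.exp(-((t - 0.0011) / 0.0004) ** 2)
    return amplitude * w / w.max()


def render_spike_trace(
    spike_times: np.ndarray,
    duration: float,
    fs: float = 10000.0,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Voltage-like sampled trace with spike waveforms on Gaussian noise.

    Returns (samples, fs).  The waveform's positive peak lands on the sample
    nearest each spike time, so detector timing can be scored exactly.
    """
    n = int(round(duration * fs))
    rng = substream(seed, 1)
    trace = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    w = spike_waveform(fs, amplitude)
    peak_off = int(np.argmax(w))
    for t in np.asarray(spike_times):
        start = int(round(t * fs)) - peak_off
        a, b = max(start, 0), min(start + len(w), n)
        if b > a:
            trace[a:b] += w[a - start : b - start]
    return trace, fs
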