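"""Signal chain from raw fluorescence to response amplitudes.

Two processing conventions are supported, matching the two preparations the
pipeline is built for:

* **fly** (single-wavelength GCaMP, transcuticular antennal imaging):
  ΔF/F₀ = (F − F₀)/F₀ with F₀ the mean over the five pre-stimulus frames
  (frames 10–14, 1-based); photobleaching is corrected by subtracting the
  ΔF/F₀ trace of a stimulus-free (blank) recording; the response amplitude
  is the mean ΔF/F₀ over frames 17–31.
* **bee** (ratiometric Fura-2, antennal-lobe imaging): the excitation
  ratio R = F340/F380 is formed per pixel and frame, ΔR/R = (R − R₀)/R₀
  with R₀ the mean over frames 10–14, a width-3 median filter is applied
  along x, y and t, a logarithmic curve a + b·ln(t + 1) fitted outside the
  stimulus/post-stimulus window is subtracted (bleach correction), and the
  amplitude is mean(frames 17–19) − mean(frames 9–11).

Delta traces are stored as dimensionless fractions; multiply by 100 for the
percent values used in reports and figures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter as _nd_median_filter

from ._frames import FrameWindow, window_slice, validate_window
from .imaging_io import AcquisitionProtocol, FrameStack, ROISet

__all__ = [
    "FluorescenceTrace",
    "DeltaTrace",
    "RatiometricTrace",
    "ResponseAmplitude",
    "delta_f_over_f0",
    "blank_subtraction",
    "ratio_timeseries",
    "delta_r_over_r",
    "median_filter_3",
    "log_bleach_correction",
    "response_amplitude",
    "fly_pipeline",
    "bee_pipeline",
]


@dataclass
class FluorescenceTrace:
    """Per-ROI raw fluorescence time series (arbitrary units)."""

    values: np.ndarray
    protocol: AcquisitionProtocol
    roi: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")
        if len(self.values) != self.protocol.n_frames:
            raise ValueError(
                f"trace length {len(self.values)} != protocol n_frames {self.protocol.n_frames}"
            )


@dataclass
class DeltaTrace:
    """Relative change per frame (ΔF/F₀ or ΔR/R, dimensionless fraction)."""

    values: np.ndarray
    baseline_value: float  # F0 or R0
    protocol: AcquisitionProtocol
    kind: str = "dF/F0"  # "dF/F0" | "dR/R"
    roi: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def percent(self) -> np.ndarray:
        return self.values * 100.0


@dataclass
class RatiometricTrace:
    """R = F340/F380 per ROI (1-D) or per pixel (frames × h × w)."""

    r_values: np.ndarray
    protocol: AcquisitionProtocol
    n_masked: int = 0  # samples masked because F380 <= 0


@dataclass
class ResponseAmplitude:
    """Scalar response amplitude (dimensionless fraction; ×100 for %)."""

    value: float
    convention: str  # "fly" | "bee"
    stimulus: str | None = None
    animal: str | None = None
    roi: str | None = None

    @property
    def percent(self) -> float:
        return self.value * 100.0


# ---------------------------------------------------------------------------
# ΔF/F0 and blank subtraction (fly chain)


def delta_f_over_f0(trace: FluorescenceTrace) -> DeltaTrace:
    """ΔF/F₀ = (F − F₀)/F₀, F₀ = mean fluorescence over the baseline window."""
    f0 = float(np.mean(trace.values[window_slice(trace.protocol.baseline_window)]))
    if f0 <= 0:
        raise ValueError(f"non-physical baseline F0 = {f0:g} (must be > 0)")
    return DeltaTrace(
        values=(trace.values - f0) / f0,
        baseline_value=f0,
        protocol=trace.protocol,
        kind="dF/F0",
        roi=trace.roi,
    )


def blank_subtraction(delta: DeltaTrace, blank: DeltaTrace) -> DeltaTrace:
    """Subtract a stimulus-free recording framewise (photobleach correction)."""
    if len(delta.values) != len(blank.values):
        raise ValueError(
            f"trace length {len(delta.values)} != blank length {len(blank.values)}"
        )
    if delta.protocol != blank.protocol:
        raise ValueError("trace and blank were recorded under different protocols")
    return DeltaTrace(
        values=delta.values - blank.values,
        baseline_value=delta.baseline_value,
        protocol=delta.protocol,
        kind=delta.kind,
        roi=delta.roi,
    )


# ---------------------------------------------------------------------------
# Ratiometric chain (bee)


def ratio_timeseries(
    f340: FrameStack | FluorescenceTrace | np.ndarray,
    f380: FrameStack | FluorescenceTrace | np.ndarray,
    protocol: AcquisitionProtocol | None = None,
) -> RatiometricTrace:
    """Excitation ratio R = F340/F380 per pixel (stacks) or per ROI (traces).

    Samples with F380 ≤ 0 are masked to NaN with a warning; if any masked
    sample falls inside the baseline window the ratio baseline R₀ would be
    undefined and an error is raised instead.
    """
    def unwrap(x):
        nonlocal protocol
        if isinstance(x, FrameStack):
            return x.pixels
        if isinstance(x, FluorescenceTrace):
            protocol = protocol or x.protocol
            return x.values
        return np.asarray(x, dtype=float)

    a340, a380 = unwrap(f340), unwrap(f380)
    if protocol is None:
        raise ValueError("an AcquisitionProtocol is required")
    if a340.shape != a380.shape:
        raise ValueError(f"wavelength channels differ in shape: {a340.shape} vs {a380.shape}")
    bad = a380 <= 0
    n_masked = int(bad.sum())
    if n_masked:
        bsl = window_slice(protocol.baseline_window)
        if bad[bsl].any():
            raise ValueError(
                "F380 <= 0 inside the baseline window; ratio baseline R0 undefined"
            )
        warnings.warn(f"masked {n_masked} samples with F380 <= 0", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(bad, np.nan, a340 / np.where(bad, 1.0, a380))
    return RatiometricTrace(r_values=r, protocol=protocol, n_masked=n_masked)


def delta_r_over_r(ratio: RatiometricTrace) -> DeltaTrace | np.ndarray:
    """ΔR/R = (R − R₀)/R₀ with R₀ the baseline-window mean (per pixel/ROI).

    1-D ratios return a :class:`DeltaTrace`; pixelwise stacks return the
    ΔR/R array (frames first) for further filtering before ROI averaging.
    """
    r = ratio.r_values
    r0 = np.nanmean(r[window_slice(ratio.protocol.baseline_window)], axis=0)
    if np.any(np.asarray(r0) <= 0):
        raise ValueError("non-physical ratio baseline R0 <= 0")
    delta = (r - r0) / r0
    if r.ndim == 1:
        return DeltaTrace(
            values=delta, baseline_value=float(r0), protocol=ratio.protocol, kind="dR/R"
        )
    return delta


# ---------------------------------------------------------------------------
# Median filter


def median_filter_3(data: np.ndarray, axes: tuple[int, ...] | None = None) -> np.ndarray:
    """Sequential width-3 median filter along each axis (reflect padding).

    For a (frames, height, width) stack the default order is x, then y,
    then t — three separable per-axis passes, not a 3×3×3 cube median.
    Axes shorter than 3 samples are skipped with a warning.
    """
    data = np.asarray(data, dtype=float)
    if axes is None:
        # spatial first (x = last axis, then y), temporal (axis 0) last
        axes = tuple(range(data.ndim - 1, -1, -1))
    out = data
    for ax in axes:
        if data.shape[ax] < 3:
            warnings.warn(
                f"axis {ax} has fewer than 3 samples; median filter skipped", stacklevel=2
            )
            continue
        size = [1] * data.ndim
        size[ax] = 3
        out = _nd_median_filter(out, size=tuple(size), mode="reflect")
    return out


# ---------------------------------------------------------------------------
# Logarithmic bleach correction


def log_bleach_correction(
    delta: DeltaTrace,
    exclusion: FrameWindow | None = None,
    model: str = "log",
) -> DeltaTrace:
    """Subtract a fitted slow-decay curve from a delta trace.

    A curve f(t) = a + b·ln(t + 1) (t = 0-based frame index; ``model="exp"``
    uses a·exp(−t/τ) + c instead) is least-squares fitted to the trace with
    the stimulus/post-stimulus interval excluded — by default the protocol's
    ``bleach_exclusion`` window, stimulus onset through 5 s after onset —
    and subtracted over all frames.  A (near-)constant input yields the
    input minus its mean, with a warning.
    """
    y = np.asarray(delta.values, dtype=float)
    n = len(y)
    if exclusion is None:
        exclusion = delta.protocol.bleach_exclusion
    keep = np.ones(n, dtype=bool)
    if exclusion is not None:
        validate_window(exclusion, n, "bleach exclusion")
        keep[window_slice(exclusion)] = False
    if keep.sum() < 5:
        raise ValueError("need at least 5 frames outside the bleach-exclusion window")
    t = np.arange(n, dtype=float)

    if np.ptp(y[keep]) < 1e-14:
        warnings.warn("constant trace: bleach fit degenerate, subtracting mean", stacklevel=2)
        return _replace_values(delta, y - y[keep].mean())

    if model == "log":
        design = np.column_stack([np.ones(n), np.log(t + 1.0)])
        coef, *_ = np.linalg.lstsq(design[keep], y[keep], rcond=None)
        fitted = design @ coef
    elif model == "exp":
        from scipy.optimize import curve_fit

        def f(t, a, tau, c):
            return a * np.exp(-t / tau) + c

        p0 = (y[keep][0] - y[keep][-1], n / 2.0, y[keep][-1])
        coef, _ = curve_fit(f, t[keep], y[keep], p0=p0, maxfev=20000)
        fitted = f(t, *coef)
    else:
        raise ValueError(f"unknown bleach model {model!r} (use 'log' or 'exp')")
    return _replace_values(delta, y - fitted)


def _replace_values(delta: DeltaTrace, values: np.ndarray) -> DeltaTrace:
    return DeltaTrace(
        values=values,
        baseline_value=delta.baseline_value,
        protocol=delta.protocol,
        kind=delta.kind,
        roi=delta.roi,
    )


# ---------------------------------------------------------------------------
# Response amplitude


def response_amplitude(delta: DeltaTrace, convention: str, **ids) -> ResponseAmplitude:
    """Window-mean response amplitude.

    bee: mean over the response window (frames 17–19) minus mean over the
    pre-stimulus window (frames 9–11).  Invariant under additive offsets.

    fly: mean over the response window (frames 17–31) minus mean over the
    baseline window; the second term is zero by ΔF/F₀ construction but is
    retained so the amplitude is robust to offset traces (e.g. after blank
    subtraction).
    """
    p = delta.protocol
    if convention == "bee":
        if p.prestim_window is None:
            raise ValueError("bee convention requires a prestim_window in the protocol")
        ref = p.prestim_window
    elif convention == "fly":
        ref = p.baseline_window
    else:
        raise ValueError(f"unknown amplitude convention {convention!r} (use 'fly' or 'bee')")
    value = float(
        np.mean(delta.values[window_slice(p.response_window)])
        - np.mean(delta.values[window_slice(ref)])
    )
    return ResponseAmplitude(value=value, convention=convention, roi=delta.roi, **ids)


# ---------------------------------------------------------------------------
# End-to-end pipelines


def fly_pipeline(
    trace: FluorescenceTrace,
    blank: FluorescenceTrace | DeltaTrace | None = None,
    bleach: str = "blank",
    **ids,
) -> ResponseAmplitude:
    """Single-wavelength chain: ΔF/F₀ → bleach correction → amplitude.

    ``bleach`` selects the correction: ``"blank"`` subtracts the ΔF/F₀ of a
    stimulus-free recording (requires ``blank``), ``"log"`` fits and removes
    a logarithmic decay, ``"none"`` skips correction.
    """
    delta = delta_f_over_f0(trace)
    if bleach == "blank":
        if blank is None:
            raise ValueError("blank bleach correction requires a blank recording")
        blank_delta = blank if isinstance(blank, DeltaTrace) else delta_f_over_f0(blank)
        delta = blank_subtraction(delta, blank_delta)
    elif bleach == "log":
        delta = log_bleach_correction(delta)
    elif bleach != "none":
        raise ValueError(f"unknown bleach mode {bleach!r}")
    return response_amplitude(delta, "fly", **ids)


def bee_pipeline(
    f340: FrameStack,
    f380: FrameStack,
    rois: ROISet,
    protocol: AcquisitionProtocol,
    median_filter: bool = True,
    bleach: str = "log",
) -> dict[str, ResponseAmplitude]:
    """Ratiometric chain: R → ΔR/R → median filter → bleach → ROI amplitudes."""
    ratio = ratio_timeseries(f340, f380, protocol)
    delta_stack = delta_r_over_r(ratio)
    if median_filter:
        delta_stack = median_filter_3(delta_stack)
    out = {}
    for name in rois.names():
        mask = rois.mask(name, f340.shape)
        if not mask.any():
            raise ValueError(f"ROI {name!r} covers no pixel")
        trace = DeltaTrace(
            values=delta_stack[:, mask].mean(axis=1),
            baseline_value=float("nan"),
            protocol=protocol,
            kind="dR/R",
            roi=name,
        )
        if bleach == "log":
            trace = log_bleach_correction(trace)
        elif bleach != "none":
            raise ValueError(f"unknown bleach mode {bleach!r}")
        out[name] = response_amplitude(trace, "bee")
    return out
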