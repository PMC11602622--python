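"""Frame-stack, ROI, protocol and table I/O plus ROI trace extraction.

Containers
----------
:class:`FrameStack`
    A ``frames × height × width`` intensity array at one excitation
    wavelength (single-wavelength GCaMP recordings, or the 340 nm / 380 nm
    channels of a Fura-2 recording stored as two stacks).
:class:`ROISet`
    Named polygonal regions of interest in pixel coordinates (0-based,
    pixel-center convention, origin top-left).
:class:`AcquisitionProtocol`
    Frame rate and the 1-based inclusive frame windows (baseline, stimulus,
    response, pre-stimulus, bleach-fit exclusion) that parameterize the
    signal chain.  Two presets ship with the package: ``"bee"`` for
    ratiometric antennal-lobe recordings (amplitude = frames 17–19 minus
    frames 9–11) and ``"fly"`` for single-wavelength transcuticular antennal
    recordings (amplitude window frames 17–31).  Both use 100 frames at
    5 Hz with a 1 s stimulus at frames 15–20 and baseline frames 10–14.

File formats: TIFF for stacks (via tifffile), JSON for ROI polygons, YAML
for protocols, long-format CSV for traces and amplitude tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from skimage.draw import polygon as _sk_polygon

from ._frames import FrameWindow, validate_window, windows_overlap

__all__ = [
    "FrameStack",
    "ROISet",
    "AcquisitionProtocol",
    "FormatError",
    "read_stack",
    "write_stack",
    "read_rois",
    "write_rois",
    "read_protocol",
    "write_protocol",
    "extract_roi_traces",
    "read_trace_table",
    "write_trace_table",
    "read_amplitude_table",
    "write_amplitude_table",
    "PROTOCOL_PRESETS",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


# ---------------------------------------------------------------------------
# Frame stacks


@dataclass
class FrameStack:
    """Grayscale frame stack at a single excitation wavelength."""

    pixels: np.ndarray  # (frames, height, width)
    wavelength_label: str = "single"  # "single" | "340" | "380"
    frame_rate: float = 5.0  # Hz

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise FormatError(
                f"frame stack must be (frames, height, width), got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1:
            raise FormatError("frame stack must contain at least one frame")
        if not np.all(np.isfinite(self.pixels)):
            raise FormatError("frame stack contains non-finite intensities")
        if np.any(self.pixels < 0):
            raise FormatError("frame stack contains negative intensities")
        if self.wavelength_label not in ("single", "340", "380"):
            raise ValueError(f"unknown wavelength label {self.wavelength_label!r}")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of one frame."""
        return self.pixels.shape[1:]


def read_stack(path: str | Path, wavelength_label: str = "single", frame_rate: float = 5.0) -> FrameStack:
    """Read a TIFF frame stack.

    Raises :class:`FormatError` for truncated/corrupt files, ragged frame
    shapes or empty stacks — never a silent partial read.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            shapes = {page.shape for page in tf.pages}
            if len(shapes) > 1:
                raise FormatError(f"{path}: pages have inconsistent shapes {sorted(shapes)}")
            pixels = tf.asarray()
    except FormatError:
        raise
    except Exception as exc:  # tifffile raises assorted exception types
        raise FormatError(f"{path}: not a readable TIFF stack ({exc})") from exc
    if pixels.ndim == 2:
        pixels = pixels[None]
    if pixels.ndim != 3 or pixels.shape[0] < 1:
        raise FormatError(f"{path}: expected a frames × height × width stack, got shape {pixels.shape}")
    return FrameStack(pixels=pixels, wavelength_label=wavelength_label, frame_rate=frame_rate)


def write_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a frame stack as a multi-page TIFF (lossless for integer data)."""
    tifffile.imwrite(Path(path), stack.pixels, photometric="minisblack")


# ---------------------------------------------------------------------------
# ROIs


@dataclass
class ROISet:
    """Named ROI polygons.

    ``polygons`` maps name → array of (x, y) vertices in 0-based pixel
    coordinates (pixel-center convention, origin top-left, x = column,
    y = row).  A pixel belongs to the ROI when its center falls inside the
    polygon (closed boundary included, per skimage.draw.polygon).
    """

    polygons: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.polygons = {
            str(name): np.asarray(verts, dtype=float).reshape(-1, 2)
            for name, verts in self.polygons.items()
        }
        for name, verts in self.polygons.items():
            if len(verts) < 3:
                raise ValueError(f"ROI {name!r} needs at least 3 vertices")

    @classmethod
    def from_rectangles(cls, rects: Mapping[str, tuple[int, int, int, int]]) -> "ROISet":
        """Build from name → (x0, y0, x1, y1) inclusive pixel rectangles."""
        polys = {}
        for name, (x0, y0, x1, y1) in rects.items():
            polys[name] = np.array(
                [[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float
            )
        return cls(polygons=polys)

    def names(self) -> list[str]:
        return list(self.polygons)

    def mask(self, name: str, shape: tuple[int, int]) -> np.ndarray:
        """Boolean pixel mask of one ROI for a (height, width) frame shape."""
        verts = self.polygons[name]
        rr, cc = _sk_polygon(verts[:, 1], verts[:, 0], shape=shape)
        m = np.zeros(shape, dtype=bool)
        m[rr, cc] = True
        return m

    def masks(self, shape: tuple[int, int]) -> dict[str, np.ndarray]:
        return {name: self.mask(name, shape) for name in self.polygons}


def read_rois(path: str | Path) -> ROISet:
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict) or "rois" not in data:
        raise FormatError(f"{path}: expected a JSON object with a 'rois' key")
    return ROISet(polygons={r["name"]: np.asarray(r["vertices"], dtype=float) for r in data["rois"]})


def write_rois(rois: ROISet, path: str | Path) -> None:
    payload = {
        "coordinates": "0-based pixel centers, origin top-left, (x, y)",
        "rois": [
            {"name": name, "vertices": verts.tolist()}
            for name, verts in rois.polygons.items()
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# Acquisition protocol


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Frame rate plus the 1-based inclusive frame windows of an experiment.

    ``baseline_window`` defines F₀ (or R₀); ``response_window`` minus
    ``prestim_window`` (bee convention) or ``response_window`` alone relative
    to the baseline (fly convention) defines the response amplitude;
    ``bleach_exclusion`` is the interval left out of the logarithmic
    bleach fit (stimulus onset through 5 s after onset).
    """

    frame_rate: float = 5.0
    n_frames: int = 100
    baseline_window: FrameWindow = (10, 14)
    stimulus_window: FrameWindow = (15, 20)
    response_window: FrameWindow = (17, 19)
    prestim_window: FrameWindow | None = (9, 11)
    bleach_exclusion: FrameWindow | None = (15, 40)

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        validate_window(self.baseline_window, self.n_frames, "baseline_window")
        validate_window(self.stimulus_window, self.n_frames, "stimulus_window")
        validate_window(self.response_window, self.n_frames, "response_window")
        if self.prestim_window is not None:
            validate_window(self.prestim_window, self.n_frames, "prestim_window")
        if self.bleach_exclusion is not None:
            validate_window(self.bleach_exclusion, self.n_frames, "bleach_exclusion")
        if windows_overlap(self.baseline_window, self.stimulus_window):
            raise ValueError(
                f"baseline window {self.baseline_window} must end before "
                f"stimulus window {self.stimulus_window} starts"
            )


# The bee bleach-exclusion end is stimulus onset (frame 15) plus 5 s at 5 Hz.
PROTOCOL_PRESETS: dict[str, AcquisitionProtocol] = {
    "bee": AcquisitionProtocol(
        frame_rate=5.0,
        n_frames=100,
        baseline_window=(10, 14),
        stimulus_window=(15, 20),
        response_window=(17, 19),
        prestim_window=(9, 11),
        bleach_exclusion=(15, 40),
    ),
    "fly": AcquisitionProtocol(
        frame_rate=5.0,
        n_frames=100,
        baseline_window=(10, 14),
        stimulus_window=(15, 20),
        response_window=(17, 31),
        prestim_window=None,
        bleach_exclusion=(15, 40),
    ),
}

_PROTOCOL_KEYS = {
    "preset",
    "frame_rate",
    "n_frames",
    "baseline_window",
    "stimulus_window",
    "response_window",
    "prestim_window",
    "bleach_exclusion",
}


def read_protocol(path: str | Path) -> AcquisitionProtocol:
    """Read an acquisition protocol from YAML.

    A ``preset: bee|fly`` key fills defaults; any explicit key overrides the
    preset.  Unknown keys are rejected.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:  # includes the line/column mark
        raise FormatError(f"{path}: malformed YAML — {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: protocol file must contain a mapping")
    unknown = set(data) - _PROTOCOL_KEYS
    if unknown:
        raise FormatError(f"{path}: unknown protocol keys {sorted(unknown)}")
    preset = data.pop("preset", None)
    if preset is not None:
        if preset not in PROTOCOL_PRESETS:
            raise FormatError(f"{path}: unknown preset {preset!r} (available: {sorted(PROTOCOL_PRESETS)})")
        base = asdict(PROTOCOL_PRESETS[preset])
    else:
        base = asdict(AcquisitionProtocol())
    base.update(data)
    for key in ("baseline_window", "stimulus_window", "response_window", "prestim_window", "bleach_exclusion"):
        if base[key] is not None:
            base[key] = tuple(base[key])
    return AcquisitionProtocol(**base)


def write_protocol(protocol: AcquisitionProtocol, path: str | Path) -> None:
    data = asdict(protocol)
    data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# ROI trace extraction


def extract_roi_traces(stack: FrameStack, rois: ROISet) -> pd.DataFrame:
    """Average pixel intensity inside each ROI at each frame.

    Returns a DataFrame with one column per ROI and one row per frame
    (``trace[t] = unweighted mean of pixels inside the ROI at frame t``).
    ROIs covering no pixel raise a ValueError naming the ROI.
    """
    shape = stack.shape
    traces = {}
    for name in rois.names():
        mask = rois.mask(name, shape)
        if not mask.any():
            raise ValueError(f"ROI {name!r} covers no pixel inside the {shape} image")
        traces[name] = stack.pixels[:, mask].mean(axis=1)
    df = pd.DataFrame(traces)
    df.index.name = "frame"
    return df


# ---------------------------------------------------------------------------
# Long-format tables

TRACE_COLUMNS = ["animal", "receptor", "stimulus", "frame", "value"]
AMPLITUDE_COLUMNS = ["animal", "receptor", "stimulus", "dose", "amplitude"]


def _check_columns(df: pd.DataFrame, required: Sequence[str], path: str | Path) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def read_trace_table(path: str | Path) -> pd.DataFrame:
    """Long-format per-frame trace table: animal, receptor, stimulus, frame, value."""
    return _check_columns(pd.read_csv(path), TRACE_COLUMNS, path)


def write_trace_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_amplitude_table(path: str | Path) -> pd.DataFrame:
    """Long-format amplitude table: animal, receptor, stimulus, dose, amplitude (%)."""
    df = pd.read_csv(path)
    if "dose" not in df.columns:
        df = df.assign(dose=np.nan)
    return _check_columns(df, AMPLITUDE_COLUMNS, path)


def write_amplitude_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
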