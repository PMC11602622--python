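"""Centralized 1-based ↔ 0-based frame-interval conversion.

Acquisition protocols and all user-facing reports count frames 1-based with
inclusive endpoints (frame 1 is the first frame recorded); internal numpy
arrays are 0-based.  Every window conversion in the package goes through
:func:`window_slice` / :func:`window_indices` so the off-by-one convention
lives in exactly one place.
"""

from __future__ import annotations

import numpy as np

FrameWindow = tuple[int, int]


def validate_window(window: FrameWindow, n_frames: int | None = None, name: str = "window") -> FrameWindow:
    """Check a 1-based inclusive frame interval and return it as a tuple."""
    a, b = int(window[0]), int(window[1])
    if a < 1 or b < a:
        raise ValueError(f"{name} must satisfy 1 <= start <= stop, got [{a}, {b}]")
    if n_frames is not None and b > n_frames:
        raise ValueError(f"{name} [{a}, {b}] exceeds recording length {n_frames}")
    return (a, b)


def window_slice(window: FrameWindow) -> slice:
    """Slice selecting a 1-based inclusive frame interval from a 0-based array."""
    a, b = window
    return slice(a - 1, b)


def window_indices(window: FrameWindow) -> np.ndarray:
    """0-based frame indices of a 1-based inclusive interval."""
    a, b = window
    return np.arange(a - 1, b)


def window_length(window: FrameWindow) -> int:
    a, b = window
    return b - a + 1


def windows_overlap(w1: FrameWindow, w2: FrameWindow) -> bool:
    return w1[0] <= w2[1] and w2[0] <= w1[1]
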