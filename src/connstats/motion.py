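"""Head-motion quantification and frame censoring.

Framewise displacement (FD) summarizes per-frame head motion as the L1 norm
of the backward differences of the six rigid-body realignment parameters,
with rotations (radians) converted to millimeters of arc on a 50 mm sphere.
Frames with FD above 0.2 mm are censored; subjects retaining fewer than
8 min of data (600 frames at TR 0.8 s) are excluded rather than silently
truncated.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "compute_fd",
    "censor_frames",
    "min_frames_for_duration",
    "InsufficientFramesError",
]

DEFAULT_FD_THRESHOLD_MM = 0.2
DEFAULT_MIN_FRAMES = 600
DEFAULT_HEAD_RADIUS_MM = 50.0


class InsufficientFramesError(Exception):
    """Subject retains too few low-motion frames for reliable connectivity."""

    def __init__(self, retained: int, min_frames: int, subject: str | None = None):
        self.retained = retained
        self.min_frames = min_frames
        self.subject = subject
        who = f"subject {subject}: " if subject else ""
        super().__init__(
            f"{who}only {retained} frames retained after censoring "
            f"(minimum {min_frames})"
        )


def compute_fd(
    motion_params: np.ndarray, head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
) -> np.ndarray:
    """Framewise displacement from 6-dof realignment parameters.

    ``motion_params`` is (frames, 6): three translations in mm followed by
    three rotations in radians.  ``FD_t = sum|d trans| + r * sum|d rot|``;
    the first frame's FD is 0 by definition.
    """
    params = np.asarray(motion_params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError(
            f"motion parameters must have 6 columns (3 trans mm, 3 rot rad); "
            f"got shape {params.shape}"
        )
    if params.shape[0] < 1:
        raise ValueError("need at least one frame")
    diffs = np.abs(np.diff(params, axis=0))
    fd = np.zeros(params.shape[0])
    fd[1:] = diffs[:, :3].sum(axis=1) + head_radius_mm * diffs[:, 3:].sum(axis=1)
    return fd


def censor_frames(
    fd: np.ndarray,
    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
    min_frames: int = DEFAULT_MIN_FRAMES,
    subject: str | None = None,
) -> np.ndarray:
    """Boolean retained-frame mask: True where ``FD <= threshold``.

    Frames exactly at the threshold are retained (the exclusion rule is
    ``FD > threshold``).  Raises :class:`InsufficientFramesError` if fewer
    than ``min_frames`` frames survive, so exclusion is an explicit, typed
    event callers must handle.
    """
    if fd_threshold_mm <= 0:
        raise ValueError("fd_threshold_mm must be positive")
    fd = np.asarray(fd, dtype=float)
    if np.any(fd < 0):
        raise ValueError("FD values must be non-negative")
    mask = fd <= fd_threshold_mm
    retained = int(mask.sum())
    if retained < min_frames:
        raise InsufficientFramesError(retained, min_frames, subject=subject)
    return mask


def min_frames_for_duration(minutes: float, tr_seconds: float) -> int:
    """Frame count corresponding to a scan duration (e.g. 8 min at TR 0.8 s -> 600)."""
    if minutes <= 0 or tr_seconds <= 0:
        raise ValueError("duration and TR must be positive")
    return int(round(minutes * 60.0 / tr_seconds))
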