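"""Head-yaw sequences and their mapping onto interviewer focus regions.

In the triadic setup one interviewer (A) sits across the table from the
participant and the other (B) to the side, so a head turn from one
interviewer to the other spans roughly 45 degrees.  Each interviewer owns
an angular region extending ``half_width`` degrees to either side of their
direction; a frame whose yaw lies inside a region is attributed to that
interviewer, any other yaw to neither.  Head orientation (not eye gaze) is
the attention proxy throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "FocusLabel",
    "RegionLayout",
    "OrientationSequence",
    "NoDataError",
    "classify_frame",
    "classify_sequence",
    "normalize_yaw",
    "labels_from_strings",
    "labels_to_strings",
]


class NoDataError(ValueError):
    """Raised when an operation receives an empty sequence."""


class FocusLabel(IntEnum):
    """Per-frame attention target: interviewer A, interviewer B, or neither."""

    A = 0
    B = 1
    NONE = 2


_LABEL_STR = {FocusLabel.A: "A", FocusLabel.B: "B", FocusLabel.NONE: "NONE"}
_STR_LABEL = {v: k for k, v in _LABEL_STR.items()}


def labels_to_strings(labels) -> list[str]:
    return [_LABEL_STR[FocusLabel(int(v))] for v in np.asarray(labels).ravel()]


def labels_from_strings(strings) -> np.ndarray:
    try:
        return np.array([_STR_LABEL[s] for s in strings], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - message only
        raise ValueError(f"unknown focus label {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class RegionLayout:
    """Angular geometry of the two interviewer regions.

    Defaults place interviewer A straight ahead (0 deg) and interviewer B at
    45 deg, each owning a closed interval of +/-15 deg.  The two intervals
    must be disjoint.
    """

    interviewer_a_center: float = 0.0
    interviewer_b_center: float = 45.0
    half_width: float = 15.0

    def __post_init__(self):
        if not self.half_width > 0:
            raise ValueError("half_width must be positive")
        if abs(self.interviewer_a_center - self.interviewer_b_center) <= 2 * self.half_width:
            raise ValueError("interviewer regions overlap; centers must be separated by more than 2*half_width")

    def interval(self, target: FocusLabel) -> tuple[float, float]:
        center = self.interviewer_a_center if target == FocusLabel.A else self.interviewer_b_center
        return (center - self.half_width, center + self.half_width)


@dataclass(frozen=True)
class OrientationSequence:
    """Per-frame head yaw in degrees, sampled at a fixed frame period.

    The default frame period of 0.75 s corresponds to the ~1.3 fps tracking
    rate of the ceiling-mounted orientation estimator.
    """

    yaw: np.ndarray
    frame_period: float = 0.75

    def __post_init__(self):
        yaw = np.asarray(self.yaw, dtype=float)
        if yaw.ndim != 1 or yaw.size == 0:
            raise NoDataError("orientation sequence must contain at least one frame")
        if not np.all(np.isfinite(yaw)):
            raise ValueError("yaw values must be finite")
        if not self.frame_period > 0:
            raise ValueError("frame_period must be positive")
        object.__setattr__(self, "yaw", yaw)

    def __len__(self) -> int:
        return self.yaw.size

    @property
    def duration_seconds(self) -> float:
        return self.yaw.size * self.frame_period


def normalize_yaw(yaw):
    """Map angles into the canonical interval (-180, 180]."""
    yaw = np.asarray(yaw, dtype=float)
    wrapped = -((-yaw + 180.0) % 360.0 - 180.0)
    return wrapped


def _classify_array(yaw: np.ndarray, layout: RegionLayout) -> np.ndarray:
    yaw = normalize_yaw(yaw)
    out = np.full(yaw.shape, FocusLabel.NONE, dtype=np.int8)
    for target in (FocusLabel.A, FocusLabel.B):
        lo, hi = layout.interval(target)
        out[(yaw >= lo) & (yaw <= hi)] = target  # closed on both ends
    return out


def classify_frame(yaw: float, layout: RegionLayout | None = None) -> FocusLabel:
    """Classify a single yaw angle into A, B or NONE.

    Region intervals are closed on both ends: a yaw exactly on a boundary
    belongs to the region.
    """
    layout = layout or RegionLayout()
    return FocusLabel(int(_classify_array(np.asarray([yaw]), layout)[0]))


def classify_sequence(seq, layout: RegionLayout | None = None) -> np.ndarray:
    """Classify every frame of a sequence; returns an int8 FocusLabel array.

    Accepts an :class:`OrientationSequence` or any 1-D array of yaw degrees.
    """
    layout = layout or RegionLayout()
    yaw = seq.yaw if isinstance(seq, OrientationSequence) else np.asarray(seq, dtype=float)
    if yaw.size == 0:
        raise NoDataError("cannot classify an empty sequence")
    return _classify_array(yaw, layout)
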