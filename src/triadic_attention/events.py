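"""Contact and exclusion event detection on focus-label sequences.

Two behavioral events are extracted from the per-frame focus labels:

* **Contact** -- the participant orients toward one interviewer for at
  least ``min_contact_len`` consecutive frames (default 3, about 2.5 s).
  Contacts are maximal same-target runs.
* **Exclusion** -- a stretch of conversation during which one interviewer
  receives no attention while the other receives most of it.  A 20-frame
  window qualifies as excluding interviewer Y when at least 15 of its
  frames are oriented toward the other interviewer X and none toward Y.
  Windows are evaluated at every start index (rolling, stride 1) and
  overlapping or abutting qualifying windows for the same excluded
  interviewer merge into one maximal episode whose span is their union.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .orientation import FocusLabel, NoDataError

__all__ = [
    "ContactEvent",
    "ExclusionEpisode",
    "detect_contacts",
    "qualifying_windows",
    "detect_exclusions",
]


@dataclass(frozen=True)
class ContactEvent:
    """A maximal run of >= min_contact_len frames toward one interviewer.

    Frame spans are 0-based and inclusive on both ends.
    """

    target: FocusLabel
    start_frame: int
    end_frame: int

    def __post_init__(self):
        if self.target not in (FocusLabel.A, FocusLabel.B):
            raise ValueError("contact target must be an interviewer (A or B)")
        if self.end_frame < self.start_frame:
            raise ValueError("end_frame precedes start_frame")

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass(frozen=True)
class ExclusionEpisode:
    """A maximal union of qualifying windows excluding one interviewer."""

    excluded: FocusLabel
    start_frame: int
    end_frame: int

    def __post_init__(self):
        if self.excluded not in (FocusLabel.A, FocusLabel.B):
            raise ValueError("excluded party must be an interviewer (A or B)")
        if self.end_frame < self.start_frame:
            raise ValueError("end_frame precedes start_frame")

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def _as_label_array(labels) -> np.ndarray:
    arr = np.asarray(labels, dtype=np.int8)
    if arr.ndim != 1:
        raise ValueError("labels must be one-dimensional")
    return arr


def detect_contacts(labels, min_contact_len: int = 3) -> list[ContactEvent]:
    """Return every maximal same-interviewer run of length >= min_contact_len.

    Runs of NONE never produce events.  Events are ordered by start frame.
    """
    arr = _as_label_array(labels)
    if arr.size == 0:
        raise NoDataError("cannot detect contacts in an empty label sequence")
    if min_contact_len < 1:
        raise ValueError("min_contact_len must be >= 1")

    # run-length encode: boundaries where the label changes
    change = np.flatnonzero(arr[1:] != arr[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [arr.size - 1]))
    events = []
    for s, e in zip(starts, ends):
        lab = FocusLabel(int(arr[s]))
        if lab is FocusLabel.NONE:
            continue
        if e - s + 1 >= min_contact_len:
            events.append(ContactEvent(target=lab, start_frame=int(s), end_frame=int(e)))
    return events


def qualifying_windows(
    labels, window_len: int = 20, majority: int = 15
) -> list[tuple[int, FocusLabel]]:
    """Enumerate (start index, excluded interviewer) for every qualifying window.

    A window starting at ``i`` qualifies as excluding Y iff among frames
    ``i .. i+window_len-1`` at least ``majority`` carry the other
    interviewer's label and none carry Y's.  Sequences shorter than the
    window yield an empty list.
    """
    arr = _as_label_array(labels)
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    if not 0 < majority <= window_len:
        raise ValueError("majority must satisfy 0 < majority <= window_len")
    n = arr.size
    if n < window_len:
        return []

    out: list[tuple[int, FocusLabel]] = []
    counts = {}
    for lab in (FocusLabel.A, FocusLabel.B):
        c = np.concatenate(([0], np.cumsum(arr == lab)))
        counts[lab] = c[window_len:] - c[:-window_len]  # per-start window counts
    qa = (counts[FocusLabel.A] >= majority) & (counts[FocusLabel.B] == 0)  # excludes B
    qb = (counts[FocusLabel.B] >= majority) & (counts[FocusLabel.A] == 0)  # excludes A
    for start in np.flatnonzero(qa):
        out.append((int(start), FocusLabel.B))
    for start in np.flatnonzero(qb):
        out.append((int(start), FocusLabel.A))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def _merge_window_starts(starts: np.ndarray, window_len: int) -> list[tuple[int, int]]:
    """Union of equal-length windows: merge starts whose spans overlap or abut."""
    if starts.size == 0:
        return []
    spans = []
    run_start = int(starts[0])
    prev = int(starts[0])
    for s in starts[1:]:
        s = int(s)
        # next window [s, s+w-1] overlaps or abuts [.., prev+w-1] iff s <= prev+w
        if s <= prev + window_len:
            prev = s
        else:
            spans.append((run_start, prev + window_len - 1))
            run_start = prev = s
    spans.append((run_start, prev + window_len - 1))
    return spans


def detect_exclusions(
    labels, window_len: int = 20, majority: int = 15
) -> list[ExclusionEpisode]:
    """Merge qualifying windows into maximal exclusion episodes.

    Merging is done independently per excluded interviewer; episode span is
    the union of the merged windows.  Episodes are ordered by start frame.
    """
    windows = qualifying_windows(labels, window_len=window_len, majority=majority)
    episodes: list[ExclusionEpisode] = []
    for excluded in (FocusLabel.A, FocusLabel.B):
        starts = np.array([s for s, who in windows if who == excluded], dtype=int)
        for s, e in _merge_window_starts(starts, window_len):
            episodes.append(ExclusionEpisode(excluded=excluded, start_frame=s, end_frame=e))
    episodes.sort(key=lambda ep: (ep.start_frame, ep.excluded))
    return episodes
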