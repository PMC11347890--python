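"""The five per-session attention-distribution statistics.

A session profile condenses one conversation into five domain statistics:

* ``AvgCon``   mean contact duration, frames
* ``AvgNoCon`` mean duration of maximal non-contact gaps, frames
* ``NumCon``   contacts per minute
* ``MaxExc``   longest exclusion episode, frames (0 when none)
* ``ExcPct``   percent of session frames covered by exclusion episodes

A session with no contacts has an undefined AvgCon (stored as NaN, never
0, which would masquerade as very short contacts) and NumCon 0; a session
with no exclusions contributes MaxExc 0 and ExcPct 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .events import detect_contacts, detect_exclusions
from .orientation import NoDataError

__all__ = ["SessionProfile", "compute_profile", "DOMAINS"]

DOMAINS = ("AvgCon", "AvgNoCon", "NumCon", "MaxExc", "ExcPct")


@dataclass(frozen=True)
class SessionProfile:
    """Five domain statistics plus raw counts for one session."""

    avg_con: float
    avg_no_con: float
    num_con: float
    max_exc: float
    exc_pct: float
    n_contacts: int
    n_exclusions: int
    session_frames: int

    def domain_value(self, domain: str) -> float:
        return {
            "AvgCon": self.avg_con,
            "AvgNoCon": self.avg_no_con,
            "NumCon": self.num_con,
            "MaxExc": self.max_exc,
            "ExcPct": self.exc_pct,
        }[domain]

    def to_dict(self) -> dict:
        d = {dom: self.domain_value(dom) for dom in DOMAINS}
        d.update(
            n_contacts=self.n_contacts,
            n_exclusions=self.n_exclusions,
            session_frames=self.session_frames,
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionProfile":
        return cls(
            avg_con=float(d["AvgCon"]) if d["AvgCon"] is not None else math.nan,
            avg_no_con=float(d["AvgNoCon"]),
            num_con=float(d["NumCon"]),
            max_exc=float(d["MaxExc"]),
            exc_pct=float(d["ExcPct"]),
            n_contacts=int(d["n_contacts"]),
            n_exclusions=int(d["n_exclusions"]),
            session_frames=int(d["session_frames"]),
        )


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        ls, le = merged[-1]
        if s <= le + 1:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def compute_profile(
    labels,
    frame_period: float = 0.75,
    min_contact_len: int = 3,
    window_len: int = 20,
    majority: int = 15,
) -> SessionProfile:
    """Compute the five domain statistics from a focus-label sequence.

    Contact durations pool both interviewers into one mean.  Non-contact
    gaps are the maximal runs of frames not covered by any contact event,
    including leading and trailing segments; a session with zero contacts
    has a single gap spanning the whole session.  ExcPct uses the union of
    exclusion episodes over both excluded interviewers, so overlap never
    double counts.
    """
    arr = np.asarray(labels, dtype=np.int8)
    if arr.size == 0:
        raise NoDataError("cannot profile an empty label sequence")
    n = arr.size

    contacts = detect_contacts(arr, min_contact_len=min_contact_len)
    exclusions = detect_exclusions(arr, window_len=window_len, majority=majority)

    durations = np.array([c.duration_frames for c in contacts], dtype=float)
    if durations.size:
        avg_con = float(durations.mean())
    else:
        avg_con = math.nan

    covered = np.zeros(n, dtype=bool)
    for c in contacts:
        covered[c.start_frame : c.end_frame + 1] = True
    # run-length encode the uncovered mask to get maximal non-contact gaps
    change = np.flatnonzero(covered[1:] != covered[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [n - 1]))
    gap_lengths = [e - s + 1 for s, e in zip(starts, ends) if not covered[s]]
    avg_no_con = float(np.mean(gap_lengths)) if gap_lengths else 0.0

    minutes = n * frame_period / 60.0
    num_con = len(contacts) / minutes

    if exclusions:
        max_exc = float(max(ep.duration_frames for ep in exclusions))
        union = _merge_intervals([(ep.start_frame, ep.end_frame) for ep in exclusions])
        exc_frames = sum(e - s + 1 for s, e in union)
        exc_pct = 100.0 * exc_frames / n
    else:
        max_exc = 0.0
        exc_pct = 0.0

    return SessionProfile(
        avg_con=avg_con,
        avg_no_con=avg_no_con,
        num_con=num_con,
        max_exc=max_exc,
        exc_pct=exc_pct,
        n_contacts=len(contacts),
        n_exclusions=len(exclusions),
        session_frames=n,
    )
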