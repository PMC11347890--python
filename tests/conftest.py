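import numpy as np
import pytest

from triadic_attention.orientation import labels_from_strings


@pytest.fixture
def labels():
    """Compact builder: labels('A A B NONE') -> int8 label array."""

    def build(spec: str) -> np.ndarray:
        return labels_from_strings(spec.split())

    return build


def brute_force_qualifying_windows(seq, window_len=20, majority=15):
    """Independent oracle: enumerate every window with plain counting."""
    out = []
    n = len(seq)
    for start in range(n - window_len + 1):
        win = list(seq[start : start + window_len])
        n_a = sum(1 for v in win if v == 0)
        n_b = sum(1 for v in win if v == 1)
        if n_a >= majority and n_b == 0:
            out.append((start, 1))  # excludes B
        if n_b >= majority and n_a == 0:
            out.append((start, 0))  # excludes A
    return out


def brute_force_exclusions(seq, window_len=20, majority=15):
    """Oracle episodes: interval union of qualifying windows, per excluded."""
    windows = brute_force_qualifying_windows(seq, window_len, majority)
    episodes = []
    for excl in (0, 1):
        intervals = sorted(
            (s, s + window_len - 1) for s, who in windows if who == excl
        )
        merged = []
        for s, e in intervals:
            if merged and s <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        episodes.extend((excl, s, e) for s, e in merged)
    episodes.sort(key=lambda t: (t[1], t[0]))
    return episodes
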