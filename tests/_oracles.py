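"""Independent brute-force oracles used by the test suite.

Deliberately naive: direct O(intervals x instants) membership checks,
with none of the searchsorted/cumsum machinery of the implementation.
"""

import numpy as np
import pandas as pd


def brute_force_counts(starts, ends, instants) -> np.ndarray:
    """#{intervals with start <= t < end} at each instant, by direct
    comparison."""
    starts = pd.DatetimeIndex(starts).to_numpy()
    ends = pd.DatetimeIndex(ends).to_numpy()
    t = pd.DatetimeIndex(instants).to_numpy()
    out = np.zeros(len(t), dtype=np.int64)
    for s, e in zip(starts, ends):
        out += (s <= t) & (t < e)
    return out


def brute_force_event_tally(times, instants, interval_minutes) -> np.ndarray:
    """#{events in [t, t + interval)} at each instant, by direct
    comparison."""
    times = pd.DatetimeIndex(times).to_numpy()
    t = pd.DatetimeIndex(instants).to_numpy()
    width = np.timedelta64(interval_minutes * 60, "s")
    out = np.zeros(len(t), dtype=np.int64)
    for tau in times:
        out += (t <= tau) & (tau < t + width)
    return out


def random_stays(rng, units, start, n, max_hours=96):
    """Random stay intervals with second-resolution, off-minute bounds."""
    t0 = pd.Timestamp(start)
    entry = t0 + pd.to_timedelta(rng.integers(0, 7 * 24 * 60, n), unit="m")
    entry = entry + pd.to_timedelta(rng.integers(1, 60, n), unit="s")
    exit_ = entry + pd.to_timedelta(rng.integers(30, max_hours * 60, n), unit="m")
    return pd.DataFrame(
        {
            "case_id": [f"P{i:05d}" for i in range(n)],
            "unit_id": rng.choice(np.array(units, dtype=object), n),
            "department": "D",
            "entry_ts": entry,
            "exit_ts": exit_,
            "entry_kind": rng.choice(np.array(["admission", "transfer_in"], dtype=object), n),
            "exit_kind": rng.choice(np.array(["discharge", "transfer_out"], dtype=object), n),
        }
    )


def random_segments(rng, units, start, n):
    t0 = pd.Timestamp(start)
    s = t0 + pd.to_timedelta(rng.integers(0, 7 * 24 * 60, n), unit="m")
    e = s + pd.to_timedelta(rng.integers(60, 10 * 60, n), unit="m")
    return pd.DataFrame(
        {
            "nurse_id": [f"N{i:05d}" for i in range(n)],
            "unit_id": rng.choice(np.array(units, dtype=object), n),
            "group": rng.integers(1, 4, n),
            "start_ts": s,
            "end_ts": e,
        }
    )
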