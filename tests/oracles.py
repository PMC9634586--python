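"""Independent brute-force oracles for the exposure statistics.

These deliberately avoid the implementation's algorithms (cumulative sums,
single-pass run merging): the window oracle scans every window explicitly and
the run oracle enumerates every pair of use days.
"""

from __future__ import annotations

import numpy as np


def brute_max_window_average(arr, window: int) -> float:
    """Exhaustive scan of all contiguous windows."""
    arr = np.asarray(arr, dtype=float)
    views = np.lib.stride_tricks.sliding_window_view(arr, window)
    return float(views.mean(axis=1).max())


def brute_max_run(arr, max_gap: int) -> int:
    """Exhaustive enumeration of all use-day pairs (i, j).

    A pair delimits a merged episode iff no internal gap of non-use days
    exceeds `max_gap`; the answer is the maximal span over valid pairs.
    """
    use = np.flatnonzero(np.asarray(arr) > 0)
    if use.size == 0:
        return 0
    gaps_bad = (np.diff(use) - 1) > max_gap
    bad_prefix = np.concatenate([[0], np.cumsum(gaps_bad)])
    # valid(i, j): no bad gap strictly between use[i] and use[j]
    valid = (bad_prefix[None, :] - bad_prefix[:, None]) == 0
    spans = use[None, :] - use[:, None] + 1
    upper = np.triu(np.ones_like(spans, dtype=bool))
    return int(spans[valid & upper].max())
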