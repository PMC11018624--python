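"""Sliding-window bookkeeping shared by the diversity, Fst and H scans.

Window coordinates are 0-based half-open (BED convention) throughout;
1-based site positions are converted internally.
"""

from __future__ import annotations

import numpy as np


def sliding_windows(chroms, positions, window_bp: int, step_bp: int):
    """Yield (chrom, start, end, site_index_array) for each window.

    Windows start at 0 and advance by ``step_bp`` until the last site of the
    chromosome is covered; a window spans [start, start + window_bp).
    Empty windows are yielded too (callers decide how to report them).
    """
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    for chrom in _unique_keep_order(chroms):
        mask = chroms == chrom
        pos0 = positions[mask] - 1  # to 0-based
        idx = np.where(mask)[0]
        if pos0.size == 0:
            continue
        last = pos0.max()
        start = 0
        while start <= last:
            in_win = (pos0 >= start) & (pos0 < start + window_bp)
            yield chrom, start, start + window_bp, idx[in_win]
            start += step_bp


def _unique_keep_order(arr):
    seen, out = set(), []
    for a in arr:
        if a not in seen:
            seen.add(a)
            out.append(a)
    return out
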