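"""Sorted-interval primitives shared across the pipeline.

All coordinates are 0-based, half-open ``[start, end)``. Interval sets are
represented as parallel integer arrays; most consumers work per chromosome.
The merge/complement/overlap routines here assume (and produce) sorted input
and are the single place interval arithmetic happens, so the convention
cannot drift between modules.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "merge_intervals",
    "complement_intervals",
    "overlaps_any",
    "overlap_lengths",
    "total_length",
]


def merge_intervals(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping or book-ended intervals into a sorted disjoint set."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts.copy(), ends.copy()
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    # running maximum of ends; a new block starts where start > max(end so far)
    run_end = np.maximum.accumulate(ends)
    new_block = np.empty(starts.size, dtype=bool)
    new_block[0] = True
    new_block[1:] = starts[1:] > run_end[:-1]
    idx = np.flatnonzero(new_block)
    out_starts = starts[idx]
    out_ends = np.empty(idx.size, dtype=np.int64)
    out_ends[:-1] = run_end[idx[1:] - 1]
    out_ends[-1] = run_end[-1]
    return out_starts, out_ends


def complement_intervals(starts, ends, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Gaps of ``[0, size)`` not covered by the (merged) intervals."""
    starts, ends = merge_intervals(starts, ends)
    starts = np.clip(starts, 0, size)
    ends = np.clip(ends, 0, size)
    gap_starts = np.concatenate(([0], ends))
    gap_ends = np.concatenate((starts, [size]))
    keep = gap_starts < gap_ends
    return gap_starts[keep], gap_ends[keep]


def overlap_lengths(q_start: int, q_end: int, r_starts, r_ends) -> np.ndarray:
    """Overlap in bp of one query against each reference interval."""
    r_starts = np.asarray(r_starts, dtype=np.int64)
    r_ends = np.asarray(r_ends, dtype=np.int64)
    return np.maximum(
        np.minimum(q_end, r_ends) - np.maximum(q_start, r_starts), 0
    )


def overlaps_any(q_starts, q_ends, r_starts, r_ends, min_bp: int = 1) -> np.ndarray:
    """For each query, does any reference interval overlap it by >= min_bp?

    References must be sorted by start and disjoint (e.g. merged peaks).
    """
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    r_starts = np.asarray(r_starts, dtype=np.int64)
    r_ends = np.asarray(r_ends, dtype=np.int64)
    out = np.zeros(q_starts.size, dtype=bool)
    if r_starts.size == 0 or q_starts.size == 0:
        return out
    if min_bp == 1:
        # first reference ending after the query start; overlap iff it begins
        # before the query end
        idx = np.searchsorted(r_ends, q_starts, side="right")
        valid = idx < r_starts.size
        out[valid] = r_starts[idx[valid]] < q_ends[valid]
        return out
    lo = np.searchsorted(r_ends, q_starts, side="right")
    hi = np.searchsorted(r_starts, q_ends, side="left")
    for i in range(q_starts.size):
        if lo[i] >= hi[i]:
            continue
        ov = overlap_lengths(q_starts[i], q_ends[i], r_starts[lo[i]:hi[i]], r_ends[lo[i]:hi[i]])
        out[i] = bool((ov >= min_bp).any())
    return out


def total_length(starts, ends) -> int:
    starts, ends = merge_intervals(starts, ends)
    return int((ends - starts).sum())
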