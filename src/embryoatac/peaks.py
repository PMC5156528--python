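"""Window-based accessible-peak calling on pooled open fragments.

The caller scores sliding windows against a locally estimated
negative-binomial background, corrects the per-window p-values by
Benjamini–Hochberg, merges significant windows, and refines merged regions
on 10-bp binned fragment density so that closely spaced accessible elements
are resolved as separate peaks. It deliberately occupies the slot of a
heavier zero-inflated-regression peak caller in the original pipeline: it
consumes the same open-fragment input and produces the same record shape
(interval, confidence score in [0, 1], summit), and externally produced peak
BED files are accepted interchangeably downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import uniform_filter1d
from statsmodels.stats.multitest import multipletests

from .fragments import FragmentSet, FragmentStateError, concat
from .intervals import merge_intervals, overlaps_any

__all__ = ["CallerParams", "pool", "call_peaks", "overlaps", "read_peaks", "write_peaks"]


@dataclass
class CallerParams:
    """Window-caller settings (window/step/FDR mirroring the study's caller)."""

    win_size: int = 300
    step: int = 50
    merge_gap: int = 0
    fdr: float = 0.05
    min_score: float = 0.8
    local_bg_window: int = 75_000
    refine: bool = True
    refine_bin: int = 10
    min_peak_width: int = 50

    def __post_init__(self):
        if self.step > self.win_size:
            raise ValueError("step must be <= win_size")
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must be in (0, 1)")


def pool(sets: list[FragmentSet], by: dict | None = None, label: str | None = None) -> FragmentSet:
    """Concatenate fragment sets, optionally filtering on metadata keys.

    ``by`` maps metadata keys to required values (e.g. ``{"phase":
    "metaphase"}`` keeps only metaphase-flagged samples). Constituent sample
    metadata is recorded in the pooled set's provenance. Sets must share Tn5
    adjustment state.
    """
    selected = []
    for fs in sets:
        if by and any(fs.metadata.get(k) != v for k, v in by.items()):
            continue
        selected.append(fs)
    if not selected:
        raise ValueError(f"no fragment sets match pooling criteria {by!r}")
    states = {fs.tn5_adjusted for fs in selected}
    if len(states) > 1:
        raise FragmentStateError("cannot pool sets with mixed Tn5 adjustment state")
    meta = {
        "pooled_by": dict(by or {}),
        "label": label,
        "constituents": [dict(fs.metadata) for fs in selected],
    }
    return concat(selected, metadata=meta)


def _window_counts(starts, ends, win_starts, win_size):
    """Number of fragments overlapping each window (sorted input arrays)."""
    s_sorted = np.sort(starts)
    e_sorted = np.sort(ends)
    win_ends = win_starts + win_size
    # overlap iff start < win_end and end > win_start
    n_start_before_end = np.searchsorted(s_sorted, win_ends, side="left")
    n_end_before_start = np.searchsorted(e_sorted, win_starts, side="right")
    return n_start_before_end - n_end_before_start


def call_peaks(
    open_fs: FragmentSet, chrom_sizes: dict, params: CallerParams | None = None
) -> pd.DataFrame:
    """Call accessible peaks from pooled open fragments.

    Returns a table with columns ``chrom, start, end, score, summit``. Score
    is 1 − q of the best constituent window; peaks scoring below
    ``params.min_score`` are dropped. Summits sit at the maximum of 10-bp
    binned fragment density (leftmost tie wins).
    """
    params = params or CallerParams()
    if len(open_fs) == 0:
        warnings.warn("call_peaks: empty fragment set", stacklevel=2)
        return _empty_peaks()

    per_chrom = {}
    all_pvals = []
    for chrom, grp in open_fs.df.groupby("chrom", sort=True):
        chrom = str(chrom)
        size = int(chrom_sizes[chrom])
        if size < params.win_size:
            warnings.warn(f"call_peaks: {chrom} shorter than win_size, skipped", stacklevel=2)
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        win_starts = np.arange(0, size - params.win_size + 1, params.step, dtype=np.int64)
        counts = _window_counts(starts, ends, win_starts, params.win_size)

        # local negative-binomial background: method-of-moments over the
        # surrounding local_bg_window of window counts, floored at Poisson.
        # Windows far in the upper Poisson tail of the chromosome's median
        # rate are masked out of the moment estimates so enriched regions do
        # not inflate their own background.
        k = max(params.local_bg_window // params.step, 3)
        lam0 = max(float(np.median(counts)), 0.1)
        bg_mask = counts <= stats.poisson.isf(1e-4, lam0)
        c = counts.astype(float)
        w = bg_mask.astype(float)
        denom = np.maximum(uniform_filter1d(w, size=k, mode="nearest"), 1e-12)
        mu = uniform_filter1d(c * w, size=k, mode="nearest") / denom
        ex2 = uniform_filter1d(c**2 * w, size=k, mode="nearest") / denom
        var = np.maximum(ex2 - mu**2, mu)
        mu = np.maximum(mu, 1e-8)
        pvals = np.empty(counts.size)
        pois = var <= mu * (1 + 1e-9)
        pvals[pois] = stats.poisson.sf(counts[pois] - 1, mu[pois])
        nb = ~pois
        if nb.any():
            p_nb = mu[nb] / var[nb]
            r = mu[nb] ** 2 / (var[nb] - mu[nb])
            pvals[nb] = stats.nbinom.sf(counts[nb] - 1, r, p_nb)
        per_chrom[chrom] = (win_starts, counts, pvals, starts, ends)
        all_pvals.append(pvals)

    if not per_chrom:
        return _empty_peaks()
    flat = np.concatenate(all_pvals)
    _, qvals, _, _ = multipletests(flat, alpha=params.fdr, method="fdr_bh")

    rows = []
    offset = 0
    for chrom, (win_starts, counts, pvals, fstarts, fends) in per_chrom.items():
        q = qvals[offset : offset + pvals.size]
        offset += pvals.size
        sig = q <= params.fdr
        if not sig.any():
            continue
        s = win_starts[sig]
        e = s + params.win_size
        merged_s, merged_e = _merge_with_gap(s, e, params.merge_gap)
        fmids = (fstarts + fends) // 2
        for ms, me in zip(merged_s, merged_e):
            win_in = (win_starts + params.win_size > ms) & (win_starts < me)
            region_q = float(q[win_in].min()) if win_in.any() else float(q[sig].min())
            for ps, pe, summit in _refine_region(int(ms), int(me), fmids, params):
                score = 1.0 - region_q
                if score < params.min_score or pe - ps < params.min_peak_width:
                    continue
                rows.append((chrom, ps, pe, score, summit))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "summit"])
    if not peaks.empty:
        peaks = peaks.sort_values(["chrom", "start"]).reset_index(drop=True)
    return peaks


def _empty_peaks() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "score": pd.Series(dtype=float),
            "summit": pd.Series(dtype=np.int64),
        }
    )


def _merge_with_gap(starts, ends, gap):
    if gap > 0:
        s, e = merge_intervals(starts, ends + gap)
        return s, e - gap
    return merge_intervals(starts, ends)


def _refine_region(ms, me, fmids, params: CallerParams):
    """Split a merged window region at insertion-density valleys.

    Fragment-midpoint counts per 10-bp bin locate the accessible elements at
    sub-window resolution: maximal runs of occupied bins separated by an
    empty stretch longer than ``max(30 bp, merge_gap)`` become separate
    peaks, trimmed to their occupied span. The summit is the densest bin
    (leftmost tie). A region with no midpoints is kept whole.
    """
    bw = params.refine_bin
    n_bins = max(-(-(me - ms) // bw), 1)
    m = fmids[(fmids >= ms) & (fmids < me)]
    counts = np.bincount((m - ms) // bw, minlength=n_bins).astype(float)
    if not params.refine or not counts.any():
        summit = ms + int(np.argmax(counts)) * bw + bw // 2 if counts.any() else (ms + me) // 2
        return [(ms, me, summit)]
    gap_bins = max(3, params.merge_gap // bw)
    runs = _signal_runs(counts > 0, max_gap_bins=gap_bins)
    # summit localization uses lightly smoothed density; splitting uses raw
    smooth = uniform_filter1d(counts, size=5, mode="nearest")
    out = []
    for r0, r1 in runs:  # r1 inclusive
        ps = ms + r0 * bw
        pe = min(ms + (r1 + 1) * bw, me)
        local = smooth[r0 : r1 + 1]
        summit = ps + int(np.argmax(local)) * bw + bw // 2
        out.append((ps, pe, summit))
    return out


def _signal_runs(signal: np.ndarray, max_gap_bins: int = 0):
    idx = np.flatnonzero(signal)
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 > max_gap_bins:
            runs.append((start, prev))
            start = i
        prev = i
    runs.append((start, prev))
    return runs


def overlaps(a: pd.DataFrame, b: pd.DataFrame, min_bp: int = 1) -> np.ndarray:
    """For each peak in ``a``, is it overlapped by >= min_bp of some peak in ``b``?"""
    a = a.reset_index(drop=True)
    out = np.zeros(len(a), dtype=bool)
    for chrom, grp in a.groupby("chrom", sort=False):
        bb = b[b["chrom"] == chrom].sort_values("start")
        if bb.empty:
            continue
        rs, re = merge_intervals(bb["start"].to_numpy(), bb["end"].to_numpy())
        hit = overlaps_any(grp["start"].to_numpy(), grp["end"].to_numpy(), rs, re, min_bp=min_bp)
        out[grp.index.to_numpy()] = hit
    return out


def read_peaks(path) -> pd.DataFrame:
    """Read a BED3+ peak file (optional 4th score and 5th summit columns)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    if df.shape[1] > 4:
        df = df.rename(columns={3: "name", 4: "score"})
    peaks = df[["chrom", "start", "end"]].copy()
    peaks["score"] = df["score"] if "score" in df else 1.0
    peaks["summit"] = (peaks["start"] + peaks["end"]) // 2
    return peaks


def write_peaks(peaks: pd.DataFrame, path, name_prefix: str = "peak") -> None:
    """Write peaks as BED6+ with score and summit-offset columns."""
    out = peaks.copy()
    out["name"] = [f"{name_prefix}_{i:05d}" for i in range(len(out))]
    out["strand"] = "."
    out["summit_offset"] = out["summit"] - out["start"]
    out[["chrom", "start", "end", "name", "score", "strand", "summit_offset"]].to_csv(
        path, sep="\t", header=False, index=False
    )
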