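"""Binned open-fragment coverage and its two-stage normalization.

Coverage is computed as the number of open fragments overlapping each
fixed-width bin (10 bp by default), normalized to counts-per-million of the
*full* (unsplit) library, and finally standardized against the log-scale mean
and standard deviation of coverage over a large set of randomly placed
background regions. The background standardization sets a common noise floor
across timepoints, so accessibility values are comparable through the
timecourse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .fragments import FragmentSet
from .intervals import complement_intervals, merge_intervals

__all__ = [
    "CoverageTrack",
    "BackgroundRegions",
    "bin_coverage",
    "cpm_normalize",
    "sample_background",
    "standardize",
    "replicate_correlation",
    "write_bedgraph",
]


class DegenerateBackgroundError(RuntimeError):
    """Background regions have zero variance; standardization undefined."""


@dataclass
class CoverageTrack:
    """Per-chromosome binned coverage with its normalization state."""

    values: dict  # chrom -> float array of per-bin values
    bin_width: int = 10
    normalization: str = "raw"  # raw | cpm | standardized
    library_total: int = 0
    chrom_sizes: dict = field(default_factory=dict)
    transform: dict = field(default_factory=dict)  # mu/sigma/epsilon once standardized

    def max_in(self, chrom: str, start: int, end: int) -> float:
        """Maximum bin value within [start, end)."""
        v = self.values[chrom]
        b0 = start // self.bin_width
        b1 = max(-(-end // self.bin_width), b0 + 1)
        return float(v[b0 : min(b1, v.size)].max())

    def mean_in(self, chrom: str, start: int, end: int) -> float:
        v = self.values[chrom]
        b0 = start // self.bin_width
        b1 = max(-(-end // self.bin_width), b0 + 1)
        return float(v[b0 : min(b1, v.size)].mean())


@dataclass
class BackgroundRegions:
    """Randomly placed peak-free regions used to estimate the noise floor."""

    intervals: pd.DataFrame  # chrom, start, end
    n_requested: int
    n_retained: int


def bin_coverage(open_fs: FragmentSet, chrom_sizes: dict, bin_width: int = 10) -> CoverageTrack:
    """Count open fragments overlapping each fixed-width bin.

    A fragment increments every bin it overlaps. Fragments running past a
    chromosome end are clipped with a warning.
    """
    values = {}
    n_bins = {c: -(-int(s) // bin_width) for c, s in chrom_sizes.items()}
    for c, nb in n_bins.items():
        values[c] = np.zeros(nb, dtype=float)
    n_clipped = 0
    for chrom, grp in open_fs.df.groupby("chrom", sort=False):
        chrom = str(chrom)
        if chrom not in values:
            continue
        size = chrom_sizes[chrom]
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        over = ends > size
        n_clipped += int(over.sum())
        ends = np.minimum(ends, size)
        # difference-array over bins: +1 at first overlapped bin, -1 after last
        b0 = starts // bin_width
        b1 = (ends - 1) // bin_width + 1
        diff = np.zeros(n_bins[chrom] + 1, dtype=float)
        np.add.at(diff, b0, 1.0)
        np.add.at(diff, b1, -1.0)
        values[chrom] += np.cumsum(diff[:-1])
    if n_clipped:
        warnings.warn(f"bin_coverage: clipped {n_clipped} fragments at chromosome ends", stacklevel=2)
    return CoverageTrack(
        values=values,
        bin_width=bin_width,
        normalization="raw",
        library_total=len(open_fs),
        chrom_sizes=dict(chrom_sizes),
    )


def cpm_normalize(track: CoverageTrack, full_library_total: int) -> CoverageTrack:
    """Scale to counts-per-million of the full (unsplit) library."""
    if track.normalization != "raw":
        raise ValueError(f"expected a raw track, got {track.normalization}")
    if full_library_total <= 0:
        raise ValueError("full_library_total must be positive")
    factor = 1e6 / full_library_total
    return CoverageTrack(
        values={c: v * factor for c, v in track.values.items()},
        bin_width=track.bin_width,
        normalization="cpm",
        library_total=full_library_total,
        chrom_sizes=dict(track.chrom_sizes),
    )


def sample_background(
    peaks: pd.DataFrame,
    chrom_sizes: dict,
    track: CoverageTrack | None = None,
    n: int = 25_000,
    widen_to: int = 20_000,
    seed: int = 0,
) -> BackgroundRegions:
    """Place ``n`` random peak-free regions mirroring the peak-width profile.

    Peaks are widened symmetrically about their midpoints to ``widen_to`` bp,
    merged, and subtracted from the genome; region positions are uniform over
    the remaining gaps with widths resampled (with replacement) from the peak
    widths. Regions are truncated to stay inside their gap. When a coverage
    track is supplied, regions with zero coverage are discarded (not
    replaced), so ``n_retained <= n``.
    """
    rng = np.random.default_rng(seed)
    gaps = []  # (chrom, gap_start, gap_end)
    for chrom, size in chrom_sizes.items():
        if peaks is None or peaks.empty:
            gaps.append((chrom, 0, int(size)))
            continue
        p = peaks[peaks["chrom"] == chrom]
        if p.empty:
            gaps.append((chrom, 0, int(size)))
            continue
        mid = (p["start"].to_numpy() + p["end"].to_numpy()) // 2
        ws = mid - widen_to // 2
        we = ws + widen_to
        ms, me = merge_intervals(np.clip(ws, 0, size), np.clip(we, 0, size))
        gs, ge = complement_intervals(ms, me, int(size))
        gaps.extend((chrom, int(a), int(b)) for a, b in zip(gs, ge))
    if not gaps:
        raise RuntimeError("peak-free complement is empty; cannot sample background")
    gap_len = np.array([b - a for _, a, b in gaps], dtype=float)
    if peaks is not None and not peaks.empty:
        width_pool = (peaks["end"] - peaks["start"]).to_numpy()
    else:
        width_pool = np.array([500])
    gi = rng.choice(len(gaps), size=n, p=gap_len / gap_len.sum())
    widths = rng.choice(width_pool, size=n, replace=True)
    rows = []
    for g, wdt in zip(gi, widths):
        chrom, a, b = gaps[g]
        start = a + int(rng.random() * (b - a))
        end = min(start + int(wdt), b)  # truncate at the gap edge
        rows.append((chrom, start, end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df = df[df["end"] > df["start"]].reset_index(drop=True)
    if track is not None:
        means = np.array([track.mean_in(c, s, e) for c, s, e in df.itertuples(index=False)])
        keep = means > 0
        df = df[keep].reset_index(drop=True)
    return BackgroundRegions(intervals=df, n_requested=n, n_retained=len(df))


def background_stats(track: CoverageTrack, bg: BackgroundRegions, log_space: bool = True):
    """Per-region mean coverage and its (log-space) mean/sd plus the pseudocount."""
    means = np.array(
        [track.mean_in(c, s, e) for c, s, e in bg.intervals.itertuples(index=False)]
    )
    all_vals = np.concatenate([v for v in track.values.values()])
    positive = all_vals[all_vals > 0]
    eps = float(positive.min()) / 2.0 if positive.size else 1.0
    if log_space:
        vals = np.log(means + eps)
    else:
        vals = means
        eps = 0.0
    mu = float(vals.mean())
    sigma = float(vals.std(ddof=0))
    return means, mu, sigma, eps


def standardize(
    track: CoverageTrack, bg: BackgroundRegions, log_space: bool = True
) -> CoverageTrack:
    """Z-transform the genome-wide track against the background distribution.

    With the default log-space mode, each bin becomes
    ``(log(x + eps) - mu_bg) / sigma_bg`` where ``mu_bg``/``sigma_bg`` are the
    mean and sd of log per-region mean coverage over the background regions
    and ``eps`` is half the smallest positive bin value.
    """
    if track.normalization != "cpm":
        raise ValueError("standardize expects a CPM-normalized track")
    _, mu, sigma, eps = background_stats(track, bg, log_space=log_space)
    if sigma == 0:
        raise DegenerateBackgroundError("background coverage has zero variance")
    values = {}
    for c, v in track.values.items():
        x = np.log(v + eps) if log_space else v
        values[c] = (x - mu) / sigma
    return CoverageTrack(
        values=values,
        bin_width=track.bin_width,
        normalization="standardized",
        library_total=track.library_total,
        chrom_sizes=dict(track.chrom_sizes),
        transform={"mu": mu, "sigma": sigma, "epsilon": eps, "log_space": log_space},
    )


def destandardize(track: CoverageTrack) -> dict:
    """Invert :func:`standardize` using the stored transform (round-trip check)."""
    t = track.transform
    out = {}
    for c, z in track.values.items():
        x = z * t["sigma"] + t["mu"]
        out[c] = np.exp(x) - t["epsilon"] if t["log_space"] else x
    return out


def replicate_correlation(count_matrix: pd.DataFrame):
    """Replicate distance (1 − Pearson r of CPM counts in peaks) + linkage.

    ``count_matrix``: peaks × replicates raw open-fragment counts. Columns are
    CPM-normalized by their totals before correlation. Constant columns have
    undefined correlation and are excluded (flagged). Returns
    ``(distance DataFrame, linkage matrix, excluded column list)``.
    """
    if count_matrix.shape[1] < 2:
        raise ValueError("need at least two replicates")
    cpm = count_matrix / count_matrix.sum(axis=0) * 1e6
    sd = cpm.std(axis=0)
    excluded = list(cpm.columns[sd == 0])
    kept = cpm.loc[:, sd > 0]
    corr = kept.corr(method="pearson")
    dist = 1.0 - corr
    z = linkage(squareform(dist.values, checks=False), method="complete")
    return dist, z, excluded


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, v in track.values.items():
            size = track.chrom_sizes.get(chrom, v.size * track.bin_width)
            for i, val in enumerate(v):
                if val == 0:
                    continue
                start = i * track.bin_width
                end = min(start + track.bin_width, int(size))
                fh.write(f"{chrom}\t{start}\t{end}\t{val:.6g}\n")


def write_bigwig(track: CoverageTrack, path) -> None:
    """Optional bigWig writer (requires pyBigWig)."""
    import pyBigWig  # local import: optional dependency

    bw = pyBigWig.open(str(path), "w")
    header = [(c, int(track.chrom_sizes[c])) for c in track.values]
    bw.addHeader(header)
    for chrom, v in track.values.items():
        size = int(track.chrom_sizes[chrom])
        starts = np.arange(v.size) * track.bin_width
        ends = np.minimum(starts + track.bin_width, size)
        bw.addEntries(
            [chrom] * v.size, starts.tolist(), ends=ends.tolist(), values=v.astype(float).tolist()
        )
    bw.close()
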