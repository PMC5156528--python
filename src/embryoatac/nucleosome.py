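"""Nucleosome dyad calling, promoter NFR geometry, and recovery dynamics.

Dyads are called per analysis region as local maxima of Gaussian-smoothed
nucleosomal-fragment midpoint density — a deliberately simple stand-in for a
full fragmentation-model nucleosome caller, producing the same record shape
(dyad center + occupancy score), so externally supplied dyad tables plug in
interchangeably. Calls are modeled into canonical 147-bp nucleosomes, and the
promoter nucleosome-free region (NFR) is measured between the −1 and +1
dyads flanking a vantage point 25 bp upstream of the TSS (upstream in
transcription orientation; the vantage avoids mistaking a TSS-occluding +1
nucleosome for the −1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .fragments import FragmentSet
from .ncratio import bootstrap_median_diff_ci, permutation_test

__all__ = [
    "DyadParams",
    "prepare_regions",
    "call_dyads",
    "model_nucleosomes",
    "compute_nfr",
    "compute_nfrs",
    "occupancy_matrix",
    "nfr_dynamics",
    "recovery_latency",
]

NUCLEOSOME_BP = 147


@dataclass
class DyadParams:
    """Dyad-caller settings.

    ``nuc_len_range`` restricts input to fragments with a well-defined
    mononucleosome midpoint; ``smooth_sd`` is the Gaussian kernel width on
    midpoint density; maxima closer than ``min_separation`` merge into the
    stronger call; ``rel_height`` discards maxima below that fraction of the
    region's density maximum (suppresses background ripple between real
    nucleosomes).
    """

    smooth_sd: float = 20.0
    min_separation: int = 120
    nuc_len_range: tuple = (117, 250)
    rel_height: float = 0.2


def prepare_regions(peaks: pd.DataFrame, chrom_sizes: dict, width: int = 2500) -> pd.DataFrame:
    """2500-bp analysis windows centered on peak summits.

    Overlapping windows are kept, not merged. Windows running off a
    chromosome end are clipped and flagged.
    """
    out = []
    half = width // 2
    for i, row in peaks.reset_index(drop=True).iterrows():
        size = int(chrom_sizes[row["chrom"]])
        start = int(row["summit"]) - half
        end = start + width
        clipped = start < 0 or end > size
        out.append(
            {
                "region_id": f"region_{i:05d}",
                "chrom": row["chrom"],
                "start": max(start, 0),
                "end": min(end, size),
                "clipped": clipped,
            }
        )
    return pd.DataFrame(out, columns=["region_id", "chrom", "start", "end", "clipped"])


def call_dyads(
    nucleosomal_fs: FragmentSet, regions: pd.DataFrame, params: DyadParams | None = None
) -> pd.DataFrame:
    """Call nucleosome dyads within each region from fragment midpoints.

    Returns rows (region_id, chrom, dyad, occupancy) where occupancy is the
    smoothed midpoint density (fragments per bp) at the dyad.
    """
    params = params or DyadParams()
    lo, hi = params.nuc_len_range
    df = nucleosomal_fs.df
    lengths = (df["end"] - df["start"]).to_numpy()
    keep = (lengths >= lo) & (lengths <= hi)
    mids = ((df["start"].to_numpy() + df["end"].to_numpy()) // 2)[keep]
    chroms = df["chrom"].to_numpy()[keep]

    rows = []
    for _, reg in regions.iterrows():
        sel = (chroms == reg["chrom"]) & (mids >= reg["start"]) & (mids < reg["end"])
        m = mids[sel] - reg["start"]
        n_pos = int(reg["end"] - reg["start"])
        if m.size == 0 or n_pos < 3:
            continue
        density = np.bincount(m, minlength=n_pos).astype(float)
        smooth = gaussian_filter1d(density, sigma=params.smooth_sd, mode="constant")
        height = params.rel_height * smooth.max() if smooth.max() > 0 else None
        peaks_idx, _ = find_peaks(smooth, distance=params.min_separation, height=height)
        for p in peaks_idx:
            rows.append(
                {
                    "region_id": reg["region_id"],
                    "chrom": reg["chrom"],
                    "dyad": int(reg["start"] + p),
                    "occupancy": float(smooth[p]),
                }
            )
    return pd.DataFrame(rows, columns=["region_id", "chrom", "dyad", "occupancy"])


def model_nucleosomes(calls: pd.DataFrame) -> pd.DataFrame:
    """Widen dyads into canonical 147-bp nucleosome intervals.

    Each interval is [dyad − 73, dyad + 74): 147 bp with left-biased
    rounding of the center.
    """
    out = calls.copy()
    out["start"] = out["dyad"] - 73
    out["end"] = out["dyad"] + 74
    return out[["chrom", "start", "end", "dyad", "occupancy"] +
               (["region_id"] if "region_id" in calls.columns else [])]


def compute_nfr(tss_pos: int, strand: str, dyads: np.ndarray, vantage_offset: int = 25):
    """Locate the −1/+1 dyads around the TSS−25 vantage; derive the NFR size.

    ``dyads`` are candidate dyad positions (same chromosome, already
    restricted to the promoter's analysis region). The vantage sits
    ``vantage_offset`` bp upstream of the TSS in transcription orientation.
    Returns a dict with minus1_dyad, plus1_dyad and
    ``nfr_size = |plus1 − minus1| − 147`` (negative if the dyads sit closer
    than one wrapped nucleosome), or ``{"omitted": True, "reason": ...}``
    when either flanking dyad is missing.
    """
    dyads = np.asarray(dyads, dtype=np.int64)
    if strand == "+":
        vantage = tss_pos - vantage_offset
        up = dyads[dyads < vantage]
        down = dyads[dyads > vantage]
        minus1 = int(up.max()) if up.size else None
        plus1 = int(down.min()) if down.size else None
    else:
        vantage = tss_pos + vantage_offset
        up = dyads[dyads > vantage]
        down = dyads[dyads < vantage]
        minus1 = int(up.min()) if up.size else None
        plus1 = int(down.max()) if down.size else None
    if minus1 is None or plus1 is None:
        missing = []
        if minus1 is None:
            missing.append("-1")
        if plus1 is None:
            missing.append("+1")
        return {"omitted": True, "reason": "missing " + " and ".join(missing)}
    return {
        "omitted": False,
        "vantage": int(vantage),
        "minus1_dyad": minus1,
        "plus1_dyad": plus1,
        "nfr_size": int(abs(plus1 - minus1) - NUCLEOSOME_BP),
    }


def compute_nfrs(
    tss: pd.DataFrame, calls: pd.DataFrame, window: int = 1250, vantage_offset: int = 25
) -> pd.DataFrame:
    """Per-promoter NFR records (omissions included with reasons).

    ``tss`` columns: tss_id, chrom, pos, strand. Candidate dyads are calls
    on the same chromosome within ±``window`` bp of the TSS.
    """
    rows = []
    by_chrom = {c: g["dyad"].to_numpy() for c, g in calls.groupby("chrom")}
    for _, t in tss.iterrows():
        d = by_chrom.get(t["chrom"], np.array([], dtype=np.int64))
        d = d[(d >= t["pos"] - window) & (d <= t["pos"] + window)]
        rec = compute_nfr(int(t["pos"]), t["strand"], d, vantage_offset)
        rec.update({"tss_id": t["tss_id"], "chrom": t["chrom"], "tss": int(t["pos"]), "strand": t["strand"]})
        rows.append(rec)
    cols = ["tss_id", "chrom", "tss", "strand", "omitted", "reason",
            "vantage", "minus1_dyad", "plus1_dyad", "nfr_size"]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = pd.NA
    return df[cols]


def occupancy_matrix(
    tss: pd.DataFrame, calls_by_timepoint: dict, window: int = 800
):
    """Occupancy-weighted nucleosome coverage heatmaps around TSSs.

    For each timepoint, each promoter row holds per-bp coverage of modeled
    147-bp nucleosomes weighted by occupancy over TSS ± window/2, oriented so
    transcription runs left→right. Rows are ordered by the time-averaged −1
    dyad position. Returns ``(matrices, row_order, profiles)`` where
    ``profiles`` has per-timepoint column averages, their log10, and the
    flank-normalized version (mean of the two flanking 200-bp margins = 1).
    """
    half = window // 2
    tss = tss.reset_index(drop=True)
    tps = sorted(calls_by_timepoint)
    mats = {}
    minus1_positions = np.full((len(tss), len(tps)), np.nan)
    for j, tp in enumerate(tps):
        calls = calls_by_timepoint[tp]
        by_chrom = {c: g for c, g in calls.groupby("chrom")}
        mat = np.zeros((len(tss), window))
        for i, t in tss.iterrows():
            g = by_chrom.get(t["chrom"])
            if g is None:
                continue
            rel = g["dyad"].to_numpy() - int(t["pos"])
            if t["strand"] == "-":
                rel = -rel
            occ = g["occupancy"].to_numpy()
            near = np.abs(rel) <= half + NUCLEOSOME_BP
            for r, o in zip(rel[near], occ[near]):
                a = max(int(r) - 73 + half, 0)
                b = min(int(r) + 74 + half, window)
                if a < b:
                    mat[i, a:b] += o
            rec = compute_nfr(int(t["pos"]), t["strand"], g["dyad"].to_numpy())
            if not rec["omitted"]:
                rel_m1 = rec["minus1_dyad"] - int(t["pos"])
                minus1_positions[i, j] = -rel_m1 if t["strand"] == "-" else rel_m1
        mats[tp] = mat
    with np.errstate(invalid="ignore"):
        avg_m1 = np.nanmean(minus1_positions, axis=1)
    has_any = ~np.isnan(avg_m1)
    row_order = np.argsort(avg_m1[has_any], kind="stable")
    kept = np.flatnonzero(has_any)[row_order]
    profiles = []
    for tp in tps:
        mats[tp] = mats[tp][kept]
        col = mats[tp].mean(axis=0)
        flank = np.concatenate([col[:200], col[-200:]]).mean()
        norm = col / flank if flank > 0 else np.full_like(col, np.nan)
        profiles.append(
            pd.DataFrame(
                {
                    "timepoint": [tp] * window,
                    "offset": np.arange(-half, half),
                    "mean_occupancy": col,
                    "log10_mean_occupancy": np.log10(col + 1e-12),
                    "flank_normalized": norm,
                }
            )
        )
    return mats, tss.loc[kept, "tss_id"].tolist(), pd.concat(profiles, ignore_index=True)


def nfr_dynamics(
    nfr_table: pd.DataFrame,
    n_perm: int = 10_000,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean-normalized NFR-size traces per group with group-difference tests.

    ``nfr_table`` columns: tss_id, timepoint, group, nfr_size. Sizes are
    mean-normalized within group (group mean over all loci and timepoints
    maps to 0), then summarized as the per-timepoint median. When exactly
    two groups are present, each timepoint gets a one-tailed permutation p
    (first group smaller) and a bootstrap 95% CI of the median difference;
    statistics are suppressed for groups smaller than 3.
    """
    df = nfr_table.copy()
    df["norm_size"] = df["nfr_size"] - df.groupby("group")["nfr_size"].transform("mean")
    groups = sorted(df["group"].unique())
    rows = []
    for tp, tgrp in df.groupby("timepoint"):
        for g in groups:
            vals = tgrp.loc[tgrp["group"] == g, "norm_size"].to_numpy()
            rec = {
                "timepoint": tp,
                "group": g,
                "n": vals.size,
                "median_norm_size": float(np.median(vals)) if vals.size else np.nan,
                "p_value": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
            }
            rows.append(rec)
        if len(groups) == 2:
            a = tgrp.loc[tgrp["group"] == groups[0], "norm_size"].to_numpy()
            b = tgrp.loc[tgrp["group"] == groups[1], "norm_size"].to_numpy()
            if a.size >= 3 and b.size >= 3:
                p = permutation_test(b, a, "median_diff", n_perm=n_perm, seed=seed)
                lo, hi = bootstrap_median_diff_ci(a, b, n_boot=n_boot, seed=seed)
                rows[-2]["p_value"] = p
                rows[-2]["ci_low"], rows[-2]["ci_high"] = lo, hi
    return pd.DataFrame(rows)


def recovery_latency(
    times: np.ndarray,
    series: np.ndarray,
    reference: np.ndarray,
    ids=None,
    grid_step: float = 0.1,
) -> pd.DataFrame:
    """Time to recover the preceding-metaphase accessibility after mitosis.

    ``times`` (minutes into the cycle), ``series`` (loci × timepoints max
    standardized open coverage), ``reference`` (per-locus preceding-metaphase
    accessibility). A natural cubic spline through each locus' series is
    evaluated on a ``grid_step``-minute grid; latency is the earliest grid
    time at which interpolated accessibility >= reference. Loci that never
    recover are censored at the cycle end. The raw (non-interpolated)
    latency — earliest sampled timepoint meeting the reference — is also
    reported. With fewer than 3 timepoints the spline is unavailable and
    only raw latency is returned. Also reports per-locus log2 fold change
    between last and first timepoint.
    """
    times = np.asarray(times, dtype=float)
    series = np.atleast_2d(np.asarray(series, dtype=float))
    reference = np.asarray(reference, dtype=float)
    n = series.shape[0]
    ids = list(ids) if ids is not None else [f"locus_{i}" for i in range(n)]
    grid = np.arange(times[0], times[-1] + grid_step / 2, grid_step)
    rows = []
    for i in range(n):
        vals = series[i]
        raw_hit = np.flatnonzero(vals >= reference[i])
        raw_latency = float(times[raw_hit[0]]) if raw_hit.size else np.nan
        if times.size >= 3:
            spline = CubicSpline(times, vals, bc_type="natural")
            interp = spline(grid)
            hit = np.flatnonzero(interp >= reference[i])
            latency = float(grid[hit[0]]) if hit.size else np.nan
        else:
            latency = raw_latency
        with np.errstate(divide="ignore", invalid="ignore"):
            log2fc = float(np.log2(vals[-1] / vals[0])) if vals[0] > 0 and vals[-1] > 0 else np.nan
        rows.append(
            {
                "id": ids[i],
                "latency": latency,
                "raw_latency": raw_latency,
                "censored": bool(np.isnan(latency)),
                "log2_fc": log2fc,
            }
        )
    out = pd.DataFrame(rows)
    raw = out["raw_latency"].dropna()
    out.attrs["median_raw_latency"] = float(raw.median()) if len(raw) else float("nan")
    return out
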