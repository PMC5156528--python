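"""Diploid vs haploid comparison: nucleo-cytoplasmic-ratio vs time dependence.

Haploid embryos carry half the DNA of diploids, so they reach any given N:C
ratio one cycle later: diploid NC11/NC12/NC13 match haploid NC12/NC13/NC14
at relative ratios 0.25/0.5/1.0. Comparing peak presence at matched
developmental time versus matched N:C ratio classifies each dynamic peak as
time-dependent (opens on schedule regardless of ploidy) or
N:C-ratio-dependent (opens only at the matching ratio, i.e. one cycle late
in haploids).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .peaks import overlaps

__all__ = [
    "NC_RATIO_MAP",
    "match_samples",
    "classify_dependence",
    "median_trace",
    "permutation_test",
    "bootstrap_median_diff_ci",
]

#: relative N:C ratio per (genotype, cycle)
NC_RATIO_MAP = {
    ("diploid", 11): 0.25,
    ("diploid", 12): 0.5,
    ("diploid", 13): 1.0,
    ("haploid", 12): 0.25,
    ("haploid", 13): 0.5,
    ("haploid", 14): 1.0,
}


def match_samples(diploid_cycles, haploid_cycles, mode: str = "nc_ratio"):
    """Pair diploid to haploid cycles at equal time or equal N:C ratio.

    ``mode="time"`` pairs equal cycle indices; ``mode="nc_ratio"`` pairs
    cycles with equal relative ratios (11<->12, 12<->13, 13<->14). Cycles
    without a partner are omitted with a warning.
    """
    if mode not in ("time", "nc_ratio"):
        raise ValueError(f"unknown mode {mode!r}")
    pairs = []
    hset = set(haploid_cycles)
    for dc in diploid_cycles:
        if mode == "time":
            hc = dc
            if hc not in hset:
                warnings.warn(f"match_samples: no haploid cycle {hc}; diploid NC{dc} omitted")
                continue
        else:
            ratio = NC_RATIO_MAP.get(("diploid", dc))
            hc = next(
                (c for c in haploid_cycles if NC_RATIO_MAP.get(("haploid", c)) == ratio), None
            )
            if ratio is None or hc is None:
                warnings.warn(f"match_samples: no ratio match for diploid NC{dc}; omitted")
                continue
        pairs.append((dc, hc))
    return pairs


def classify_dependence(
    diploid_timing: pd.DataFrame,
    haploid_per_cycle: dict,
    haploid_union: pd.DataFrame,
    min_overlap_bp: int = 1,
) -> pd.DataFrame:
    """Call each diploid dynamic peak N:C-ratio- or time-dependent.

    Only peaks that gained accessibility at NC12 or NC13 (timing new_NC12 /
    new_NC13) are scored, and only if present in the haploid union call.
    A peak present in haploids at the matched developmental time is
    time-dependent (presence at the earlier time shows N:C independence,
    so a time match takes precedence over a ratio match); one absent at
    matched time but present at the matched N:C ratio (one cycle later) is
    N:C-ratio-dependent. Remaining peaks stay unscored with the reason
    recorded.
    """
    out = diploid_timing.reset_index(drop=True).copy()
    n = len(out)
    call = np.full(n, "unscored", dtype=object)
    reason = np.full(n, "", dtype=object)
    in_union = overlaps(out, haploid_union, min_bp=min_overlap_bp)
    dynamic = out["timing"].isin(["new_NC12", "new_NC13"]).to_numpy()
    reason[~dynamic] = "not_dynamic"
    reason[dynamic & ~in_union] = "missing_in_haploid"

    present_time = np.zeros(n, dtype=bool)
    present_ratio = np.zeros(n, dtype=bool)
    for timing, gain_cycle in (("new_NC12", 12), ("new_NC13", 13)):
        sel = (out["timing"] == timing).to_numpy()
        if not sel.any():
            continue
        sub = out[sel]
        if gain_cycle in haploid_per_cycle:
            present_time[sel] = overlaps(sub, haploid_per_cycle[gain_cycle], min_bp=min_overlap_bp)
        if gain_cycle + 1 in haploid_per_cycle:
            present_ratio[sel] = overlaps(sub, haploid_per_cycle[gain_cycle + 1], min_bp=min_overlap_bp)

    scorable = dynamic & in_union
    call[scorable & present_time] = "time_dependent"
    call[scorable & ~present_time & present_ratio] = "nc_dependent"
    neither = scorable & ~present_time & ~present_ratio
    reason[neither] = "absent_at_both_matches"

    out["nc_class"] = call
    out["unscored_reason"] = reason
    out["present_matched_time"] = present_time
    out["present_matched_ratio"] = present_ratio
    out["present_in_haploid_union"] = in_union
    return out


def median_trace(
    tracks_by_timepoint: dict,
    regions: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    statistic: str = "max",
) -> pd.DataFrame:
    """Median per-region accessibility per group at each timepoint.

    ``tracks_by_timepoint`` maps a timepoint key (anything sortable; e.g.
    ``(cycle, minutes)``) to a standardized coverage track. The per-region
    accessibility statistic is the max (default; config ``statistic="mean"``)
    of standardized coverage within the region. Returns long-format rows
    (timepoint, group, median, n).
    """
    regions = regions.reset_index(drop=True)
    groups = np.asarray(groups, dtype=object)
    rows = []
    for tp in sorted(tracks_by_timepoint):
        track = tracks_by_timepoint[tp]
        fn = track.max_in if statistic == "max" else track.mean_in
        vals = np.array(
            [fn(c, s, e) for c, s, e in regions[["chrom", "start", "end"]].itertuples(index=False)]
        )
        for g in pd.unique(groups):
            sel = groups == g
            if sel.sum() == 0:
                warnings.warn(f"median_trace: empty group {g!r}")
                continue
            rows.append((tp, g, float(np.median(vals[sel])), int(sel.sum())))
    return pd.DataFrame(rows, columns=["timepoint", "group", "median", "n"])


def per_region_accessibility(track, regions: pd.DataFrame, statistic: str = "max") -> np.ndarray:
    """Max (or mean) standardized coverage within each region."""
    fn = track.max_in if statistic == "max" else track.mean_in
    return np.array(
        [fn(c, s, e) for c, s, e in regions[["chrom", "start", "end"]].itertuples(index=False)]
    )


def permutation_test(
    values_a,
    values_b,
    statistic: str = "median_diff",
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "greater",
) -> float:
    """One-tailed label-permutation p for a group difference in location.

    The observed statistic is stat(a) − stat(b) (median or mean). Group
    sizes are preserved in every permutation and the p-value uses the
    add-one estimator ``(1 + #{perm >= obs}) / (n_perm + 1)``, so p is
    always in (0, 1].
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 100:
        warnings.warn("permutation_test: n_perm < 100 gives a coarse p-value")
    stat = np.median if statistic == "median_diff" else np.mean
    observed = stat(a) - stat(b)
    if alternative == "less":
        observed = -observed
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    count = 0
    # vectorized in chunks: each row of the key matrix encodes one permutation
    chunk = max(1, int(5e6) // max(pooled.size, 1))
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        order = rng.random((k, pooled.size)).argsort(axis=1)
        perms = pooled[order]
        diffs = stat(perms[:, : a.size], axis=1) - stat(perms[:, a.size :], axis=1)
        if alternative == "less":
            diffs = -diffs
        count += int((diffs >= observed).sum())
        done += k
    return (1 + count) / (n_perm + 1)


def bootstrap_median_diff_ci(
    values_a, values_b, n_boot: int = 10_000, seed: int = 0, level: float = 0.95
):
    """Percentile bootstrap CI for the difference of medians (a − b)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, a.size, size=(n_boot, a.size))
    ib = rng.integers(0, b.size, size=(n_boot, b.size))
    diffs = np.median(a[ia], axis=1) - np.median(b[ib], axis=1)
    alpha = (1 - level) / 2
    return float(np.quantile(diffs, alpha)), float(np.quantile(diffs, 1 - alpha))
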