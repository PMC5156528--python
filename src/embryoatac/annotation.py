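"""Feature categories, timing classes, and enrichment statistics for peaks.

Accessible peaks are assigned to genomic feature categories with a strict
precedence (promoter > insulator > enhancer > other), to per-cycle timing
classes based on when they are first called present, and to metaphase
maintenance status. Enrichment of features across timing groups uses the
two-sided Fisher exact test on 2x2 contingency tables.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import merge_intervals, overlaps_any
from .peaks import overlaps

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationBundle",
    "assign_category",
    "assign_timing",
    "metaphase_maintenance",
    "enrichment",
    "enhancer_activity_fractions",
    "EARLY_STAGES",
]

CATEGORIES = ("promoter", "insulator", "enhancer", "other")
TIMING_ORDER = ("open_by_NC11", "new_NC12", "new_NC13", "absent")
#: embryonic stages counted as "early" activity (pre/peri-ZGA collection window)
EARLY_STAGES = ("4-6",)


@dataclass
class AnnotationBundle:
    """Annotation inputs for category assignment.

    ``tss``: table with chrom/pos/strand. ``insulator_tracks`` and
    ``enhancer_marks`` map factor names to interval tables;
    ``validated_enhancers`` carries a ``first_active_stage`` column.
    """

    tss: pd.DataFrame
    insulator_tracks: dict
    enhancer_marks: dict
    validated_enhancers: pd.DataFrame
    tss_flank: int = 50

    required_insulators: tuple = ("CTCF", "GAF", "BEAF32", "CP190", "Mod(Mdg4)", "Su(Hw)")
    required_marks: tuple = ("CBP", "H3K4me1", "H3K27ac", "Zelda")

    def __post_init__(self):
        for name in self.required_insulators:
            if name not in self.insulator_tracks:
                raise KeyError(f"missing insulator track: {name!r}")
        for name in self.required_marks:
            if name not in self.enhancer_marks:
                raise KeyError(f"missing enhancer evidence track: {name!r}")

    @classmethod
    def from_genome(cls, genome, tss_flank: int = 50) -> "AnnotationBundle":
        """Build a bundle from a synthetic genome model."""
        ins = {n: genome.insulator_tracks.get(n, pd.DataFrame(columns=["chrom", "start", "end"]))
               for n in cls.required_insulators}
        marks = {n: genome.mark_tracks.get(n, pd.DataFrame(columns=["chrom", "start", "end"]))
                 for n in cls.required_marks}
        return cls(
            tss=genome.tss,
            insulator_tracks=ins,
            enhancer_marks=marks,
            validated_enhancers=genome.validated_enhancers,
            tss_flank=tss_flank,
        )


def _track_hits(peaks: pd.DataFrame, track: pd.DataFrame) -> np.ndarray:
    out = np.zeros(len(peaks), dtype=bool)
    if track.empty or peaks.empty:
        return out
    for chrom, grp in peaks.groupby("chrom", sort=False):
        t = track[track["chrom"] == chrom]
        if t.empty:
            continue
        rs, re = merge_intervals(t["start"].to_numpy(), t["end"].to_numpy())
        out[grp.index.to_numpy()] = overlaps_any(
            grp["start"].to_numpy(), grp["end"].to_numpy(), rs, re
        )
    return out


def assign_category(peaks: pd.DataFrame, ann: AnnotationBundle) -> pd.DataFrame:
    """Assign each peak one feature category with strict precedence.

    promoter: any overlap with the TSS +/- flank window; insulator (if not
    promoter): overlap with peaks of >= 2 distinct insulator proteins;
    enhancer (if neither): overlap with a validated enhancer OR >= 2 distinct
    chromatin-mark/TF evidence tracks; otherwise "other". Alongside the
    exclusive category, the raw per-annotation overlap flags are returned so
    overlap bookkeeping is auditable.
    """
    peaks = peaks.reset_index(drop=True)
    tss_iv = pd.DataFrame(
        {
            "chrom": ann.tss["chrom"],
            "start": np.maximum(ann.tss["pos"] - ann.tss_flank, 0),
            "end": ann.tss["pos"] + ann.tss_flank + 1,
        }
    )
    is_promoter = _track_hits(peaks, tss_iv)
    ins_hits = {n: _track_hits(peaks, t) for n, t in ann.insulator_tracks.items()}
    n_ins = np.sum(list(ins_hits.values()), axis=0) if ins_hits else np.zeros(len(peaks))
    mark_hits = {n: _track_hits(peaks, t) for n, t in ann.enhancer_marks.items()}
    n_marks = np.sum(list(mark_hits.values()), axis=0) if mark_hits else np.zeros(len(peaks))
    validated = _track_hits(peaks, ann.validated_enhancers)

    category = np.full(len(peaks), "other", dtype=object)
    is_enh = validated | (n_marks >= 2)
    category[is_enh] = "enhancer"
    category[np.asarray(n_ins) >= 2] = "insulator"
    category[is_promoter] = "promoter"

    out = peaks.copy()
    out["category"] = category
    out["overlap_promoter"] = is_promoter
    out["n_insulator_tracks"] = np.asarray(n_ins, dtype=int)
    out["n_enhancer_marks"] = np.asarray(n_marks, dtype=int)
    out["overlap_validated_enhancer"] = validated
    for n, h in ins_hits.items():
        out[f"ins_{n}"] = h
    for n, h in mark_hits.items():
        out[f"mark_{n}"] = h
    return out


def assign_timing(
    union_peaks: pd.DataFrame, per_cycle: dict, min_overlap_bp: int = 1
) -> pd.DataFrame:
    """Classify union peaks by the first cycle in which they are called.

    ``per_cycle`` maps cycle number (e.g. 11, 12, 13) to that cycle's pooled
    peak call. open_by_NC11 = present in the earliest cycle; new_NC12 =
    absent then but present at NC12; new_NC13 = absent at NC11/NC12 and
    present at NC13; absent otherwise. Presence is any >= ``min_overlap_bp``
    overlap.
    """
    cycles = sorted(per_cycle)
    if not cycles:
        raise KeyError("per_cycle peak sets are required")
    if cycles != list(range(cycles[0], cycles[-1] + 1)):
        raise KeyError(f"per_cycle keys must be contiguous cycles, got {cycles}")
    present = {}
    for c in cycles:
        present[c] = overlaps(union_peaks, per_cycle[c], min_bp=min_overlap_bp)
    out = union_peaks.reset_index(drop=True).copy()
    timing = np.full(len(out), "absent", dtype=object)
    assigned = np.zeros(len(out), dtype=bool)
    labels = {11: "open_by_NC11", 12: "new_NC12", 13: "new_NC13"}
    for c in cycles:
        label = labels.get(c, f"new_NC{c}")
        newly = present[c] & ~assigned
        timing[newly] = label if c != cycles[0] else "open_by_NC11"
        assigned |= present[c]
    out["timing"] = timing
    for c in cycles:
        out[f"present_NC{c}"] = present[c]
    return out


def metaphase_maintenance(
    interphase_peaks: dict, metaphase_peaks: dict, categories: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Fraction of interphase peaks still accessible at metaphase, per cycle.

    ``interphase_peaks`` and ``metaphase_peaks`` map cycle -> peak table.
    When ``categories`` (a table with chrom/start/end/category) is given,
    fractions are additionally split by feature category. Returns rows of
    (cycle, category, n_interphase, n_maintained, fraction); category "all"
    rows summarize each cycle. Empty interphase sets yield NaN with a
    warning.
    """
    rows = []
    for cycle, inter in interphase_peaks.items():
        meta = metaphase_peaks.get(cycle)
        if meta is None:
            continue
        if inter.empty:
            warnings.warn(f"metaphase_maintenance: no interphase peaks for cycle {cycle}")
            rows.append((cycle, "all", 0, 0, float("nan")))
            continue
        maintained = overlaps(inter, meta)
        rows.append((cycle, "all", len(inter), int(maintained.sum()), float(maintained.mean())))
        if categories is not None:
            cat = categories.reset_index(drop=True)
            cat_of_peak = overlaps_to_category(inter, cat)
            for c in CATEGORIES:
                sel = cat_of_peak == c
                if sel.sum() == 0:
                    continue
                rows.append(
                    (cycle, c, int(sel.sum()), int(maintained[sel].sum()), float(maintained[sel].mean()))
                )
    return pd.DataFrame(rows, columns=["cycle", "category", "n_interphase", "n_maintained", "fraction"])


def overlaps_to_category(peaks: pd.DataFrame, categorized: pd.DataFrame) -> np.ndarray:
    """Carry categories from a categorized peak table onto another peak set."""
    out = np.full(len(peaks), "other", dtype=object)
    for c in ("enhancer", "insulator", "promoter"):  # promoter last: precedence
        sub = categorized[categorized["category"] == c]
        if sub.empty:
            continue
        hit = overlaps(peaks.reset_index(drop=True), sub)
        out[hit] = c
    return out


def enrichment(feature_flag, group_flag):
    """Odds ratio and two-sided Fisher exact p for a feature x group table.

    Returns ``(odds_ratio, p_value, table)`` with ``table = [[a, b], [c, d]]``
    where ``a`` counts feature+ group+ peaks. The odds ratio is the sample
    ratio ``ad/bc`` (``inf`` when bc = 0 with ad > 0, ``nan`` for 0/0); the
    p-value is the exact two-sided hypergeometric tail (sum over tables with
    probability <= observed). Empty margins give OR nan and p = 1 with a
    warning.
    """
    f = np.asarray(feature_flag, dtype=bool)
    g = np.asarray(group_flag, dtype=bool)
    if f.shape != g.shape:
        raise ValueError("flags must align")
    a = int(np.sum(f & g))
    b = int(np.sum(f & ~g))
    c = int(np.sum(~f & g))
    d = int(np.sum(~f & ~g))
    table = np.array([[a, b], [c, d]])
    if min(table.sum(axis=0).min(), table.sum(axis=1).min()) == 0:
        warnings.warn("enrichment: empty margin; association undefined", stacklevel=2)
        return float("nan"), 1.0, table
    if b * c == 0:
        odds = math.inf if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return odds, float(p), table


def enhancer_activity_fractions(
    timing_of_enhancer: pd.Series | np.ndarray,
    first_active_stage: pd.Series | np.ndarray,
    early_stages: tuple = EARLY_STAGES,
) -> pd.DataFrame:
    """Distribution of first-active stages within each peak timing class.

    Inputs align one entry per validated enhancer: its peak timing class (or
    "absent" when no accessible peak overlaps it) and its first-active stage
    label. Unlabeled enhancers (NaN/empty stage) are excluded from
    denominators with a log message. Returns per (timing, stage) rows with
    fraction within timing class, plus per-timing "early" (stage in
    ``early_stages``) fractions under stage label ``early``.
    """
    df = pd.DataFrame({"timing": np.asarray(timing_of_enhancer, dtype=object),
                       "stage": np.asarray(first_active_stage, dtype=object)})
    unlabeled = df["stage"].isna() | (df["stage"] == "")
    if unlabeled.any():
        logger.info("enhancer_activity_fractions: %d unlabeled enhancers excluded", int(unlabeled.sum()))
    lab = df[~unlabeled]
    rows = []
    for timing, grp in lab.groupby("timing"):
        n = len(grp)
        for stage, cnt in grp["stage"].value_counts().items():
            rows.append((timing, stage, int(cnt), n, cnt / n))
        n_early = int(grp["stage"].isin(early_stages).sum())
        rows.append((timing, "early", n_early, n, n_early / n))
    return pd.DataFrame(rows, columns=["timing", "stage", "count", "n", "fraction"])
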