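"""Fragment-level I/O and pre-processing.

The universal currency of the pipeline is the sequenced fragment: the genomic
interval spanned by a Tn5-generated paired-end insert after mate collapsing.
This module reads fragment BED files, applies the transposase end correction,
and splits libraries into sub-nucleosomal ("open") and nucleosome-protected
fractions by insert length.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical chromosome filter used for all genome-wide statistics
CANONICAL_CHROMS = frozenset({"chrX", "chr2L", "chr2R", "chr3L", "chr3R", "chr4"})

#: insert-length cutoff (inclusive) separating open from nucleosomal fragments
OPEN_CUTOFF = 98


class FragmentStateError(RuntimeError):
    """Raised when an operation is applied in the wrong adjustment state."""


class FragmentParseError(ValueError):
    """Raised for malformed fragment records; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass
class FragmentSet:
    """A collection of fragments plus sample metadata.

    ``df`` holds one row per fragment with at least ``chrom`` (str),
    ``start`` and ``end`` (int, 0-based half-open). ``tn5_adjusted`` records
    whether the −4/+5 transposase end correction has been applied; it may be
    set exactly once.
    """

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    tn5_adjusted: bool = False

    def __post_init__(self):
        for col in ("chrom", "start", "end"):
            if col not in self.df.columns:
                raise ValueError(f"fragment table missing column {col!r}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def per_chrom(self) -> dict[str, pd.DataFrame]:
        return {str(c): g for c, g in self.df.groupby("chrom", sort=True)}

    def copy(self) -> "FragmentSet":
        return FragmentSet(self.df.copy(), dict(self.metadata), self.tn5_adjusted)


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fragments(
    path,
    allowed_chroms: Iterable[str] | None = CANONICAL_CHROMS,
    metadata: Mapping | None = None,
) -> FragmentSet:
    """Read a BED3+ fragment file, dropping disallowed chromosomes.

    Only the first three columns are interpreted (chrom, start, end); extra
    columns are ignored. Records on chromosomes outside ``allowed_chroms``
    are dropped with a logged count; ``allowed_chroms=None`` keeps all.
    Malformed records raise :class:`FragmentParseError` with the offending
    line number; an empty file yields an empty set with a warning.
    """
    allowed = None if allowed_chroms is None else set(allowed_chroms)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    n_dropped = 0
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FragmentParseError("expected >=3 tab-separated fields", lineno)
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FragmentParseError(f"non-integer coordinates: {exc}", lineno) from None
            if start < 0 or start >= end:
                raise FragmentParseError(
                    f"invalid interval [{start}, {end}) (need 0 <= start < end)", lineno
                )
            if allowed is not None and chrom not in allowed:
                n_dropped += 1
                continue
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
    if n_dropped:
        logger.info("read_fragments(%s): dropped %d fragments on disallowed chromosomes", path, n_dropped)
    if not chroms:
        warnings.warn(f"{path}: no fragments retained", stacklevel=2)
    df = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=str),
            "start": pd.Series(starts, dtype=np.int64),
            "end": pd.Series(ends, dtype=np.int64),
        }
    )
    return FragmentSet(df, dict(metadata or {}))


def write_fragments(fs: FragmentSet, path, extra_cols: Iterable[str] = ()) -> None:
    """Write fragments as BED3+ with a trailing length column."""
    out = fs.df[["chrom", "start", "end"]].copy()
    out["length"] = fs.lengths
    for col in extra_cols:
        out[col] = fs.df[col].values
    out.to_csv(path, sep="\t", header=False, index=False)


def adjust_tn5(fs: FragmentSet, convention: str = "paper") -> FragmentSet:
    """Correct fragment ends for the 9-bp Tn5 insertion-site duplication.

    ``convention="paper"`` widens each fragment outward (start − 4, end + 5),
    matching the GRanges one-liner the source analysis used; lengths grow by
    exactly 9 bp. ``convention="centered"`` applies the common inward +4/−5
    shift instead (lengths shrink by 9 bp). Starts falling below 0 are clamped
    with a warning. Applying the correction twice is a state error.
    """
    if fs.tn5_adjusted:
        raise FragmentStateError("Tn5 adjustment already applied to this FragmentSet")
    if convention not in ("paper", "centered"):
        raise ValueError(f"unknown tn5 convention {convention!r}")
    df = fs.df.copy()
    if convention == "paper":
        df["start"] = df["start"] - 4
        df["end"] = df["end"] + 5
    else:
        df["start"] = df["start"] + 4
        df["end"] = df["end"] - 5
        if (df["start"] >= df["end"]).any():
            raise ValueError("centered Tn5 adjustment produced empty fragments (length <= 9)")
    n_clamped = int((df["start"] < 0).sum())
    if n_clamped:
        warnings.warn(f"adjust_tn5: clamped {n_clamped} fragment starts to 0", stacklevel=2)
        df["start"] = df["start"].clip(lower=0)
    return FragmentSet(df, dict(fs.metadata), tn5_adjusted=True)


def split_by_length(
    fs: FragmentSet, cutoff: int = OPEN_CUTOFF, require_adjusted: bool = True
) -> tuple[FragmentSet, FragmentSet]:
    """Partition fragments into (open, nucleosomal) by insert length.

    Open fragments are those with length <= ``cutoff`` (inclusive). The split
    is exhaustive and disjoint. By default the set must carry the Tn5 end
    correction, so the cutoff is interpreted on corrected lengths.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if require_adjusted and not fs.tn5_adjusted:
        raise FragmentStateError("split_by_length requires a Tn5-adjusted FragmentSet")
    is_open = fs.lengths <= cutoff
    open_fs = FragmentSet(fs.df[is_open].reset_index(drop=True), dict(fs.metadata), fs.tn5_adjusted)
    nuc_fs = FragmentSet(fs.df[~is_open].reset_index(drop=True), dict(fs.metadata), fs.tn5_adjusted)
    return open_fs, nuc_fs


def deduplicate(fs: FragmentSet) -> FragmentSet:
    """Optional exact-interval deduplication (off by default in the pipeline)."""
    df = fs.df.drop_duplicates(subset=["chrom", "start", "end"]).reset_index(drop=True)
    return FragmentSet(df, dict(fs.metadata), fs.tn5_adjusted)


def length_histogram(fs: FragmentSet, sample_n: int = 100_000, seed: int = 0) -> pd.DataFrame:
    """Counts per 1-bp length bin from a seeded subsample without replacement.

    If the set holds fewer than ``sample_n`` fragments the full set is used.
    Returns a table with columns ``length`` and ``count``.
    """
    lengths = fs.lengths
    if lengths.size > sample_n:
        rng = np.random.default_rng(seed)
        lengths = rng.choice(lengths, size=sample_n, replace=False)
    if lengths.size == 0:
        return pd.DataFrame({"length": np.array([], dtype=int), "count": np.array([], dtype=int)})
    values, counts = np.unique(lengths, return_counts=True)
    return pd.DataFrame({"length": values.astype(int), "count": counts.astype(int)})


def concat(sets: list[FragmentSet], metadata: Mapping | None = None) -> FragmentSet:
    """Concatenate fragment sets sharing an adjustment state."""
    if not sets:
        raise ValueError("need at least one FragmentSet")
    states = {fs.tn5_adjusted for fs in sets}
    if len(states) > 1:
        raise FragmentStateError("cannot concatenate sets with mixed Tn5 adjustment state")
    df = pd.concat([fs.df for fs in sets], ignore_index=True)
    return FragmentSet(df, dict(metadata or {}), sets[0].tn5_adjusted)
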