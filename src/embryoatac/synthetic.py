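"""Synthetic data with known ground truth for the whole pipeline.

The generator emulates the structure of a time-resolved single-embryo ATAC
experiment across the pre-MBT nuclear cycles (NC11–NC14):

* a small genome with annotated TSSs, insulator-protein tracks, enhancer
  marks, validated enhancers, and "truth" accessible peaks carrying a timing
  class (open by NC11, new at NC12, new at NC13), an N:C-ratio- vs
  time-dependence label, and a metaphase-persistence flag;
* fragment libraries whose insert lengths follow a bimodal exponential +
  Gaussian mixture, with sub-nucleosomal ("open") fragments concentrated in
  peaks that have opened by the sampled stage, and nucleosome-protected
  fragments phased at the canonical −1/+1 dyad positions around TSSs;
* haploid series in which N:C-ratio-dependent peaks open one cycle later
  than in diploids while time-dependent peaks open at the same cycle;
* early-S nucleosome disruption: at the first minutes of each interphase,
  extra dyad-position jitter and reduced open-fragment yield, strongest in
  NC11/NC12 and weak by NC13;
* fluorescence movies of nuclei whose punctate ("focal") intensity fraction
  follows a known S-phase trajectory, for the texture-heterogeneity stage.

Every draw flows from a single integer seed, so identical configurations
reproduce bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fragments import FragmentSet

__all__ = [
    "GenomeConfig",
    "GenomeModel",
    "SampleSpec",
    "FragmentMixtureParams",
    "ImageSpec",
    "PlacementError",
    "make_genome",
    "sample_fragments",
    "make_series",
    "make_pcna_movie",
    "default_timepoint_grid",
    "write_genome",
]

INSULATOR_PROTEINS = ("CTCF", "GAF", "BEAF32", "CP190", "Mod(Mdg4)", "Su(Hw)")
ENHANCER_MARKS = ("CBP", "H3K4me1", "H3K27ac", "Zelda")
STAGE_VOCABULARY = ("4-6", "7-8", "9-10", "11-12", "13-16")
TIMING_CLASSES = ("NC11", "NC12", "NC13")

#: minutes post-anaphase at which metaphase begins, per cycle
METAPHASE_MINUTES = {11: 9.0, 12: 12.0, 13: 18.0, 14: 21.0}


class PlacementError(RuntimeError):
    """Requested feature density cannot be placed without overlap."""


@dataclass
class GenomeConfig:
    """Settings for :func:`make_genome`.

    Defaults give a two-chromosome 2 Mb toy genome with 200 truth peaks in
    the study's timing-class proportions (31% open by NC11, 39% new at NC12,
    30% new at NC13) and an N:C-dependent share of dynamic peaks matching
    the study's 2630-of-4288 split.
    """

    chrom_sizes: dict = field(
        default_factory=lambda: {"chr2L": 1_000_000, "chr3R": 1_000_000}
    )
    n_truth_peaks: int = 200
    timing_proportions: tuple = (0.31, 0.39, 0.30)
    nc_dependent_fraction: float = 0.61
    metaphase_persistent_prob: float = 0.75
    peak_width_range: tuple = (300, 800)
    min_peak_gap: int = 3000
    # latent feature mix of truth peaks (promoter / insulator / enhancer / other)
    category_proportions: tuple = (0.30, 0.15, 0.35, 0.20)
    n_background_tss: int = 40
    enhancer_early_fraction: float = 0.452
    validated_enhancer_prob: float = 0.5


@dataclass
class GenomeModel:
    """A toy genome plus annotations and the ground-truth peak table."""

    chrom_sizes: dict
    tss: pd.DataFrame  # tss_id, chrom, pos, strand
    insulator_tracks: dict  # name -> DataFrame(chrom, start, end)
    mark_tracks: dict  # name -> DataFrame(chrom, start, end)
    validated_enhancers: pd.DataFrame  # chrom, start, end, first_active_stage
    truth_peaks: pd.DataFrame
    # truth_peaks columns: peak_id, chrom, start, end, timing_class,
    #   dependence, metaphase_persistent, category

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_sizes)

    def validate(self) -> None:
        for name, df in [("truth_peaks", self.truth_peaks), ("enhancers", self.validated_enhancers)]:
            for _, row in df.iterrows():
                size = self.chrom_sizes[row["chrom"]]
                if not (0 <= row["start"] < row["end"] <= size):
                    raise ValueError(f"{name}: interval out of bounds: {row.to_dict()}")
        if not self.tss["strand"].isin(["+", "-"]).all():
            raise ValueError("every TSS must have a strand")
        for chrom, grp in self.truth_peaks.groupby("chrom"):
            s = grp.sort_values("start")
            if (s["start"].values[1:] < s["end"].values[:-1]).any():
                raise ValueError(f"truth peaks overlap on {chrom}")


@dataclass
class SampleSpec:
    """One sequencing sample: genotype, stage, and library size."""

    genotype: str  # "diploid" | "haploid"
    cycle: int
    minutes_post_anaphase: float
    phase: str  # "interphase" | "metaphase"
    n_fragments: int
    seed: int

    def __post_init__(self):
        if self.genotype not in ("diploid", "haploid"):
            raise ValueError(f"unknown genotype {self.genotype!r}")
        lo = 12 if self.genotype == "haploid" else 11
        if not (lo <= self.cycle <= 14):
            raise ValueError(f"{self.genotype} cycle must be in [{lo}, 14], got {self.cycle}")
        if self.minutes_post_anaphase < 0:
            raise ValueError("minutes_post_anaphase must be >= 0")
        if self.n_fragments <= 0:
            raise ValueError("n_fragments must be positive")
        if self.phase not in ("interphase", "metaphase"):
            raise ValueError(f"unknown phase {self.phase!r}")

    def as_dict(self) -> dict:
        return {
            "genotype": self.genotype,
            "cycle": self.cycle,
            "minutes_post_anaphase": self.minutes_post_anaphase,
            "phase": self.phase,
            "n_fragments": self.n_fragments,
            "seed": self.seed,
        }


@dataclass
class FragmentMixtureParams:
    """Insert-length mixture and fragment-placement parameters.

    ``weights`` are the mass fractions of (open exponential, mono-nucleosome
    Gaussian, di-nucleosome Gaussian). ``background_fraction`` is the share
    of open-class fragments scattered uniformly rather than into open peaks.
    The open-length exponential scale is chosen so that the fitted
    open/nucleosomal density crossover lands near the conventional 98 bp
    split. Disruption parameters implement early-S nucleosome disorder:
    within ``disruption_window_min`` minutes of anaphase, dyad jitter grows
    and open-fragment yield drops by cycle-dependent amounts that decay
    towards NC13.
    """

    open_scale: float = 23.0
    nucleosomal_means: tuple = (170.0, 360.0)
    nucleosomal_sds: tuple = (50.0, 60.0)
    weights: tuple = (0.45, 0.45, 0.10)
    background_fraction: float = 0.25
    min_insert: int = 10
    # nucleosome phasing around TSSs
    phasing_fraction: float = 0.6
    dyad_offset_upstream: int = -180
    dyad_offset_downstream: int = 135
    dyad_jitter_sd: float = 20.0
    # early-S disruption (per-cycle magnitudes, decaying towards the MBT)
    disruption_window_min: float = 3.0
    disruption_extra_jitter: dict = field(
        default_factory=lambda: {11: 30.0, 12: 20.0, 13: 5.0, 14: 3.0}
    )
    disruption_open_loss: dict = field(
        default_factory=lambda: {11: 0.5, 12: 0.35, 13: 0.1, 14: 0.05}
    )

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if len(self.nucleosomal_means) != len(self.nucleosomal_sds) or len(w) != len(self.nucleosomal_means) + 1:
            raise ValueError("weights must cover the exponential plus each Gaussian")
        if self.open_scale <= 0 or min(self.nucleosomal_sds, default=1) <= 0:
            raise ValueError("scales and sds must be positive")
        if not (0 <= self.background_fraction <= 1):
            raise ValueError("background_fraction must be in [0, 1]")


def _place_nonoverlapping(rng, size: int, widths: np.ndarray, min_gap: int) -> np.ndarray:
    """Uniformly place sorted non-overlapping intervals of given widths."""
    n = widths.size
    slack = size - int(widths.sum()) - (n + 1) * min_gap
    if slack < 0:
        raise PlacementError(
            f"cannot place {n} peaks (total width {int(widths.sum())}) in {size} bp "
            f"with {min_gap} bp gaps"
        )
    gaps = np.sort(rng.random(n)) * slack
    starts = (gaps + min_gap * (1 + np.arange(n)) + np.concatenate(([0], np.cumsum(widths[:-1])))).astype(np.int64)
    return starts


def make_genome(config: GenomeConfig | None = None, seed: int = 0) -> GenomeModel:
    """Build a deterministic annotated toy genome with truth peaks."""
    config = config or GenomeConfig()
    rng = np.random.default_rng(seed)
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)

    n = config.n_truth_peaks
    records = []
    if n > 0:
        per_chrom = rng.multinomial(n, sizes / sizes.sum())
        widths_all = rng.integers(config.peak_width_range[0], config.peak_width_range[1] + 1, size=n)
        timing = rng.choice(TIMING_CLASSES, size=n, p=np.asarray(config.timing_proportions))
        dependence = np.where(
            rng.random(n) < config.nc_dependent_fraction, "nc_ratio", "time"
        )
        persistent = rng.random(n) < config.metaphase_persistent_prob
        category = rng.choice(
            ["promoter", "insulator", "enhancer", "other"],
            size=n,
            p=np.asarray(config.category_proportions),
        )
        i0 = 0
        for chrom, k in zip(chroms, per_chrom):
            w = widths_all[i0 : i0 + k]
            starts = _place_nonoverlapping(rng, config.chrom_sizes[chrom], w, config.min_peak_gap)
            for j in range(k):
                idx = i0 + j
                records.append(
                    {
                        "peak_id": f"truth_{idx:04d}",
                        "chrom": chrom,
                        "start": int(starts[j]),
                        "end": int(starts[j] + w[j]),
                        "timing_class": timing[idx],
                        "dependence": dependence[idx],
                        "metaphase_persistent": bool(persistent[idx]),
                        "category": category[idx],
                    }
                )
            i0 += k
    truth = pd.DataFrame(
        records,
        columns=[
            "peak_id", "chrom", "start", "end",
            "timing_class", "dependence", "metaphase_persistent", "category",
        ],
    )

    # --- annotations keyed to the latent categories -------------------------
    tss_rows = []
    ins_rows: dict[str, list] = {p: [] for p in INSULATOR_PROTEINS}
    mark_rows: dict[str, list] = {m: [] for m in ENHANCER_MARKS}
    enh_rows = []

    def _interval_around(center, chrom, half=250):
        size = config.chrom_sizes[chrom]
        return {"chrom": chrom, "start": int(max(0, center - half)), "end": int(min(size, center + half))}

    for _, pk in truth.iterrows():
        center = (pk["start"] + pk["end"]) // 2
        if pk["category"] == "promoter":
            strand = "+" if rng.random() < 0.5 else "-"
            tss_rows.append(
                {"tss_id": f"tss_{pk['peak_id']}", "chrom": pk["chrom"], "pos": int(center), "strand": strand}
            )
            # N:C-dependent promoters carry GAF, a factor tied to late opening
            if pk["dependence"] == "nc_ratio":
                ins_rows["GAF"].append(_interval_around(center, pk["chrom"]))
        elif pk["category"] == "insulator":
            pool = [p for p in INSULATOR_PROTEINS if p != "GAF"]
            chosen = list(rng.choice(pool, size=2, replace=False))
            if pk["dependence"] == "nc_ratio":
                chosen.append("GAF")
            for p in chosen:
                ins_rows[p].append(_interval_around(center, pk["chrom"]))
        elif pk["category"] == "enhancer":
            if rng.random() < config.validated_enhancer_prob:
                early = rng.random() < config.enhancer_early_fraction
                stage = STAGE_VOCABULARY[0] if early else str(rng.choice(STAGE_VOCABULARY[1:]))
                enh_rows.append({**_interval_around(center, pk["chrom"]), "first_active_stage": stage})
            else:
                # time-dependent enhancers are Zelda-marked, the early-opening factor
                marks = ["Zelda"] if pk["dependence"] == "time" else ["CBP"]
                others = [m for m in ENHANCER_MARKS if m not in marks]
                marks += list(rng.choice(others, size=1))
                for m in marks:
                    mark_rows[m].append(_interval_around(center, pk["chrom"]))

    # background TSSs outside peaks (promoters that never open)
    for i in range(config.n_background_tss):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1000, config.chrom_sizes[chrom] - 1000))
        strand = "+" if rng.random() < 0.5 else "-"
        tss_rows.append({"tss_id": f"tss_bg_{i:03d}", "chrom": chrom, "pos": pos, "strand": strand})

    tss = pd.DataFrame(tss_rows, columns=["tss_id", "chrom", "pos", "strand"])
    cols = ["chrom", "start", "end"]
    insulator_tracks = {p: pd.DataFrame(rows, columns=cols) for p, rows in ins_rows.items()}
    mark_tracks = {m: pd.DataFrame(rows, columns=cols) for m, rows in mark_rows.items()}
    enhancers = pd.DataFrame(enh_rows, columns=cols + ["first_active_stage"])

    model = GenomeModel(
        chrom_sizes=dict(config.chrom_sizes),
        tss=tss,
        insulator_tracks=insulator_tracks,
        mark_tracks=mark_tracks,
        validated_enhancers=enhancers,
        truth_peaks=truth,
    )
    model.validate()
    return model


def onset_cycle(timing_class: str, dependence: str, genotype: str) -> int:
    """Cycle at which a truth peak first opens for the given genotype.

    In haploids, N:C-ratio-dependent peaks open one cycle later (the embryo
    needs an extra division to reach the same N:C ratio); time-dependent
    peaks open at the same cycle index.
    """
    base = int(timing_class[2:])
    if genotype == "haploid" and dependence == "nc_ratio":
        return base + 1
    return base


def _open_peaks(genome: GenomeModel, spec: SampleSpec) -> pd.DataFrame:
    t = genome.truth_peaks
    if t.empty:
        return t
    onsets = np.array(
        [onset_cycle(tc, dep, spec.genotype) for tc, dep in zip(t["timing_class"], t["dependence"])]
    )
    is_open = onsets <= spec.cycle
    if spec.phase == "metaphase":
        is_open &= t["metaphase_persistent"].to_numpy()
    return t[is_open]


def sample_fragments(
    genome: GenomeModel,
    spec: SampleSpec,
    mixture: FragmentMixtureParams | None = None,
) -> FragmentSet:
    """Draw one fragment library for a sample.

    Insert lengths follow the configured exponential/Gaussian mixture.
    Open-class fragments land inside truth peaks whose onset has passed for
    this genotype/stage (metaphase samples: persistent peaks only), except
    for a uniform background share. Nucleosomal-fragment midpoints are
    phased at the configured −1/+1 dyad offsets around TSSs with early-S
    jitter, the remainder uniform.
    """
    mixture = mixture or FragmentMixtureParams()
    if genome.truth_peaks.shape[0] and not set(genome.truth_peaks["chrom"]).issubset(genome.chrom_sizes):
        raise ValueError("genome truth peaks reference unknown chromosomes")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_fragments
    chroms = genome.chrom_names
    sizes = np.array([genome.chrom_sizes[c] for c in chroms], dtype=np.int64)

    early_s = spec.phase == "interphase" and spec.minutes_post_anaphase <= mixture.disruption_window_min
    extra_jitter = mixture.disruption_extra_jitter.get(spec.cycle, 0.0) if early_s else 0.0
    open_loss = mixture.disruption_open_loss.get(spec.cycle, 0.0) if early_s else 0.0

    comp = rng.choice(len(mixture.weights), size=n, p=np.asarray(mixture.weights))
    lengths = np.empty(n, dtype=np.int64)
    is_open = comp == 0
    n_open = int(is_open.sum())
    lengths[is_open] = mixture.min_insert + np.round(
        rng.exponential(mixture.open_scale, size=n_open)
    ).astype(np.int64)
    for k, (m, s) in enumerate(zip(mixture.nucleosomal_means, mixture.nucleosomal_sds), start=1):
        sel = comp == k
        draw = rng.normal(m, s, size=int(sel.sum()))
        bad = draw < 100  # resample the sub-mononucleosome tail, no pile-up
        while bad.any():
            draw[bad] = rng.normal(m, s, size=int(bad.sum()))
            bad = draw < 100
        lengths[sel] = np.round(draw).astype(np.int64)

    chrom_idx = np.empty(n, dtype=np.int64)
    mid = np.empty(n, dtype=np.int64)

    # --- open fragments: peak-concentrated plus uniform background ----------
    open_df = _open_peaks(genome, spec)
    p_in_peak = (1.0 - mixture.background_fraction) * (1.0 - open_loss)
    open_pos = np.flatnonzero(is_open)
    in_peak = rng.random(open_pos.size) < (p_in_peak if len(open_df) else 0.0)
    bg_sel = open_pos[~in_peak]
    chrom_idx[bg_sel], mid[bg_sel] = _uniform_positions(rng, bg_sel.size, sizes)
    if in_peak.any():
        pk_sel = open_pos[in_peak]
        widths = (open_df["end"] - open_df["start"]).to_numpy()
        which = rng.choice(len(open_df), size=pk_sel.size, p=widths / widths.sum())
        chrom_lookup = {c: i for i, c in enumerate(chroms)}
        pk_chrom = open_df["chrom"].map(chrom_lookup).to_numpy()
        chrom_idx[pk_sel] = pk_chrom[which]
        mid[pk_sel] = open_df["start"].to_numpy()[which] + (
            rng.random(pk_sel.size) * widths[which]
        ).astype(np.int64)

    # --- nucleosomal fragments: TSS-phased plus uniform ---------------------
    nuc_pos = np.flatnonzero(~is_open)
    has_tss = len(genome.tss) > 0
    phased = rng.random(nuc_pos.size) < (mixture.phasing_fraction if has_tss else 0.0)
    bg_sel = nuc_pos[~phased]
    chrom_idx[bg_sel], mid[bg_sel] = _uniform_positions(rng, bg_sel.size, sizes)
    if phased.any():
        ph_sel = nuc_pos[phased]
        n_tss = len(genome.tss)
        # early-S disruption: replication displaces whole nucleosomes, so each
        # promoter's -1/+1 dyads carry a shared positional offset this sample
        displacement = (
            rng.normal(0, extra_jitter, size=(n_tss, 2)) if extra_jitter > 0 else np.zeros((n_tss, 2))
        )
        t_idx = rng.integers(n_tss, size=ph_sel.size)
        tss_pos = genome.tss["pos"].to_numpy()[t_idx]
        tss_strand = genome.tss["strand"].to_numpy()[t_idx]
        chrom_lookup = {c: i for i, c in enumerate(chroms)}
        chrom_idx[ph_sel] = genome.tss["chrom"].map(chrom_lookup).to_numpy()[t_idx]
        upstream = rng.random(ph_sel.size) < 0.5
        offset = np.where(upstream, mixture.dyad_offset_upstream, mixture.dyad_offset_downstream)
        offset = offset + displacement[t_idx, np.where(upstream, 0, 1)]
        offset = np.where(tss_strand == "+", offset, -offset)
        mid[ph_sel] = (
            tss_pos + np.round(offset + rng.normal(0, mixture.dyad_jitter_sd, ph_sel.size))
        ).astype(np.int64)

    starts = mid - lengths // 2
    ends = starts + lengths
    # shift fragments that stick out back inside the chromosome
    csize = sizes[chrom_idx]
    shift = np.where(starts < 0, -starts, 0) - np.where(ends > csize, ends - csize, 0)
    starts = starts + shift
    ends = ends + shift
    starts = np.maximum(starts, 0)
    ends = np.minimum(ends, csize)

    df = pd.DataFrame(
        {
            "chrom": pd.Categorical.from_codes(chrom_idx, categories=chroms).astype(str),
            "start": starts,
            "end": ends,
        }
    )
    return FragmentSet(df, spec.as_dict(), tn5_adjusted=True)


def _uniform_positions(rng, n, sizes):
    if n == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    p = sizes / sizes.sum()
    ci = rng.choice(sizes.size, size=n, p=p)
    pos = (rng.random(n) * sizes[ci]).astype(np.int64)
    return ci, pos


def default_timepoint_grid(genotype: str) -> list[tuple[int, float]]:
    """The 13-timepoint 3-min sampling grid (shifted one cycle for haploids)."""
    if genotype == "diploid":
        cycles = {11: (3, 6, 9), 12: (3, 6, 9, 12), 13: (3, 6, 9, 12, 15, 18)}
    else:
        cycles = {12: (3, 6, 9), 13: (3, 6, 9, 12), 14: (3, 6, 9, 12, 15, 18)}
    return [(c, float(m)) for c, mins in cycles.items() for m in mins]


def make_series(
    genome: GenomeModel,
    genotype: str,
    timepoint_grid: Sequence[tuple[int, float]],
    mixture: FragmentMixtureParams | None = None,
    seed: int = 0,
    n_fragments: int = 50_000,
    metaphase_minutes: dict | None = None,
) -> list[FragmentSet]:
    """Sample one fragment library per (cycle, minutes) grid point.

    Phase is inferred from ``metaphase_minutes`` (default: metaphase begins
    at 9/12/18/21 min in NC11–NC14). Grid must be monotone in developmental
    time. Per-timepoint seeds are spawned from ``seed``.
    """
    mm = metaphase_minutes or METAPHASE_MINUTES
    keys = [(c, m) for c, m in timepoint_grid]
    if keys != sorted(keys):
        raise ValueError("timepoint grid must be monotone in (cycle, minutes)")
    child_seeds = np.random.SeedSequence(seed).generate_state(max(len(keys), 1)) % (2**31)
    out = []
    for (cycle, minutes), s in zip(keys, child_seeds):
        phase = "metaphase" if minutes >= mm.get(cycle, np.inf) else "interphase"
        spec = SampleSpec(
            genotype=genotype,
            cycle=cycle,
            minutes_post_anaphase=minutes,
            phase=phase,
            n_fragments=n_fragments,
            seed=int(s),
        )
        out.append(sample_fragments(genome, spec, mixture))
    return out


# --------------------------------------------------------------------------
# imaging
# --------------------------------------------------------------------------

@dataclass
class ImageSpec:
    """Settings for the synthetic replication-focus movie."""

    n_frames: int = 20
    n_nuclei: int = 9
    frame_shape: tuple = (192, 192)
    nucleus_radius: int = 24
    n_foci: int = 150
    focus_sigma: float = 1.5
    psf_sigma: float = 1.0
    total_intensity: float = 4.0e5
    focal_fraction: Sequence[float] = ()
    conserve_total: bool = True
    poisson_noise: bool = True
    noise_scale: float = 1.0  # photons per intensity unit; higher = less shot noise
    pixel_size_nm: float = 100.0


def default_focal_trajectory(n_frames: int = 20, peak: float = 0.5) -> np.ndarray:
    """A rising-then-falling S-phase focal-fraction trajectory.

    The peak defaults to 0.5: about half the nuclear signal in punctate
    form at maximal replication activity, the regime where the texture
    statistic discriminates well.
    """
    up = n_frames // 2
    rise = np.linspace(0.02, peak, up)
    fall = np.linspace(peak * 0.92, 0.03, n_frames - up)
    return np.concatenate([rise, fall])


def make_pcna_movie(spec: ImageSpec, seed: int = 0):
    """Render a movie of nuclei with a known focal-intensity fraction.

    Each nucleus is a disk of uniform intensity carrying punctate foci whose
    summed intensity equals ``focal_fraction[t]`` of the nucleus total (the
    total is conserved across frames when ``conserve_total``). Returns
    ``(stack, labels, truth)``: a float movie of shape (frames, H, W), an
    integer label mask (0 = background), and the truth trajectory.
    """
    truth = np.asarray(spec.focal_fraction, dtype=float)
    if truth.size != spec.n_frames:
        raise ValueError("focal_fraction must have one value per frame")
    if ((truth < 0) | (truth > 1)).any():
        raise ValueError("focal fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = spec.frame_shape
    labels = np.zeros((h, w), dtype=np.int32)
    grid = int(np.ceil(np.sqrt(spec.n_nuclei)))
    pitch_y, pitch_x = h // grid, w // grid
    yy, xx = np.mgrid[0:h, 0:w]
    centers = []
    for i in range(spec.n_nuclei):
        cy = (i // grid) * pitch_y + pitch_y // 2
        cx = (i % grid) * pitch_x + pitch_x // 2
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.nucleus_radius**2
        labels[disk] = i + 1
        centers.append((cy, cx))

    from scipy.ndimage import gaussian_filter

    stack = np.zeros((spec.n_frames, h, w), dtype=float)
    masks = [labels == lab for lab in range(1, spec.n_nuclei + 1)]
    for t in range(spec.n_frames):
        f = truth[t]
        frame = np.zeros((h, w), dtype=float)
        for (cy, cx), mask in zip(centers, masks):
            npx = int(mask.sum())
            my, mx = np.nonzero(mask)
            frame[mask] = (1.0 - f) * spec.total_intensity / npx
            if f > 0:
                # foci: Gaussian blobs at random interior positions with
                # variable amplitude; the active-focus count scales with the
                # focal fraction (more replication factories at S-phase peak)
                k = max(int(np.ceil(spec.n_foci * f)), 1)
                theta = rng.random(k) * 2 * np.pi
                r = np.sqrt(rng.random(k)) * (spec.nucleus_radius - 3)
                fy = cy + r * np.sin(theta)
                fx = cx + r * np.cos(theta)
                amp = rng.random(k) + 0.2
                blob = np.zeros(my.size, dtype=float)
                for y0, x0, a in zip(fy, fx, amp):
                    d2 = (my - y0) ** 2 + (mx - x0) ** 2
                    blob += a * np.exp(-d2 / (2 * spec.focus_sigma**2))
                if blob.sum() > 0:
                    frame[my, mx] += blob * (f * spec.total_intensity / blob.sum())
        if spec.poisson_noise:
            # shot noise at acquisition, before optical/projection smoothing
            scale = spec.noise_scale
            frame = rng.poisson(frame * scale).astype(float) / scale
        if spec.psf_sigma > 0:
            frame = gaussian_filter(frame, spec.psf_sigma)
        for mask in masks:
            # restore the exact per-nucleus budget after PSF bleed
            s = frame[mask].sum()
            if s > 0:
                factor = spec.total_intensity / s
                if not spec.conserve_total:
                    factor *= 0.8 + 0.4 * rng.random()
                frame[mask] *= factor
        stack[t] = frame
    return stack, labels, truth


# --------------------------------------------------------------------------
# writers
# --------------------------------------------------------------------------

def write_movie(stack, labels, out_dir, pixel_size_nm: float = 100.0) -> None:
    """Write a movie as multi-page TIFF plus a label-mask TIFF and sidecar YAML."""
    import tifffile
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "movie.tif", stack.astype(np.float32))
    tifffile.imwrite(out / "masks.tif", labels.astype(np.uint16))
    with open(out / "movie.yaml", "w") as fh:
        yaml.safe_dump(
            {"pixel_size_nm": float(pixel_size_nm), "n_frames": int(stack.shape[0])}, fh
        )


def write_genome(genome: GenomeModel, out_dir, config: GenomeConfig | None = None,
                 seed: int | None = None) -> None:
    """Write annotations as BED6/TSV, the truth table as TSV, and config YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config is not None:
        import yaml
        from dataclasses import asdict

        payload = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()}
        if seed is not None:
            payload["seed"] = seed
        with open(out / "generator.yaml", "w") as fh:
            yaml.safe_dump(payload, fh)
    with open(out / "chrom.sizes", "w") as fh:
        for c, s in genome.chrom_sizes.items():
            fh.write(f"{c}\t{s}\n")
    tss = genome.tss.copy()
    tss_bed = pd.DataFrame(
        {
            "chrom": tss["chrom"],
            "start": tss["pos"],
            "end": tss["pos"] + 1,
            "name": tss["tss_id"],
            "score": 0,
            "strand": tss["strand"],
        }
    )
    tss_bed.to_csv(out / "tss.bed", sep="\t", header=False, index=False)
    for name, df in {**genome.insulator_tracks, **genome.mark_tracks}.items():
        safe = name.replace("(", "").replace(")", "")
        bed = df.copy()
        bed["name"] = name
        bed["score"] = 0
        bed["strand"] = "."
        bed.to_csv(out / f"track_{safe}.bed", sep="\t", header=False, index=False)
    genome.validated_enhancers.to_csv(out / "validated_enhancers.tsv", sep="\t", index=False)
    genome.truth_peaks.to_csv(out / "truth_peaks.tsv", sep="\t", index=False)
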