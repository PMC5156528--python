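"""Ground-truth generator: determinism, invariants, and planted structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import embryoatac as ea
from embryoatac.synthetic import (
    FragmentMixtureParams,
    GenomeConfig,
    ImageSpec,
    PlacementError,
    SampleSpec,
    default_focal_trajectory,
    make_pcna_movie,
    onset_cycle,
)


class TestMakeGenome:
    def test_identical_seed_gives_identical_model(self):
        a = ea.make_genome(GenomeConfig(), seed=5)
        b = ea.make_genome(GenomeConfig(), seed=5)
        pd.testing.assert_frame_equal(a.truth_peaks, b.truth_peaks)
        pd.testing.assert_frame_equal(a.tss, b.tss)
        for k in a.insulator_tracks:
            pd.testing.assert_frame_equal(a.insulator_tracks[k], b.insulator_tracks[k])

    def test_zero_truth_peaks_still_valid(self):
        g = ea.make_genome(GenomeConfig(n_truth_peaks=0), seed=1)
        assert len(g.truth_peaks) == 0
        assert len(g.tss) > 0
        g.validate()

    def test_timing_class_proportions_within_binomial_tolerance(self):
        cfg = GenomeConfig(n_truth_peaks=100, timing_proportions=(0.31, 0.39, 0.30))
        counts = ea.make_genome(cfg, seed=2).truth_peaks["timing_class"].value_counts()
        for cls, p in zip(("NC11", "NC12", "NC13"), (0.31, 0.39, 0.30)):
            # 3 sigma binomial band around the requested proportion
            assert abs(counts.get(cls, 0) - 100 * p) <= 3 * np.sqrt(100 * p * (1 - p))

    def test_truth_peaks_nonoverlapping_and_in_bounds(self, genome):
        genome.validate()

    def test_impossible_density_raises_placement_error(self):
        cfg = GenomeConfig(chrom_sizes={"chrS": 50_000}, n_truth_peaks=200)
        with pytest.raises(PlacementError):
            ea.make_genome(cfg, seed=0)


class TestSampleSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(genotype="haploid", cycle=11),
            dict(genotype="diploid", cycle=15),
            dict(minutes_post_anaphase=-1.0),
            dict(n_fragments=0),
            dict(phase="prophase"),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        base = dict(
            genotype="diploid", cycle=12, minutes_post_anaphase=3.0,
            phase="interphase", n_fragments=10, seed=0,
        )
        base.update(kwargs)
        with pytest.raises(ValueError):
            SampleSpec(**base)


class TestSampleFragments:
    def test_bitwise_deterministic(self, genome):
        spec = SampleSpec("diploid", 12, 6.0, "interphase", 5000, seed=4)
        a = ea.sample_fragments(genome, spec)
        b = ea.sample_fragments(genome, spec)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_fragments_positive_and_within_bounds(self, nc13_sample, genome):
        lengths = nc13_sample.lengths
        assert (lengths > 0).all()
        for chrom, grp in nc13_sample.df.groupby("chrom"):
            assert grp["start"].min() >= 0
            assert grp["end"].max() <= genome.chrom_sizes[str(chrom)]

    def test_open_lengths_match_configured_exponential_ks(self, genome):
        # pure open-class library: every length is min_insert + Exp(open_scale).
        # Lengths are integer bp; seeded uniform dequantization undoes the
        # rounding so the comparison is against the continuous law itself.
        mix = FragmentMixtureParams(weights=(1.0,), nucleosomal_means=(), nucleosomal_sds=())
        spec = SampleSpec("diploid", 13, 6.0, "interphase", 100_000, seed=6)
        lengths = ea.sample_fragments(genome, spec, mix).lengths
        jitter = np.random.default_rng(60).random(lengths.size) - 0.5
        ks = stats.kstest(lengths + jitter, "expon",
                          args=(mix.min_insert, mix.open_scale)).statistic
        assert ks < 0.02

    def test_mixture_mass_fractions_recovered_from_length_histogram(self, genome):
        # posterior responsibilities under the configured component densities
        # average to the mixture weights; their sample mean recovers the
        # configured mass fractions
        mix = FragmentMixtureParams()
        spec = SampleSpec("diploid", 13, 6.0, "interphase", 100_000, seed=7)
        lengths = ea.sample_fragments(genome, spec, mix).lengths
        comp_dens = [
            mix.weights[0] * stats.expon.pdf(lengths - mix.min_insert, scale=mix.open_scale)
        ]
        for w, m, s in zip(mix.weights[1:], mix.nucleosomal_means, mix.nucleosomal_sds):
            trunc_mass = 1.0 - stats.norm.cdf(100, m, s)  # lengths resampled to >= 100 bp
            comp_dens.append(w * stats.norm.pdf(lengths, m, s) * (lengths >= 100) / trunc_mass)
        dens = np.vstack(comp_dens)
        resp = dens / dens.sum(axis=0)
        np.testing.assert_allclose(resp.mean(axis=1), mix.weights, atol=0.02)

    def test_unopened_peak_has_background_open_density(self, genome):
        # at diploid NC11, an NC13-class truth peak is not yet open
        spec = SampleSpec("diploid", 11, 6.0, "interphase", 100_000, seed=8)
        fs = ea.sample_fragments(genome, spec)
        open_fs, _ = ea.split_by_length(fs)
        df = open_fs.df
        late = genome.truth_peaks[genome.truth_peaks["timing_class"] == "NC13"]
        genome_bp = sum(genome.chrom_sizes.values())
        bg_rate = len(df) / genome_bp
        for _, pk in late.head(10).iterrows():
            n_in = int(((df["chrom"] == pk["chrom"]) & (df["start"] < pk["end"]) & (df["end"] > pk["start"])).sum())
            expected = bg_rate * (pk["end"] - pk["start"])
            assert n_in < max(6 * expected, 12)

    def test_nucleosomal_midpoints_phased_at_configured_offsets(self, genome):
        mix = FragmentMixtureParams(phasing_fraction=1.0, weights=(0.0, 1.0),
                                    nucleosomal_means=(180.0,), nucleosomal_sds=(45.0,))
        spec = SampleSpec("diploid", 13, 6.0, "interphase", 150_000, seed=9)
        fs = ea.sample_fragments(genome, spec, mix)
        plus_tss = genome.tss[genome.tss["strand"] == "+"]
        offsets = []
        mids = (fs.df["start"].to_numpy() + fs.df["end"].to_numpy()) // 2
        for _, t in plus_tss.iterrows():
            sel = (fs.df["chrom"].to_numpy() == t["chrom"]) & (np.abs(mids - t["pos"]) < 400)
            offsets.append(mids[sel] - t["pos"])
        offsets = np.concatenate(offsets)
        hist, edges = np.histogram(offsets, bins=np.arange(-400, 401, 10))
        centers = edges[:-1] + 5
        upstream_mode = centers[:40][np.argmax(hist[:40])]
        downstream_mode = centers[40:][np.argmax(hist[40:])]
        assert abs(upstream_mode - (-180)) <= 15
        assert abs(downstream_mode - 135) <= 15

    def test_metaphase_sample_keeps_only_persistent_peaks_open(self, genome):
        spec = SampleSpec("diploid", 13, 12.0, "metaphase", 100_000, seed=10)
        open_fs, _ = ea.split_by_length(ea.sample_fragments(genome, spec))
        df = open_fs.df
        truth = genome.truth_peaks

        def density(pk):
            n = int(((df["chrom"] == pk["chrom"]) & (df["start"] < pk["end"]) & (df["end"] > pk["start"])).sum())
            return n / (pk["end"] - pk["start"])

        persistent = truth[truth["metaphase_persistent"]].head(20)
        lost = truth[~truth["metaphase_persistent"]].head(20)
        d_pers = np.mean([density(pk) for _, pk in persistent.iterrows()])
        d_lost = np.mean([density(pk) for _, pk in lost.iterrows()])
        assert d_pers > 5 * d_lost


class TestMakeSeries:
    def test_haploid_nc_ratio_peaks_open_one_cycle_later(self):
        assert onset_cycle("NC12", "nc_ratio", "diploid") == 12
        assert onset_cycle("NC12", "nc_ratio", "haploid") == 13
        assert onset_cycle("NC12", "time", "haploid") == 12
        assert onset_cycle("NC13", "time", "haploid") == 13

    def test_empty_grid_gives_empty_list(self, genome):
        assert ea.make_series(genome, "diploid", [], seed=0) == []

    def test_series_deterministic_and_phases_inferred(self, genome):
        grid = [(11, 3.0), (11, 9.0), (12, 12.0)]
        a = ea.make_series(genome, "diploid", grid, seed=3, n_fragments=2000)
        b = ea.make_series(genome, "diploid", grid, seed=3, n_fragments=2000)
        assert [fs.metadata["phase"] for fs in a] == ["interphase", "metaphase", "metaphase"]
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.df, y.df)

    def test_nonmonotone_grid_rejected(self, genome):
        with pytest.raises(ValueError):
            ea.make_series(genome, "diploid", [(12, 3.0), (11, 3.0)], seed=0)


class TestMakePcnaMovie:
    def test_truth_trajectory_passthrough_and_shapes(self):
        traj = default_focal_trajectory(6)
        stack, labels, truth = make_pcna_movie(ImageSpec(n_frames=6, focal_fraction=traj), seed=1)
        np.testing.assert_array_equal(truth, traj)
        assert stack.shape == (6, 192, 192)
        assert labels.max() == 9

    def test_zero_focal_fraction_gives_uniform_nuclei(self):
        spec = ImageSpec(n_frames=1, focal_fraction=[0.0], poisson_noise=False, psf_sigma=0.0)
        stack, labels, _ = make_pcna_movie(spec, seed=2)
        for lab in range(1, 10):
            vals = stack[0][labels == lab]
            assert np.allclose(vals, vals[0])

    def test_per_nucleus_intensity_conserved_across_frames(self):
        traj = [0.0, 0.3, 0.6, 0.2]
        spec = ImageSpec(n_frames=4, n_nuclei=4, focal_fraction=traj, poisson_noise=False)
        stack, labels, _ = make_pcna_movie(spec, seed=3)
        for lab in range(1, 5):
            sums = [stack[t][labels == lab].sum() for t in range(4)]
            np.testing.assert_allclose(sums, sums[0], rtol=1e-6)

    def test_invalid_focal_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_pcna_movie(ImageSpec(n_frames=2, focal_fraction=[0.2, 1.4]), seed=0)

    def test_movie_deterministic(self):
        spec = ImageSpec(n_frames=2, n_nuclei=4, focal_fraction=[0.1, 0.4])
        a, _, _ = make_pcna_movie(spec, seed=5)
        b, _, _ = make_pcna_movie(spec, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_movie_tiff_round_trip(self, tmp_path):
        import tifffile

        from embryoatac.synthetic import write_movie

        spec = ImageSpec(n_frames=2, n_nuclei=4, focal_fraction=[0.1, 0.4])
        stack, labels, _ = make_pcna_movie(spec, seed=6)
        write_movie(stack, labels, tmp_path)
        back = tifffile.imread(tmp_path / "movie.tif")
        np.testing.assert_allclose(back, stack.astype(np.float32))
        masks = tifffile.imread(tmp_path / "masks.tif")
        np.testing.assert_array_equal(masks, labels)


def test_write_genome_emits_annotations_and_config(tmp_path, genome):
    from embryoatac.synthetic import write_genome

    write_genome(genome, tmp_path, config=ea.GenomeConfig(), seed=3)
    assert (tmp_path / "tss.bed").exists()
    assert (tmp_path / "truth_peaks.tsv").exists()
    assert (tmp_path / "generator.yaml").exists()
    import yaml

    cfg = yaml.safe_load((tmp_path / "generator.yaml").read_text())
    assert cfg["seed"] == 3 and cfg["n_truth_peaks"] == 200
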