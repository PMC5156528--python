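"""Dyad calling, nucleosome modeling, NFR geometry, and recovery latency."""

import numpy as np
import pandas as pd
import pytest

import embryoatac as ea
from embryoatac.fragments import FragmentSet
from embryoatac.nucleosome import DyadParams, compute_nfr, recovery_latency


def _fs(records):
    return FragmentSet(pd.DataFrame(records, columns=["chrom", "start", "end"]), {}, True)


def _region(start=0, end=2500, rid="r0", chrom="chrT"):
    return pd.DataFrame(
        {"region_id": [rid], "chrom": [chrom], "start": [start], "end": [end], "clipped": [False]}
    )


class TestPrepareRegions:
    def test_window_centered_on_summit(self):
        peaks = pd.DataFrame({"chrom": ["chrT"], "start": [4900], "end": [5100],
                              "score": [0.9], "summit": [5000]})
        regions = ea.prepare_regions(peaks, {"chrT": 100_000})
        assert (regions.iloc[0]["start"], regions.iloc[0]["end"]) == (3750, 6250)
        assert not regions.iloc[0]["clipped"]

    def test_window_clipped_at_chromosome_edge_and_flagged(self):
        peaks = pd.DataFrame({"chrom": ["chrT"], "start": [50], "end": [150],
                              "score": [0.9], "summit": [100]})
        regions = ea.prepare_regions(peaks, {"chrT": 10_000})
        assert regions.iloc[0]["start"] == 0
        assert regions.iloc[0]["clipped"]

    def test_one_region_per_peak_even_when_overlapping(self):
        peaks = pd.DataFrame({"chrom": "chrT", "start": [1000, 1500], "end": [1200, 1700],
                              "score": [0.9, 0.9], "summit": [1100, 1600]})
        assert len(ea.prepare_regions(peaks, {"chrT": 100_000})) == 2


class TestCallDyads:
    def test_point_mass_gives_one_dyad_at_the_mode(self):
        fs = _fs([("chrT", 500 - 74, 500 + 74)] * 200)
        calls = ea.call_dyads(fs, _region())
        assert len(calls) == 1
        assert abs(calls.iloc[0]["dyad"] - 500) <= 1

    def test_close_dyads_merge_under_separation_rule(self):
        recs = [("chrT", 500 - 74, 500 + 74)] * 150 + [("chrT", 600 - 74, 600 + 74)] * 140
        calls = ea.call_dyads(_fs(recs), _region())
        assert len(calls) == 1  # 100 bp apart < 120 bp minimum separation

    def test_well_separated_dyads_both_called_and_far_apart(self):
        recs = [("chrT", 500 - 74, 500 + 74)] * 150 + [("chrT", 820 - 74, 820 + 74)] * 150
        calls = ea.call_dyads(_fs(recs), _region())
        assert len(calls) == 2
        assert np.diff(np.sort(calls["dyad"]))[0] >= 120

    def test_empty_region_yields_no_calls(self):
        calls = ea.call_dyads(_fs([]), _region())
        assert calls.empty

    def test_non_nucleosomal_lengths_ignored(self):
        recs = [("chrT", 480, 520)] * 100  # 40 bp, below the mononucleosome band
        assert ea.call_dyads(_fs(recs), _region()).empty


class TestModelNucleosomes:
    def test_dyad_widened_to_147_left_biased(self):
        calls = pd.DataFrame({"region_id": ["r0"], "chrom": ["chrT"], "dyad": [1000], "occupancy": [1.0]})
        nucs = ea.model_nucleosomes(calls)
        assert (nucs.iloc[0]["start"], nucs.iloc[0]["end"]) == (927, 1074)

    def test_width_always_147(self):
        rng = np.random.default_rng(1)
        calls = pd.DataFrame({"region_id": "r0", "chrom": "chrT",
                              "dyad": rng.integers(100, 10_000, 50), "occupancy": 1.0})
        nucs = ea.model_nucleosomes(calls)
        assert ((nucs["end"] - nucs["start"]) == 147).all()

    def test_empty_input_empty_output(self):
        calls = pd.DataFrame(columns=["region_id", "chrom", "dyad", "occupancy"])
        assert ea.model_nucleosomes(calls).empty


class TestComputeNfr:
    def test_canonical_positions_give_168_bp_nfr(self):
        rec = compute_nfr(10_000, "+", np.array([10_000 - 180, 10_000 + 135]))
        assert not rec["omitted"]
        assert rec["nfr_size"] == 315 - 147 == 168

    def test_missing_upstream_dyad_records_omission(self):
        rec = compute_nfr(10_000, "+", np.array([10_000 + 135]))
        assert rec["omitted"] and "-1" in rec["reason"]

    def test_minus_strand_mirrors_vantage_and_dyads(self):
        rec = compute_nfr(10_000, "-", np.array([10_000 + 180, 10_000 - 135]))
        assert rec["vantage"] == 10_025
        assert rec["minus1_dyad"] == 10_180 and rec["plus1_dyad"] == 9_865
        assert rec["nfr_size"] == 168

    def test_strand_symmetry_under_coordinate_mirroring(self):
        rng = np.random.default_rng(2)
        L = 100_000
        for _ in range(20):
            tss = int(rng.integers(2000, L - 2000))
            dyads = tss + rng.choice(np.arange(-900, 900), size=6, replace=False)
            fwd = compute_nfr(tss, "+", dyads)
            mirrored = compute_nfr(L - tss, "-", L - dyads)
            assert fwd["omitted"] == mirrored["omitted"]
            if not fwd["omitted"]:
                assert fwd["nfr_size"] == mirrored["nfr_size"]

    def test_dyads_closer_than_wrap_give_negative_size(self):
        rec = compute_nfr(1000, "+", np.array([1000 - 80, 1000 + 40]))
        assert rec["nfr_size"] == 120 - 147 == -27

    def test_batch_compute_nfrs_includes_omissions(self):
        tss = pd.DataFrame({"tss_id": ["a", "b"], "chrom": "chrT", "pos": [5000, 50_000],
                            "strand": ["+", "+"]})
        calls = pd.DataFrame({"region_id": "r", "chrom": "chrT",
                              "dyad": [4820, 5135], "occupancy": 1.0})
        out = ea.compute_nfrs(tss, calls)
        assert not out.iloc[0]["omitted"]
        assert out.iloc[1]["omitted"]


class TestOccupancyMatrix:
    def test_single_dyad_paints_its_147_box(self):
        tss = pd.DataFrame({"tss_id": ["p"], "chrom": "chrT", "pos": [10_000], "strand": ["+"]})
        calls = pd.DataFrame({"region_id": "r", "chrom": "chrT",
                              "dyad": [10_000 - 180, 10_000 + 135], "occupancy": [2.0, 2.0]})
        mats, order, profiles = ea.occupancy_matrix(tss, {0: calls})
        row = mats[0][0]
        # +1 box spans offsets [135-73, 135+74) at occupancy 2
        assert row[400 + 135] == 2.0
        assert row[400 + 135 + 80] == 0.0

    def test_flank_normalized_flanks_average_to_one(self, genome, haploid_run):
        series, _, _ = haploid_run
        _, nuc = ea.split_by_length(ea.pool(series, by={"cycle": 13}))
        tss = genome.tss.head(40)
        regions = pd.DataFrame({"region_id": tss["tss_id"], "chrom": tss["chrom"],
                                "start": tss["pos"] - 1250, "end": tss["pos"] + 1250,
                                "clipped": False})
        calls = ea.call_dyads(nuc, regions)
        mats, order, profiles = ea.occupancy_matrix(tss, {0: calls})
        col = profiles[profiles["timepoint"] == 0]
        flanks = pd.concat([col.head(200), col.tail(200)])["flank_normalized"]
        assert flanks.mean() == pytest.approx(1.0)

    def test_early_s_disruption_raises_tss_occupancy(self, genome):
        # +3 min into NC11 vs metaphase of NC11: encroachment onto the NFR
        mix = ea.FragmentMixtureParams()
        tss = genome.tss.head(60)
        regions = pd.DataFrame({"region_id": tss["tss_id"], "chrom": tss["chrom"],
                                "start": tss["pos"] - 1250, "end": tss["pos"] + 1250,
                                "clipped": False})
        calls = {}
        for tp, (minutes, phase) in enumerate([(3.0, "interphase"), (9.0, "metaphase")]):
            spec = ea.SampleSpec("diploid", 11, minutes, phase, 150_000, seed=40 + tp)
            _, nuc = ea.split_by_length(ea.sample_fragments(genome, spec, mix))
            calls[tp] = ea.call_dyads(nuc, regions)
        mats, order, profiles = ea.occupancy_matrix(tss, calls)
        tss_zone = (profiles["offset"] > -40) & (profiles["offset"] < 40)
        early = profiles[(profiles["timepoint"] == 0) & tss_zone]["flank_normalized"].mean()
        meta = profiles[(profiles["timepoint"] == 1) & tss_zone]["flank_normalized"].mean()
        assert early > meta


class TestNfrDynamics:
    def test_single_group_mean_normalizes_to_zero(self):
        rng = np.random.default_rng(3)
        tbl = pd.DataFrame({
            "tss_id": np.repeat([f"p{i}" for i in range(10)], 3),
            "timepoint": np.tile([0, 1, 2], 10),
            "group": "only",
            "nfr_size": rng.normal(170, 15, 30),
        })
        out = ea.nfr_dynamics(tbl, n_perm=200, n_boot=200)
        weighted = (out["median_norm_size"] * out["n"]).sum() / out["n"].sum()
        assert abs(weighted) < 10  # deviations centred near zero

    def test_identical_groups_null_behavior(self):
        rng = np.random.default_rng(4)
        base = rng.normal(170, 10, 60)
        tbl = pd.DataFrame({
            "tss_id": [f"p{i}" for i in range(120)],
            "timepoint": 0,
            "group": ["a"] * 60 + ["b"] * 60,
            "nfr_size": np.concatenate([base, rng.normal(170, 10, 60)]),
        })
        out = ea.nfr_dynamics(tbl, n_perm=500, n_boot=500, seed=5)
        row = out[(out["group"] == "a")].iloc[0]
        assert row["ci_low"] < 0 < row["ci_high"]

    def test_small_groups_suppress_statistics(self):
        tbl = pd.DataFrame({
            "tss_id": ["a", "b", "c", "d"],
            "timepoint": 0,
            "group": ["g1", "g1", "g2", "g2"],
            "nfr_size": [150.0, 160.0, 170.0, 180.0],
        })
        out = ea.nfr_dynamics(tbl, n_perm=100, n_boot=100)
        assert out["p_value"].isna().all()

    def test_planted_early_s_shrinkage_detected(self):
        # the susceptible group's NFRs shrink at the early-S timepoint but
        # match the resistant group later; mean-normalized within group, the
        # difference appears only at the disrupted timepoint
        rng = np.random.default_rng(6)
        n = 80
        rows = []
        for i in range(n):
            rows.append(("a_susceptible", f"s{i}", 0, rng.normal(140, 12)))
            rows.append(("a_susceptible", f"s{i}", 1, rng.normal(170, 12)))
            rows.append(("b_resistant", f"r{i}", 0, rng.normal(165, 12)))
            rows.append(("b_resistant", f"r{i}", 1, rng.normal(170, 12)))
        tbl = pd.DataFrame(rows, columns=["group", "tss_id", "timepoint", "nfr_size"])
        out = ea.nfr_dynamics(tbl, n_perm=2000, n_boot=500, seed=7)
        early = out[(out["timepoint"] == 0) & (out["group"] == "a_susceptible")].iloc[0]
        late = out[(out["timepoint"] == 1) & (out["group"] == "a_susceptible")].iloc[0]
        assert early["p_value"] < 0.01       # shrinkage at the disrupted timepoint
        assert late["p_value"] > 0.05        # no difference later
        assert early["ci_high"] < 0          # CI of (susceptible - resistant) below 0


class TestRecoveryLatency:
    def test_series_already_recovered_has_first_timepoint_latency(self):
        out = recovery_latency([3, 6, 9], [[5.0, 5.5, 6.0]], [4.0])
        assert out.iloc[0]["latency"] == 3.0
        assert not out.iloc[0]["censored"]

    def test_linear_rise_crossing_matches_analytic_solution(self):
        # y = 1 + t/3 crosses ref=3 at t = 6 exactly; spline through a line is the line
        times = [0, 3, 6, 9]
        vals = [1 + t / 3 for t in times]
        out = recovery_latency(times, [vals], [3.0], grid_step=0.1)
        assert out.iloc[0]["latency"] == pytest.approx(6.0, abs=0.1)

    def test_flat_series_below_reference_is_censored(self):
        out = recovery_latency([3, 6, 9], [[1.0, 1.0, 1.0]], [2.0])
        assert out.iloc[0]["censored"]
        assert np.isnan(out.iloc[0]["latency"])

    def test_latency_nondecreasing_in_reference(self):
        rng = np.random.default_rng(8)
        times = np.array([0, 3, 6, 9, 12], dtype=float)
        vals = np.cumsum(rng.random(5)) + 1.0
        lats = []
        for ref in [1.0, 1.5, 2.0, 2.5, 3.0]:
            out = recovery_latency(times, [vals], [ref])
            lats.append(out.iloc[0]["latency"] if not out.iloc[0]["censored"] else np.inf)
        assert all(a <= b + 1e-9 for a, b in zip(lats, lats[1:]))

    def test_log2_fold_change_last_over_first(self):
        out = recovery_latency([0, 3, 6], [[2.0, 3.0, 8.0]], [100.0])
        assert out.iloc[0]["log2_fc"] == pytest.approx(2.0)

    def test_two_timepoints_fall_back_to_raw_grid(self):
        out = recovery_latency([3, 6], [[1.0, 5.0]], [4.0])
        assert out.iloc[0]["latency"] == 6.0
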