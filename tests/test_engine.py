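"""IPI engine: calibrated defaults, scoring pipeline, PR adjustment, streams."""

import numpy as np
import pytest

from ipindex.engine import (
    AgeMode,
    CalibrationConfig,
    VitalSample,
    VitalStream,
    apply_pr_adjustment,
    compute_ipi,
    compute_ipi_batch,
    compute_ipi_stream,
    default_config,
    default_partitions,
    default_rulebase,
    grid_extrema,
    score,
)
from ipindex.errors import ConfigurationError
from ipindex.synthetic import ScenarioSpec, EpisodeSpec, generate

ALL_MODES = list(AgeMode)


class TestDefaults:
    def test_spo2_calibration_anchors(self):
        spo2 = default_partitions(AgeMode.ADULT)["spo2"]
        assert spo2["N"].grade(98.0) == 1.0
        assert spo2["L"].grade(85.0) == 1.0

    def test_rr_calibration_anchors(self):
        rr = default_partitions(AgeMode.ADULT)["rr"]
        assert rr["N"].grade(12.0) == 1.0
        assert rr["VL"].grade(0.0) == 1.0

    def test_pediatric_rr_plateau_above_adult(self):
        adult = default_partitions(AgeMode.ADULT)["rr"]["N"]
        ped = default_partitions(AgeMode.PED_1_3)["rr"]["N"]
        assert ped.b > adult.b and ped.c > adult.c

    def test_etco2_spo2_shared_across_modes(self):
        ref = default_partitions(AgeMode.ADULT)
        for mode in ALL_MODES:
            parts = default_partitions(mode)
            assert parts["etco2"] == ref["etco2"]
            assert parts["spo2"] == ref["spo2"]

    def test_rulebase_anchor_cells(self):
        rb = default_rulebase()
        assert rb.consequent("N", "N", "N") == 10
        assert rb.consequent("VH", "VH", "N") == 2  # published sample rule
        assert rb.consequent("N", "L", "N") == 8    # worked-example step 1
        assert rb.consequent("VL", "VL", "N") == 1

    def test_rulebase_full_coverage(self):
        labels = {(r, c, s) for rule in default_rulebase().rules()
                  for r, c, s in [(dict(rule.antecedent)["rr"],
                                   dict(rule.antecedent)["etco2"],
                                   dict(rule.antecedent)["spo2"])]}
        assert len(labels) == 5 * 5 * 3

    def test_rulebase_rejects_spo2_inversion(self):
        good = default_rulebase()
        mats = dict(good.matrices)
        # raise one low-SpO2 cell above its normal-SpO2 counterpart
        low = [list(r) for r in mats["L"]]
        low[0][0] = 5  # base (RR VL, PetCO2 VL) cell is 1
        bad = tuple(tuple(r) for r in low)
        with pytest.raises(ConfigurationError):
            type(good)(matrices=(("L", bad), ("N", mats["N"]), ("H", mats["H"])))

    def test_config_roundtrip_and_checksum(self, adult_cfg, tmp_path):
        data = adult_cfg.to_dict()
        again = CalibrationConfig.from_dict(data)
        assert again.checksum() == adult_cfg.checksum()
        assert again.to_dict() == data


class TestComputeIPI:
    def test_worked_example_normal_spo2(self):
        # RR 12 / PetCO2 26 with normal SpO2 and PR scores 8
        assert score(etco2=26, rr=12, spo2=98, pr=70) == 8

    def test_worked_example_desaturated(self):
        # the same ventilation pattern at SpO2 90 % drops the score to 5
        assert score(etco2=26, rr=12, spo2=90, pr=70) == 5

    def test_all_normal_scores_ten(self):
        assert score(etco2=38, rr=14, spo2=98, pr=72) == 10

    def test_worst_case_scores_one(self):
        assert score(etco2=0, rr=0, spo2=70, pr=130) == 1

    def test_result_fields_consistent(self):
        res = compute_ipi(VitalSample(0, etco2=26, rr=12, spo2=98, pr=70))
        assert res.valid and res.ipi == 8
        assert res.ipi_raw == pytest.approx(8.0, abs=1e-9)
        assert not res.pr_adjustment_applied
        assert res.grades["etco2"]["L"] == 1.0

    def test_invalid_channel_yields_gap_not_exception(self):
        res = compute_ipi(VitalSample(0, etco2=float("nan"), rr=12,
                                      spo2=98, pr=70))
        assert not res.valid and res.ipi is None
        assert "etco2" in res.reason
        res2 = compute_ipi(VitalSample(0, 38, 14, 98, 72,
                                       valid=(True, False, True, True)))
        assert not res2.valid and "rr" in res2.reason

    def test_range_invariant_random_inputs_all_modes(self, rng):
        n = 25_000  # x4 modes = 1e5 samples
        etco2 = rng.uniform(0, 150, n)
        rr = rng.uniform(0, 90, n)
        spo2 = rng.uniform(0, 100, n)
        pr = rng.uniform(0, 250, n)
        for mode in ALL_MODES:
            res = compute_ipi_batch(etco2, rr, spo2, pr, mode=mode)
            assert res["ipi"].min() >= 1 and res["ipi"].max() <= 10
            assert res["ipi_raw"].min() >= 1.0 - 1e-9
            assert res["ipi_raw"].max() <= 10.0 + 1e-9

    def test_batch_matches_scalar_pipeline(self, rng):
        etco2 = rng.uniform(0, 100, 300)
        rr = rng.uniform(0, 60, 300)
        spo2 = rng.uniform(70, 100, 300)
        pr = rng.uniform(30, 180, 300)
        batch = compute_ipi_batch(etco2, rr, spo2, pr)
        for i in range(300):
            res = compute_ipi(VitalSample(i, etco2[i], rr[i], spo2[i], pr[i]))
            assert res.ipi_raw == pytest.approx(batch["ipi_raw"][i], abs=1e-9)
            assert res.ipi == batch["ipi"][i]

    def test_continuity_under_tiny_perturbation(self, rng):
        base = np.column_stack([
            rng.uniform(1, 99, 200), rng.uniform(1, 59, 200),
            rng.uniform(70.5, 99.4, 200), rng.uniform(31, 179, 200)])
        r0 = compute_ipi_batch(*base.T)
        out0 = r0["ipi_raw"] - r0["pr_adjustment"]
        for j in range(4):
            pert = base.copy()
            pert[:, j] += 1e-6
            r1 = compute_ipi_batch(*pert.T)
            out1 = r1["ipi_raw"] - r1["pr_adjustment"]
            assert np.abs(out1 - out0).max() < 1e-3


class TestPRAdjustment:
    def crisp_grades(self, pr_lab, etco2_lab, rr_lab):
        def one_hot(labels, lab):
            return {l: 1.0 if l == lab else 0.0 for l in labels}
        five = ("VL", "L", "N", "H", "VH")
        return {"pr": one_hot(("L", "N", "H"), pr_lab),
                "etco2": one_hot(five, etco2_lab),
                "rr": one_hot(five, rr_lab)}

    def test_low_pr_high_co2_high_rr_subtracts_one(self):
        grades = self.crisp_grades("L", "H", "VH")
        assert apply_pr_adjustment(4.0, grades) == pytest.approx(3.0)

    def test_high_pr_low_co2_low_rr_subtracts_one(self):
        grades = self.crisp_grades("H", "VL", "L")
        assert apply_pr_adjustment(7.0, grades) == pytest.approx(6.0)

    def test_floor_at_scale_bottom(self):
        grades = self.crisp_grades("L", "VH", "H")
        assert apply_pr_adjustment(1.2, grades) == pytest.approx(1.0)

    def test_normal_pr_leaves_score_unchanged(self):
        grades = self.crisp_grades("N", "H", "VH")
        assert apply_pr_adjustment(4.0, grades) == pytest.approx(4.0)

    def test_mismatched_direction_not_triggered(self):
        # low PR with LOW PetCO2/RR is not a secondary-rule pattern
        grades = self.crisp_grades("L", "VL", "VL")
        assert apply_pr_adjustment(4.0, grades) == pytest.approx(4.0)

    def test_end_to_end_subtraction(self):
        # tachypneic hypercapnia (VH/VH base cell = 2) with bradycardia
        assert score(etco2=80, rr=40, spo2=98, pr=30) == 1
        assert score(etco2=80, rr=40, spo2=98, pr=70) == 2


class TestMonotonicity:
    def crisp_values(self, cfg, channel):
        part = cfg.partition(channel)
        return {lab: (mf.b + mf.c) / 2.0 for lab, mf in part.functions}

    def test_spo2_sweep_non_increasing_at_crisp_cells(self, adult_cfg):
        """Fig-2 behaviour: decreasing SpO2 never raises the score, checked
        for every crisp RR x PetCO2 x PR label combination."""
        spo2 = np.arange(100.0, 69.9, -0.5)
        rr_vals = self.crisp_values(adult_cfg, "rr").values()
        co2_vals = self.crisp_values(adult_cfg, "etco2").values()
        pr_vals = self.crisp_values(adult_cfg, "pr").values()
        for rr in rr_vals:
            for co2 in co2_vals:
                for pr in pr_vals:
                    res = compute_ipi_batch(co2, rr, spo2, pr)
                    out = res["ipi_raw"] - res["pr_adjustment"]
                    assert (np.diff(out) <= 1e-9).all()

    def test_spo2_sweep_deviation_bounded_off_plateau(self, rng):
        """With RR/PetCO2 mid-transition, min/max aggregation admits a small
        non-monotone wiggle; it stays below 0.05 IPI points."""
        spo2 = np.arange(100.0, 69.9, -0.5)
        worst = 0.0
        for _ in range(200):
            res = compute_ipi_batch(rng.uniform(0, 100), rng.uniform(0, 60),
                                    spo2, rng.uniform(30, 180))
            out = res["ipi_raw"] - res["pr_adjustment"]
            worst = max(worst, float(np.diff(out).max()))
        assert worst < 0.05

    def test_single_parameter_departure_never_raises_score(self):
        normal = dict(etco2=38.0, rr=14.0, spo2=98.0, pr=72.0)
        sweeps = {
            "etco2": (np.arange(38, -0.01, -0.25), np.arange(38, 100.01, 0.25)),
            "rr": (np.arange(14, -0.01, -0.25), np.arange(14, 60.01, 0.25)),
            "spo2": (np.arange(98, 69.99, -0.25), np.arange(98, 100.01, 0.25)),
            "pr": (np.arange(72, 29.99, -0.25), np.arange(72, 180.01, 0.25)),
        }
        for ch, directions in sweeps.items():
            for grid in directions:
                kw = {k: np.full_like(grid, v) for k, v in normal.items()}
                kw[ch] = grid
                res = compute_ipi_batch(kw["etco2"], kw["rr"], kw["spo2"], kw["pr"])
                out = res["ipi_raw"] - res["pr_adjustment"]
                assert out[0] == pytest.approx(10.0, abs=1e-9)
                assert (np.diff(out) <= 1e-9).all(), ch

    def test_mode_consistency_at_etco2_spo2_extremes(self):
        for vals in [dict(etco2=0, rr=0, spo2=70, pr=70),
                     dict(etco2=80, rr=0, spo2=85, pr=70)]:
            grades = {
                mode: {ch: default_partitions(mode)[ch].fuzzify(v)
                       for ch, v in vals.items() if ch in ("etco2", "spo2")}
                for mode in ALL_MODES}
            ref = grades[AgeMode.ADULT]
            assert all(g == ref for g in grades.values())


class TestStream:
    def test_constant_normal_stream_scores_ten(self):
        n = 600
        stream = VitalStream(
            t=np.arange(n), etco2=np.full(n, 38.0), rr=np.full(n, 14.0),
            spo2=np.full(n, 98.0), pr=np.full(n, 72.0))
        trace = compute_ipi_stream(stream)
        assert len(trace) == n
        assert (trace.ipi == 10).all()

    def test_apneic_plateau_scores_one(self):
        spec = ScenarioSpec(duration_s=200, episodes=(
            EpisodeSpec("apnea", 100, 40),), seed=3)
        stream, _ = generate(spec)
        trace = compute_ipi_stream(stream)
        assert (trace.ipi[100:140] == 1).all()

    def test_stream_equals_per_sample_map(self):
        spec = ScenarioSpec(duration_s=120, episodes=(
            EpisodeSpec("hypoxia", 40, 20, ramp_s=5),), seed=42)
        stream, _ = generate(spec)
        trace = compute_ipi_stream(stream)
        for i in range(len(stream)):
            res = compute_ipi(stream.sample(i), config=default_config())
            assert res.ipi == int(trace.ipi[i])
            assert res.ipi_raw == pytest.approx(trace.ipi_raw[i], abs=1e-9)

    def test_statelessness_split_concat(self):
        spec = ScenarioSpec(duration_s=300, episodes=(
            EpisodeSpec("apnea", 100, 35),), seed=9)
        stream, _ = generate(spec)
        whole = compute_ipi_stream(stream)
        parts = [compute_ipi_stream(stream.slice(0, 120)),
                 compute_ipi_stream(stream.slice(120, 300))]
        joined = np.concatenate([p.ipi for p in parts])
        np.testing.assert_array_equal(whole.ipi, joined)

    def test_invalid_seconds_become_gaps(self):
        n = 100
        valid = np.ones((n, 4), dtype=bool)
        valid[10:20, 2] = False
        stream = VitalStream(
            t=np.arange(n), etco2=np.full(n, 38.0), rr=np.full(n, 14.0),
            spo2=np.full(n, 98.0), pr=np.full(n, 72.0), valid=valid)
        trace = compute_ipi_stream(stream)
        assert np.isnan(trace.ipi[10:20]).all()
        assert (~trace.valid[10:20]).all() and trace.valid[20:].all()

    def test_empty_stream(self):
        stream = VitalStream(t=np.array([]), etco2=np.array([]),
                             rr=np.array([]), spo2=np.array([]),
                             pr=np.array([]))
        assert len(compute_ipi_stream(stream)) == 0


class TestGridExtrema:
    def test_decomposed_grid_matches_direct_product(self, rng):
        etco2 = np.arange(0.0, 101.0, 20.0)
        rr = np.arange(0.0, 61.0, 12.0)
        spo2 = np.arange(70.0, 101.0, 6.0)
        pr = np.arange(30.0, 181.0, 30.0)
        imin, imax, n = grid_extrema(etco2=etco2, rr=rr, spo2=spo2, pr=pr)
        E, R, S, P = np.meshgrid(etco2, rr, spo2, pr, indexing="ij")
        direct = compute_ipi_batch(E.ravel(), R.ravel(), S.ravel(), P.ravel())
        assert n == E.size
        assert imin == direct["ipi"].min()
        assert imax == direct["ipi"].max()
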