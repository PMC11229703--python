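"""Conversion-anchored trajectory models and the anchor-correlation filter."""

import numpy as np
import pandas as pd
import pytest

import msmark as mk


@pytest.fixture
def conv_data():
    cfg = mk.SimConfig(n_proteins=12, n_peak_proteins=2, n_drift_proteins=2, seed=21)
    npx, meta, truth = mk.simulate_converter_trajectories(cfg)
    conv = meta.loc[meta["converter"]]
    t = mk.time_from_conversion(conv)
    return cfg, npx, meta, truth, t


class TestTimeFromConversion:
    def test_anchor_sample_is_zero_and_sp(self, conv_data):
        _, _, meta, _, t = conv_data
        anchored = t.loc[t["t"] == 0.0]
        assert len(anchored) > 0
        assert (anchored["status"] == "SP").all()

    def test_one_year_before_anchor(self):
        meta = pd.DataFrame({
            "sample_id": ["a", "b"], "individual_id": ["i1", "i1"],
            "subtype": ["RR", "SP"], "converter": [True, True],
            "sample_date": pd.to_datetime(["2015-01-01", "2016-01-01"]),
        })
        # 365 calendar days before the anchor -> -365/365.25 years
        t = mk.time_from_conversion(meta)
        assert t.loc["a", "t"] == pytest.approx(-365 / 365.25)
        assert t.loc["a", "status"] == "RR"
        assert t.loc["b", "t"] == 0.0

    def test_nonconverter_rejected(self):
        meta = pd.DataFrame({
            "sample_id": ["a"], "individual_id": ["i1"], "subtype": ["RR"],
            "converter": [False], "sample_date": pd.to_datetime(["2015-01-01"]),
        })
        with pytest.raises(ValueError, match="non-converter"):
            mk.time_from_conversion(meta)

    def test_converter_without_sp_sample_rejected(self):
        meta = pd.DataFrame({
            "sample_id": ["a", "b"], "individual_id": ["i1", "i1"],
            "subtype": ["RR", "RR"], "converter": [True, True],
            "sample_date": pd.to_datetime(["2015-01-01", "2015-06-01"]),
        })
        with pytest.raises(ValueError, match="no SP"):
            mk.time_from_conversion(meta)

    def test_translation_invariance(self, conv_data):
        _, _, meta, _, t = conv_data
        conv = meta.loc[meta["converter"]].copy()
        conv["sample_date"] = conv["sample_date"] + pd.Timedelta(days=1000)
        t_shift = mk.time_from_conversion(conv)
        pd.testing.assert_frame_equal(t, t_shift)


class TestConversionAssoc:
    def test_flat_trajectories_no_hits(self, rng):
        cfg = mk.SimConfig(n_proteins=30, n_peak_proteins=0, n_drift_proteins=0,
                           seed=22)
        npx, meta, _, = mk.simulate_converter_trajectories(cfg)
        conv = meta.loc[meta["converter"]]
        t = mk.time_from_conversion(conv)
        sub = npx.subset(samples=list(t.index))
        res = mk.conversion_assoc(sub, meta, t)
        assert (res["fdr"] < 0.1).sum() <= 1

    def test_planted_slope_detected_with_sign(self, rng):
        """+0.5 NPX/year drift in converters, sigma 0.5, 12 x 7 visits."""
        cfg = mk.SimConfig(n_proteins=10, n_peak_proteins=0, n_drift_proteins=4,
                           drift_slope=0.5, seed=23)
        npx, meta, truth = mk.simulate_converter_trajectories(cfg)
        conv = meta.loc[meta["converter"]]
        t = mk.time_from_conversion(conv)
        res = mk.conversion_assoc(npx.subset(samples=list(t.index)), meta, t)
        res = res.set_index("analyte_id")
        drifted = truth.loc[truth["role"] == "drift", "protein_id"]
        assert (res.loc[drifted, "fdr"] < 0.1).all()
        assert (res.loc[drifted, "direction"] == "increasing").all()


class TestInteractionModel:
    def test_tent_recovery_peak_calls(self, conv_data):
        _, npx, meta, truth, t = conv_data
        sub = npx.subset(samples=list(t.index))
        res = mk.interaction_model(sub, meta, t)
        called = set(res.loc[res["peak"], "analyte_id"])
        planted = set(truth.loc[truth["role"] == "peak", "protein_id"])
        # every planted peak recovered; at most one chance false call in a
        # single replicate (the aggregate precision bound lives in the
        # acceptance suite)
        assert planted <= called
        assert len(called - planted) <= 1

    def test_monotone_trend_gives_null_interaction(self, rng):
        cfg = mk.SimConfig(n_proteins=25, n_peak_proteins=0, n_drift_proteins=25,
                           drift_slope=0.4, seed=24)
        npx, meta, _ = mk.simulate_converter_trajectories(cfg)
        conv = meta.loc[meta["converter"]]
        t = mk.time_from_conversion(conv)
        res = mk.interaction_model(npx.subset(samples=list(t.index)), meta, t)
        assert (res["fdr"] < 0.1).sum() == 0
        assert not res["peak"].any()

    def test_slope_estimates_cover_truth(self):
        cfg = mk.SimConfig(n_proteins=8, n_peak_proteins=8, n_drift_proteins=0,
                           seed=25)
        npx, meta, truth = mk.simulate_converter_trajectories(cfg)
        conv = meta.loc[meta["converter"]]
        t = mk.time_from_conversion(conv)
        res = mk.interaction_model(npx.subset(samples=list(t.index)), meta, t)
        # tent with amplitude a and width w has pre-slope a/w, post-slope -a/w
        exp_slope = cfg.peak_amplitude / cfg.peak_width_years
        ok_pre = (np.abs(res["pre_slope"] - exp_slope) < 2.5 * res["se"]).mean()
        ok_post = (np.abs(res["post_slope"] + exp_slope) < 2.5 * res["se"]).mean()
        assert ok_pre >= 0.85 and ok_post >= 0.85


class TestNonconverterControl:
    def test_drift_flagged_peak_protein_clean(self, conv_data):
        _, npx, meta, truth, _ = conv_data
        res = mk.nonconverter_control(npx, meta).set_index("analyte_id")
        drift = truth.loc[truth["role"] == "drift", "protein_id"]
        peak = truth.loc[truth["role"] == "peak", "protein_id"]
        assert (res.loc[drift, "p"] < 0.05).all()
        assert (~res.loc[drift, "conversion_specific"]).all()
        assert (res.loc[peak, "p"] >= 0.05).all()

    def test_flat_markers_near_uniform_p(self):
        cfg = mk.SimConfig(n_proteins=40, n_peak_proteins=0, n_drift_proteins=0,
                           seed=26)
        npx, meta, _ = mk.simulate_converter_trajectories(cfg)
        res = mk.nonconverter_control(npx, meta)
        assert 0.25 < res["p"].median() < 0.75


class TestAnchorCorrelationFilter:
    def test_affine_candidate_kept_with_r_one(self, rng):
        samples = [f"s{i}" for i in range(20)]
        anchor = pd.Series(rng.normal(0, 1, 20), index=samples)
        x = pd.DataFrame({"miR-150": 2 * anchor + 3,
                          "miR-neg": -0.9 * anchor + rng.normal(0, 0.2, 20),
                          "miR-null": rng.normal(0, 1, 20)}).T
        out = mk.anchor_correlation_filter(x, anchor, list(x.index)).set_index("mirna_id")
        assert out.loc["miR-150", "r"] == pytest.approx(1.0)
        assert out.loc["miR-150", "kept"]
        assert out.loc["miR-neg", "kept"] and out.loc["miR-neg", "r"] < 0

    def test_null_kept_fraction_near_alpha(self, rng):
        samples = [f"s{i}" for i in range(40)]
        anchor = pd.Series(rng.normal(0, 1, 40), index=samples)
        x = pd.DataFrame(rng.normal(0, 1, (300, 40)), columns=samples,
                         index=[f"m{i}" for i in range(300)])
        out = mk.anchor_correlation_filter(x, anchor, list(x.index))
        assert out["kept"].mean() < 0.12

    def test_zero_variance_excluded(self, rng):
        samples = [f"s{i}" for i in range(10)]
        anchor = pd.Series(rng.normal(0, 1, 10), index=samples)
        x = pd.DataFrame({"m0": np.ones(10)}, index=samples).T
        out = mk.anchor_correlation_filter(x, anchor, ["m0"])
        assert len(out) == 0
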