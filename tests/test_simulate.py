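"""Determinism, truth tables and null behaviour of the synthetic generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import msmark as mk


class TestDeterminism:
    def test_proteomics_bitwise_reproducible(self, small_cfg):
        a = mk.simulate_proteomics(small_cfg)
        b = mk.simulate_proteomics(small_cfg)
        pd.testing.assert_frame_equal(a[0].values, b[0].values)
        pd.testing.assert_frame_equal(a[1].values, b[1].values)
        pd.testing.assert_frame_equal(a[3], b[3])

    def test_trajectories_reproducible(self, small_cfg):
        a, _, _ = mk.simulate_converter_trajectories(small_cfg)
        b, _, _ = mk.simulate_converter_trajectories(small_cfg)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_mirna_counts_reproducible(self, small_cfg):
        sigs = mk.extract_signatures(mk.load_toy_atlas(), k=10)
        _, meta, _ = mk.simulate_converter_trajectories(small_cfg)
        a, _ = mk.simulate_mirna_counts(small_cfg, meta, sigs)
        b, _ = mk.simulate_mirna_counts(small_cfg, meta, sigs)
        pd.testing.assert_frame_equal(a.counts, b.counts)


class TestProteomicsStructure:
    def test_null_config_gives_uniform_p(self):
        """No effects, no offsets: per-protein two-group t-test P-values are
        uniform (KS test)."""
        cfg = mk.SimConfig(
            cohort1={"control": 25, "RR": 25, "SP": 0, "PP": 0},
            cohort2={"control": 0, "RR": 0, "SP": 0, "PP": 0},
            n_proteins=200, n_diff_proteins=0, run_offset_max=0.0,
            age_slope=0.0, sex_effect=0.0, lod_quantile=1e-6, seed=31,
        )
        run1, _, meta, _ = mk.simulate_proteomics(cfg)
        grp = meta.set_index("sample_id").loc[run1.sample_ids, "subtype"]
        serum = run1.values
        ps = []
        for p in run1.protein_ids:
            a = serum.loc[(grp == "control").to_numpy(), p].dropna()
            b = serum.loc[(grp == "RR").to_numpy(), p].dropna()
            ps.append(sps.ttest_ind(a, b, equal_var=False).pvalue)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_bridging_difference_matches_offset(self):
        """A 1.0-NPX run offset on every protein appears as a mean bridging
        difference of -1.0 within 3*sigma/sqrt(11)."""
        cfg = mk.SimConfig(n_proteins=30, run_offset_max=0.0, lod_quantile=1e-6,
                           seed=32)
        rng_off = 1.0
        run1, run2, meta, truth = mk.simulate_proteomics(cfg)
        # re-simulate with constant offset by shifting run2 manually
        run2.values += rng_off
        bridging = truth.attrs["bridging_ids"]
        d = (run1.values.loc[bridging] - run2.values.loc[bridging]).mean()
        tol = 3 * np.sqrt(2) * cfg.protein_sigma / np.sqrt(len(bridging))
        assert (np.abs(d + rng_off) < tol).mean() > 0.95

    def test_truth_table_flags_match_config(self, small_cfg):
        _, _, _, truth = mk.simulate_proteomics(small_cfg)
        n_eff = ((truth["ms_effect"] != 0) | (truth["stage_effect"] != 0)).sum()
        assert n_eff == small_cfg.n_diff_proteins
        assert len(truth.attrs["bridging_ids"]) == small_cfg.n_bridging

    def test_generated_data_roundtrips_through_io(self, small_cfg, tmp_path):
        run1, _, meta, _ = mk.simulate_proteomics(small_cfg)
        mk.write_npx(run1, tmp_path / "npx.csv", tmp_path / "lod.csv")
        back = mk.read_npx(tmp_path / "npx.csv", tmp_path / "lod.csv")
        pd.testing.assert_frame_equal(back.values, run1.values)
        mk.write_meta(meta, tmp_path / "meta.csv")
        assert len(mk.read_meta(tmp_path / "meta.csv")) == len(meta)


class TestMirnaStructure:
    def test_null_lambda_balanced_signature_expression(self, small_cfg):
        """With zero loading strength the signature sets sit at the same
        normalized level as background (relative gap small)."""
        from conftest import make_meta
        cfg = mk.SimConfig(**{**small_cfg.__dict__, "signature_strength": 0.0,
                              "compartment_loading": 0.0, "lambda_noise_sd": 0.0,
                              "n_diff_mirnas": 0})
        sigs = mk.extract_signatures(mk.load_toy_atlas(), k=10)
        meta = make_meta(30, subtypes=("RR",), seed=33)
        counts, truth = mk.simulate_mirna_counts(cfg, meta, sigs)
        x = mk.transform_log(counts, mk.size_factors(counts))
        q = truth["mirna"].set_index("mirna_id")["baseline_mean"]
        # compare observed to expected baseline on the log scale
        resid = x.mean(axis=1) - np.log2(q + 1)
        in_sig = truth["mirna"].set_index("mirna_id")["is_signature"]
        gap = resid[in_sig.to_numpy()].mean() - resid[(~in_sig).to_numpy()].mean()
        assert abs(gap) < 0.2

    def test_poisson_limit_equal_totals(self):
        """Tiny dispersion, unit size factors: column totals agree within
        3*sqrt(total)."""
        cfg = mk.SimConfig(n_mirnas=150, nb_dispersion=1e-8, libsize_log_sd=0.0,
                           n_diff_mirnas=0, signature_strength=0.0,
                           compartment_loading=0.0, lambda_noise_sd=0.0,
                           batch_log2fc_sd=0.0, seed=34)
        from conftest import make_meta
        meta = make_meta(12, subtypes=("RR",), seed=34)
        counts, _ = mk.simulate_mirna_counts(cfg, meta, {})
        totals = counts.counts.sum(axis=0).to_numpy(dtype=float)
        assert (np.abs(totals - totals.mean()) < 3 * np.sqrt(totals.mean())).mean() >= 0.9

    def test_missing_signature_mirna_rejected(self, small_cfg):
        from conftest import make_meta
        meta = make_meta(4, subtypes=("RR",), seed=35)
        cfg = mk.SimConfig(**{**small_cfg.__dict__, "n_mirnas": 5})
        with pytest.raises(ValueError, match="n_mirnas|absent"):
            mk.simulate_mirna_counts(cfg, meta, {"A": [f"x{i}" for i in range(99)]})

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            mk.SimConfig(nb_dispersion=-1.0).validate()
        with pytest.raises(ValueError):
            mk.SimConfig(anchor_visit=0).validate()


class TestTrajectoryStructure:
    def test_anchor_visit_is_time_zero(self, small_cfg):
        _, meta, _ = mk.simulate_converter_trajectories(small_cfg)
        conv = meta.loc[meta["converter"]]
        t = mk.time_from_conversion(conv)
        anchored = conv.loc[conv["sample_date"] == conv["conversion_date"], "sample_id"]
        assert (t.loc[anchored, "t"] == 0.0).all()

    def test_zero_amplitude_gives_no_interaction_hits(self):
        cfg = mk.SimConfig(n_proteins=40, peak_amplitude=0.0, n_drift_proteins=0,
                           seed=36)
        npx, meta, _ = mk.simulate_converter_trajectories(cfg)
        conv = meta.loc[meta["converter"]]
        t = mk.time_from_conversion(conv)
        res = mk.interaction_model(npx.subset(samples=list(t.index)), meta, t)
        assert (res["fdr"] < 0.1).sum() == 0
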