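"""Cross-sectional group tests, covariate adjustment, compartment comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import msmark as mk

from conftest import make_meta


def _npx_from(values: pd.DataFrame) -> mk.NpxMatrix:
    return mk.NpxMatrix(
        values,
        pd.Series(-100.0, index=values.columns),
        pd.Series("run1", index=values.index),
    )


class TestGroupTest:
    def test_type_one_error_near_nominal(self, rng):
        """Identical group means over 400 simulated null proteins: the
        fraction with P < 0.05 stays near 0.05."""
        n = 50
        meta = make_meta(2 * n, subtypes=("control", "RR"), seed=1)
        values = pd.DataFrame(rng.normal(5, 1, (2 * n, 400)),
                              index=meta["sample_id"],
                              columns=[f"P{i}" for i in range(400)])
        res = mk.group_test(_npx_from(values), meta, ["control", "RR"])
        frac = (res["p"] < 0.05).mean()
        assert 0.02 < frac < 0.08

    def test_planted_shift_detected_at_fdr(self, rng):
        """1.0-NPX shift with sigma 0.5, n=30/30 is essentially always found."""
        meta = make_meta(60, subtypes=("control", "RR"), seed=2)
        is_rr = (meta["subtype"] == "RR").to_numpy(dtype=float)
        values = pd.DataFrame(rng.normal(5, 0.5, (60, 50)),
                              index=meta["sample_id"],
                              columns=[f"P{i}" for i in range(50)])
        shifted = [f"P{i}" for i in range(10)]
        for p in shifted:
            values[p] += is_rr * 1.0
        res = mk.group_test(_npx_from(values), meta, ["control", "RR"])
        hits = set(res.loc[res["fdr"] < 0.1, "analyte_id"])
        recall = len(hits & set(shifted)) / len(shifted)
        assert recall >= 0.95
        assert res.set_index("analyte_id").loc[shifted, "beta"].mean() == pytest.approx(1.0, abs=0.15)

    def test_kway_uses_anova(self, rng):
        meta = make_meta(45, subtypes=("RR", "SP", "PP"), seed=3)
        values = pd.DataFrame(rng.normal(0, 1, (45, 5)), index=meta["sample_id"],
                              columns=list("ABCDE"))
        res = mk.group_test(_npx_from(values), meta, ["RR", "SP", "PP"])
        assert res["beta"].isna().all()  # no single effect size for k-way
        assert ((res["p"] >= 0) & (res["p"] <= 1)).all()

    def test_fdr_dominates_p(self, rng):
        meta = make_meta(30, subtypes=("control", "RR"), seed=4)
        values = pd.DataFrame(rng.normal(0, 1, (30, 25)), index=meta["sample_id"],
                              columns=[f"P{i}" for i in range(25)])
        res = mk.group_test(_npx_from(values), meta, ["control", "RR"])
        assert (res["fdr"] >= res["p"] - 1e-12).all()


class TestAdjustedTest:
    def test_matches_pooled_t_without_covariates(self, rng):
        meta = make_meta(40, subtypes=("control", "RR"), seed=5)
        values = pd.DataFrame(rng.normal(5, 1, (40, 8)), index=meta["sample_id"],
                              columns=[f"P{i}" for i in range(8)])
        res = mk.adjusted_test(_npx_from(values), meta, ("control", "RR"), covars=[])
        grp = meta.set_index("sample_id")["subtype"]
        for _, row in res.iterrows():
            a = values.loc[(grp == "control").to_numpy(), row["analyte_id"]]
            b = values.loc[(grp == "RR").to_numpy(), row["analyte_id"]]
            p_pooled = sps.ttest_ind(a, b, equal_var=True).pvalue
            assert row["p"] == pytest.approx(p_pooled, rel=1e-6)

    def test_confounded_null_recovered_by_adjustment(self, rng):
        """Group tracks age and age drives the protein, but the group effect
        is zero: adjusted beta stays near zero, inside its 2-SE band."""
        n = 120
        meta = make_meta(n, subtypes=("control",), seed=6)
        meta.loc[meta.index[n // 2:], "subtype"] = "RR"
        meta["age"] = np.where(meta["subtype"] == "RR",
                               rng.normal(60, 5, n), rng.normal(40, 5, n))
        values = pd.DataFrame(
            (0.1 * meta["age"].to_numpy())[:, None] + rng.normal(0, 0.5, (n, 40)),
            index=meta["sample_id"], columns=[f"P{i}" for i in range(40)])
        res = mk.adjusted_test(_npx_from(values), meta, ("control", "RR"),
                               covars=["age"])
        cover = ((res["beta"].abs()) < 2 * res["se"]).mean()
        assert cover >= 0.9
        assert abs(res["beta"].mean()) < 0.1

    def test_beta_coverage_of_truth(self, rng):
        """Planted group effects are recovered within +/- 2 SE for >=95% of
        simulated analytes."""
        meta = make_meta(80, subtypes=("control", "RR"), seed=7)
        is_rr = (meta["subtype"] == "RR").to_numpy(dtype=float)
        truth = rng.normal(0, 1, 100)
        noise = rng.normal(0, 0.5, (80, 100))
        values = pd.DataFrame(is_rr[:, None] * truth[None, :] + noise,
                              index=meta["sample_id"],
                              columns=[f"P{i}" for i in range(100)])
        res = mk.adjusted_test(_npx_from(values), meta, ("control", "RR"))
        res = res.set_index("analyte_id")
        err = res["beta"] - pd.Series(truth, index=[f"P{i}" for i in range(100)])
        assert ((err.abs() < 2 * res["se"]).mean()) >= 0.95


class TestCompartments:
    def _paired(self, rng, n=20, n_prot=6):
        inds = [f"i{j}" for j in range(n)]
        prot = [f"P{j}" for j in range(n_prot)]
        serum = pd.DataFrame(rng.normal(6, 1, (n, n_prot)),
                             index=[f"{i}_ser" for i in inds], columns=prot)
        csf = pd.DataFrame(rng.normal(5, 1, (n, n_prot)),
                           index=[f"{i}_csf" for i in inds], columns=prot)
        pairing = pd.DataFrame({"individual_id": inds,
                                "serum_sample": serum.index,
                                "csf_sample": csf.index})
        return serum, csf, pairing

    def test_constant_offset_all_higher_in_serum(self, rng):
        serum, csf, pairing = self._paired(rng)
        serum = csf.set_axis(serum.index, axis=0) + 1.0
        res = mk.compartment_compare(_npx_from(serum), _npx_from(csf), pairing)
        assert (res["direction"] == "higher_in_serum").all()
        np.testing.assert_allclose(res["beta"], 1.0)

    def test_independent_noise_low_correlation(self, rng):
        serum, csf, pairing = self._paired(rng, n=50)
        res = mk.compartment_compare(_npx_from(serum), _npx_from(csf), pairing)
        assert (res["r_serum_csf"].abs() < 2 / np.sqrt(50) * 2).mean() >= 0.8

    def test_shared_latent_factor_yields_high_r(self, rng):
        serum, csf, pairing = self._paired(rng, n=40)
        latent = rng.normal(0, 3, 40)  # ICC ~ 0.9 for P0 only
        serum["P0"] = 6 + latent + rng.normal(0, 1, 40)
        csf["P0"] = 5 + latent + rng.normal(0, 1, 40)
        res = mk.compartment_compare(_npx_from(serum), _npx_from(csf), pairing)
        res = res.set_index("analyte_id")
        assert res.loc["P0", "r_serum_csf"] > 0.7
        assert (res.drop("P0")["r_serum_csf"].abs() < 0.45).all()

    def test_profile_correlations_identical_matrices(self, rng):
        serum, csf, pairing = self._paired(rng)
        csf = serum.set_axis(csf.index, axis=0)
        out = mk.profile_correlations(_npx_from(serum), _npx_from(csf), pairing)
        assert out["median_within_individual"] == pytest.approx(1.0)

    def test_compartment_specific_profiles(self, rng):
        """Distinct per-compartment mean profiles: samples of the same type
        correlate more than the two compartments of one individual."""
        n, n_prot = 25, 40
        prof_serum = rng.normal(0, 2, n_prot)
        prof_csf = rng.normal(0, 2, n_prot)
        serum = pd.DataFrame(prof_serum + rng.normal(0, 0.5, (n, n_prot)),
                             index=[f"i{j}_ser" for j in range(n)],
                             columns=[f"P{j}" for j in range(n_prot)])
        csf = pd.DataFrame(prof_csf + rng.normal(0, 0.5, (n, n_prot)),
                           index=[f"i{j}_csf" for j in range(n)],
                           columns=[f"P{j}" for j in range(n_prot)])
        pairing = pd.DataFrame({"individual_id": [f"i{j}" for j in range(n)],
                                "serum_sample": serum.index,
                                "csf_sample": csf.index})
        out = mk.profile_correlations(_npx_from(serum), _npx_from(csf), pairing)
        assert out["median_within_type"] > out["median_within_individual"]
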