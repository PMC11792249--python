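"""Twin-pair statistics: response concordance, GEE behaviour in the
independence limit and under the null, LOD censoring and PK summaries."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from twinsteroid.config import AnalysisConfig
from twinsteroid.errors import DomainError, UndefinedStatisticError
from twinsteroid.twinstats import (
    censor_lod,
    fit_gee,
    pair_response_concordance,
    summarize_pk,
    twin_abs_difference,
)


class TestConcordance:
    def test_forced_count_two_of_three(self, toy_pheno):
        res = pair_response_concordance(toy_pheno)
        assert (res.n_pairs, res.n_concordant) == (3, 2)
        assert res.fraction == pytest.approx(2 / 3)

    def test_control_pairs_excluded(self, toy_pheno):
        res = pair_response_concordance(toy_pheno)
        assert res.n_pairs == 3  # E4 (control) not counted

    def test_all_concordant_gives_one(self, toy_pheno):
        df = toy_pheno.copy()
        df.loc[df.arm != "CONTROL", "responder"] = "yes"
        assert pair_response_concordance(df).fraction == 1.0

    def test_invariant_to_within_pair_ordering(self, toy_pheno):
        shuffled = toy_pheno.sample(frac=1.0, random_state=4)
        assert pair_response_concordance(shuffled) == \
            pair_response_concordance(toy_pheno)

    def test_eleven_of_twentyone_prints_52_percent(self):
        rows = []
        for i in range(21):
            conc = i < 11
            for j, status in enumerate(["yes", "yes" if conc else "no"]):
                rows.append({"fetus_id": f"E{i}.{j}", "ewe_id": f"E{i}",
                             "arm": "CS1", "responder": status})
        res = pair_response_concordance(pd.DataFrame(rows))
        assert res.percent == pytest.approx(100 * 11 / 21)
        assert round(res.percent) == 52


def _gee_frame(n, rng, cluster_size=2, beta_sex=0.0, pair_sd=0.0):
    """Simulated treated cohort for GEE tests."""
    n_clusters = n // cluster_size
    rows = []
    for c in range(n_clusters):
        u = rng.normal(0, pair_sd)
        sexes = rng.choice(["M", "F"], size=cluster_size)
        tt = "".join(sorted(sexes, reverse=True)).replace("FM", "MF")
        for k in range(cluster_size):
            eta = beta_sex * (sexes[k] == "F") + u
            rows.append(
                {"fetus_id": f"C{c}.{k}", "ewe_id": f"C{c}",
                 "arm": rng.choice(["CS1", "CS2"]), "sex": sexes[k],
                 "twin_type": tt if cluster_size == 2 else "MM",
                 "delivery_order": k + 1,
                 "responder": "yes" if rng.random() < expit(eta) else "no"}
            )
    return pd.DataFrame(rows)


class TestGee:
    def test_singleton_clusters_reduce_to_ordinary_logistic(self):
        rng = np.random.default_rng(11)
        df = _gee_frame(150, rng, cluster_size=1, beta_sex=1.0)
        gee = fit_gee(df)
        y = (df["responder"] == "yes").astype(float).to_numpy()
        X = np.column_stack(
            [np.ones(len(df)),
             (df["arm"] == "CS2").astype(float),
             (df["sex"] == "F").astype(float),
             (df["twin_type"] == "MF").astype(float),
             (df["twin_type"] == "FF").astype(float),
             (df["delivery_order"] == 1).astype(float)]
        )
        keep = [i for i in range(X.shape[1]) if np.ptp(X[:, i]) > 0 or i == 0]
        logit = sm.Logit(y, X[:, keep]).fit(disp=0, tol=1e-12)
        np.testing.assert_allclose(
            np.log(gee["odds_ratio"].to_numpy()), logit.params, atol=1e-6
        )

    def test_ci_brackets_odds_ratio(self, small_cohort):
        from twinsteroid.physiology import classify_cohort

        classified, _ = classify_cohort(small_cohort.fetuses)
        gee = fit_gee(classified)
        assert (gee["ci_low"] <= gee["odds_ratio"]).all()
        assert (gee["odds_ratio"] <= gee["ci_high"]).all()
        assert (gee["ci_low"] > 0).all()

    def test_null_type_one_error_near_nominal(self):
        """Empirical size of the sex term at alpha=0.05 over 200 null cohorts
        with genuine within-pair correlation."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_reps = 200
        for _ in range(n_reps):
            df = _gee_frame(200, rng, beta_sex=0.0, pair_sd=1.0)
            gee = fit_gee(df, covariates=("sex[female vs male]",))
            p = gee.loc[gee["term"] == "sex[female vs male]", "p_value"]
            if len(p) and float(p.iloc[0]) < 0.05:
                rejections += 1
        rate = rejections / n_reps
        half_width = 3 * np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rate - 0.05) < half_width + 0.01


class TestCensoring:
    @pytest.mark.parametrize(
        "value, lod, detected",
        [(0.4, 0.5, False), (0.9, 1.0, False), (0.5, 0.5, True), (2.0, 0.5, True)],
    )
    def test_lod_rule(self, value, lod, detected):
        out = censor_lod(value, lod)
        assert (not np.isnan(out)) is detected
        if detected:
            assert out == value

    def test_negative_concentration_rejected(self):
        with pytest.raises(DomainError):
            censor_lod(-0.1, 0.5)


class TestTwinDiff:
    def _pairs(self, values):
        rows = []
        for i, (a, b) in enumerate(values):
            rows += [{"ewe_id": f"E{i}", "x": a}, {"ewe_id": f"E{i}", "x": b}]
        return pd.DataFrame(rows)

    def test_hand_arithmetic(self):
        res = twin_abs_difference(self._pairs([(2.0, 2.5), (1.0, 1.2)]), "x")
        assert res.mean_abs_diff == pytest.approx(0.35)
        assert res.n_pairs_used == 2

    def test_identical_twin_values_give_zero(self):
        assert twin_abs_difference(self._pairs([(3.0, 3.0)]), "x").mean_abs_diff == 0.0

    def test_below_lod_pair_excluded_changes_n_not_formula(self):
        res = twin_abs_difference(
            self._pairs([(2.0, 2.5), (np.nan, 1.2)]), "x"
        )
        assert res.mean_abs_diff == pytest.approx(0.5)
        assert (res.n_pairs_used, res.n_pairs_excluded) == (1, 1)

    def test_no_eligible_pairs_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            twin_abs_difference(self._pairs([(np.nan, 1.0)]), "x")


class TestPkSummary:
    def test_control_compartments_all_below_lod(self, small_cohort, analysis_cfg):
        pk = summarize_pk(small_cohort.fetuses, analysis_cfg, ewes=small_cohort.ewes)
        ctrl = pk[pk["group"] == "CONTROL"]
        assert (ctrl["n_below_lod"] == ctrl["n"]).all()
        assert ctrl["mean"].isna().all()

    def test_means_match_direct_computation_on_detected_values(self, small_cohort):
        pk = summarize_pk(small_cohort.fetuses)
        cs1 = small_cohort.fetuses.query("arm == 'CS1'")["plasma_beta"].dropna()
        row = pk[(pk["group"] == "CS1") & (pk["compartment"] == "fetal plasma")]
        assert row["mean"].iloc[0] == pytest.approx(cs1.mean())
        assert row["sd"].iloc[0] == pytest.approx(cs1.std(ddof=1))

    def test_half_lod_substitution_lowers_mean(self, small_cohort):
        fetuses = small_cohort.fetuses.copy()
        # force one below-LOD value into a treated arm
        idx = fetuses.index[fetuses["arm"] == "CS1"][0]
        fetuses.loc[idx, "plasma_beta"] = np.nan
        base = summarize_pk(fetuses)
        sub = summarize_pk(
            fetuses, dataclasses.replace(AnalysisConfig(), half_lod_substitution=True)
        )
        pick = lambda df: df[
            (df["group"] == "CS1") & (df["compartment"] == "fetal plasma")
        ]["mean"].iloc[0]
        assert pick(sub) < pick(base)
        assert pick(sub) == pytest.approx(
            (fetuses.query("arm=='CS1'")["plasma_beta"].fillna(0.25)).mean()
        )
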