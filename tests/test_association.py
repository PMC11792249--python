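"""Two-stage association tests against independent oracles: scipy's
contingency test for the chi-square stage, direct likelihood
maximisation for the logistic stage, and planted-effect recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from oracles import chisq_oracle, logistic_mle_oracle
from twinsteroid.association import (
    build_allele_tables,
    chisq_allele_test,
    logistic_allele_test,
    shortlist,
    stage1_scan,
    two_stage_scan,
)
from twinsteroid.config import AnalysisConfig
from twinsteroid.errors import UndefinedStatisticError


def _calls(genotypes: dict[str, str], snp="S1"):
    rows = []
    for sample, g in genotypes.items():
        rows.append((sample, snp, g[0], g[1], 0.9))
    return pd.DataFrame(
        rows, columns=["sample_id", "snp_id", "allele1", "allele2", "gc_score"]
    )


def _pheno(status: dict[str, str]):
    return pd.DataFrame(
        {"fetus_id": list(status), "responder": list(status.values())}
    )


class TestAlleleTables:
    def test_hand_counted_example(self):
        # responders {AA, AB}, non-responder {BB} -> A: (3, 0); B: (1, 2)
        calls = _calls({"r1": "AA", "r2": "AB", "n1": "BB"})
        tables = build_allele_tables(
            calls, _pheno({"r1": "yes", "r2": "yes", "n1": "no"})
        )
        row = tables.loc["S1"]
        assert (row.a_resp, row.a_non, row.b_resp, row.b_non) == (3, 0, 1, 2)

    def test_missing_calls_contribute_nothing(self):
        calls = _calls({"r1": "--", "n1": "--"})
        tables = build_allele_tables(calls, _pheno({"r1": "yes", "n1": "no"}))
        assert tables.loc["S1"].sum() == 0

    def test_column_sums_are_twice_called_class_sizes(self, small_cohort):
        from twinsteroid.physiology import classify_cohort

        classified, _ = classify_cohort(small_cohort.fetuses)
        treated = classified[classified["responder"].isin(["yes", "no"])]
        with pytest.warns(UserWarning, match="lack a phenotype"):  # controls genotyped
            tables = build_allele_tables(small_cohort.genotype_calls, treated)
        n_yes = (treated["responder"] == "yes").sum()
        n_no = (treated["responder"] == "no").sum()
        assert ((tables["a_resp"] + tables["b_resp"]) == 2 * n_yes).all()
        assert ((tables["a_non"] + tables["b_non"]) == 2 * n_no).all()

    def test_orphan_genotype_warns(self):
        calls = _calls({"r1": "AA", "ghost": "AB"})
        with pytest.warns(UserWarning, match="lack a phenotype"):
            build_allele_tables(calls, _pheno({"r1": "yes", "x": "no"}))


class TestChisq:
    def test_closed_form_example(self):
        stat, p = chisq_allele_test([[30, 10], [10, 30]])
        assert stat == pytest.approx(20.0, rel=1e-12)
        assert p == pytest.approx(7.744e-6, rel=1e-3)

    def test_no_association_gives_zero(self):
        stat, p = chisq_allele_test([[20, 20], [30, 30]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_invariant_under_label_swap(self):
        a = chisq_allele_test([[30, 10], [10, 30]])
        b = chisq_allele_test([[30, 10], [10, 30]][::-1])
        c = chisq_allele_test([[10, 30], [30, 10]])
        assert a[0] == pytest.approx(b[0]) == pytest.approx(c[0])

    def test_zero_marginal_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            chisq_allele_test([[0, 0], [10, 30]])

    def test_matches_scipy_oracle_on_random_tables(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            t = rng.integers(1, 60, size=(2, 2))
            stat, p = chisq_allele_test(t)
            stat_o, p_o = chisq_oracle(t)
            assert stat == pytest.approx(stat_o, abs=1e-10)
            assert p == pytest.approx(p_o, abs=1e-10)


class TestShortlist:
    @pytest.mark.parametrize("p, kept", [(0.008, True), (0.01, False), (0.011, False)])
    def test_strict_threshold(self, p, kept):
        df = pd.DataFrame({"snp_id": ["S1"], "chisq_stat": [1.0], "chisq_p": [p]})
        assert (len(shortlist(df)) == 1) is kept

    def test_nan_p_never_shortlisted(self):
        df = pd.DataFrame({"snp_id": ["S1"], "chisq_stat": [np.nan],
                           "chisq_p": [np.nan]})
        assert shortlist(df).empty


class TestLogistic:
    def test_binary_dosage_toy_equals_log_odds_ratio(self):
        """8/10 responders in carriers vs 2/10: MLE slope = ln 16."""
        dosage = np.repeat([1, 0], 10)
        y = np.r_[np.ones(8), np.zeros(2), np.ones(2), np.zeros(8)]
        fit = logistic_allele_test(dosage, y)
        assert fit.beta == pytest.approx(math.log(16.0), abs=1e-4)
        assert not fit.separated

    def test_matches_direct_likelihood_maximisation(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, size=200).astype(float)
        sex = rng.integers(0, 2, size=200).astype(float)
        y = (rng.random(200) < expit(-0.4 + 0.8 * d + 0.5 * sex)).astype(float)
        fit = logistic_allele_test(d, y, sex)
        X = np.column_stack([np.ones(200), d, sex])
        beta_oracle = logistic_mle_oracle(X, y)
        assert fit.beta == pytest.approx(beta_oracle[1], abs=1e-4)

    def test_null_slope_shrinks_at_large_n(self):
        rng = np.random.default_rng(6)
        d = rng.integers(0, 3, size=4000).astype(float)
        y = (rng.random(4000) < 0.5).astype(float)
        fit = logistic_allele_test(d, y)
        assert abs(fit.beta) < 0.1 and fit.p > 0.01

    def test_complete_separation_is_flagged_not_raised(self):
        d = np.repeat([0, 2], 10).astype(float)
        y = np.repeat([0, 1], 10).astype(float)
        fit = logistic_allele_test(d, y)
        assert fit.separated and np.isnan(fit.p)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            logistic_allele_test([1, 1, 1], [0, 1, 0])
        with pytest.raises(UndefinedStatisticError):
            logistic_allele_test([0, 1, 2], [1, 1, 1])

    def test_planted_slope_recovered_with_small_bias(self):
        """Mean MLE over 50 seeded replicates within 10% of the planted slope."""
        beta_true = 1.0
        estimates = []
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            d = rng.binomial(2, 0.3, size=1000).astype(float)
            y = (rng.random(1000) < expit(-0.5 + beta_true * d)).astype(float)
            estimates.append(logistic_allele_test(d, y).beta)
        assert np.mean(estimates) == pytest.approx(beta_true, rel=0.10)


class TestTwoStage:
    def _planted_dataset(self, seed=0, n=400, beta=1.6):
        rng = np.random.default_rng(seed)
        n_snps = 50
        D = rng.binomial(2, 0.3, size=(n, n_snps)).astype(np.int8)
        sex = rng.integers(0, 2, size=n)
        eta = -1.0 + beta * D[:, 7] + 0.4 * sex
        resp = rng.random(n) < expit(eta)
        ids = np.array([f"S{i}" for i in range(n_snps)])
        return D, ids, resp, sex

    def test_planted_positive_effect_labelled_responder_for_b_allele(self):
        D, ids, resp, sex = self._planted_dataset()
        out = two_stage_scan(D, ids, resp, sex)
        rows = out[(out.snp_id == "S7")]
        assert not rows.empty
        assert rows.loc[rows.allele == "B", "direction"].iloc[0] == "responder"
        assert rows.loc[rows.allele == "A", "direction"].iloc[0] == "non-responder"
        b = rows.loc[rows.allele == "B", "lr_beta"].iloc[0]
        a = rows.loc[rows.allele == "A", "lr_beta"].iloc[0]
        assert a == pytest.approx(-b)

    def test_both_allele_rows_emitted_per_shortlisted_snp(self):
        D, ids, resp, sex = self._planted_dataset()
        out = two_stage_scan(D, ids, resp, sex)
        assert (out.groupby("snp_id")["allele"].nunique() == 2).all()

    def test_stage1_scan_flags_zero_marginal_as_nan(self):
        D = np.zeros((20, 2), dtype=np.int8)  # SNP 0 monomorphic
        D[:, 1] = np.tile([0, 1], 10)
        resp = np.tile([True, False], 10)
        out = stage1_scan(D, np.array(["S0", "S1"]), resp)
        assert np.isnan(out.loc[0, "chisq_p"])
        assert np.isfinite(out.loc[1, "chisq_p"])

    def test_lr_and_wald_tests_agree_at_moderate_n(self):
        D, ids, resp, sex = self._planted_dataset(seed=3)
        wald = two_stage_scan(D, ids, resp, sex, config=AnalysisConfig())
        lr = two_stage_scan(D, ids, resp, sex,
                            config=AnalysisConfig(logistic_test="lr"))
        m = wald.merge(lr, on=["snp_id", "allele"], suffixes=("_w", "_lr"))
        assert np.allclose(m["lr_beta_w"], m["lr_beta_lr"])
        sig = m[m["lr_p_w"] < 0.01]
        assert (sig["lr_p_lr"] < 0.05).all()
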