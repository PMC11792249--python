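"""Pair-level response concordance, GEE prognostic modelling and
twin pharmacokinetic difference summaries.

A twin pair is response-concordant when both steroid-treated twins
carry the same responder label.  Prognostic factors of responder status
are modelled marginally with generalized estimating equations (logit
link, exchangeable working correlation within a ewe, robust sandwich
standard errors), with the two steroid arms pooled and saline controls
excluded.  Drug-level summaries respect the assay limits of detection:
below-LOD values are excluded from means (no substitution by default)
and twin absolute differences use pairs with both values detected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .config import AnalysisConfig, TREATED_ARMS
from .errors import DomainError, InsufficientDataError, UndefinedStatisticError

__all__ = [
    "ConcordanceResult",
    "TwinDiffResult",
    "pair_response_concordance",
    "fit_gee",
    "censor_lod",
    "twin_abs_difference",
    "summarize_pk",
    "GEE_TERMS",
]

log = logging.getLogger(__name__)

# Covariate coding (reference levels): treatment CS2 vs CS1; sex female
# vs male; twin type MF and FF vs MM; delivery order first vs second.
GEE_TERMS = [
    "intercept",
    "treatment[CS2 vs CS1]",
    "sex[female vs male]",
    "twin_type[MF vs MM]",
    "twin_type[FF vs MM]",
    "order[first vs second]",
]


@dataclass(frozen=True)
class ConcordanceResult:
    n_pairs: int
    n_concordant: int
    fraction: float

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


@dataclass(frozen=True)
class TwinDiffResult:
    mean_abs_diff: float
    n_pairs_used: int
    n_pairs_excluded: int


def pair_response_concordance(pheno: pd.DataFrame) -> ConcordanceResult:
    """Fraction of steroid-treated twin pairs with matching responder labels.

    ``pheno`` is a classified phenotype table (``responder`` in
    {yes, no, not-applicable}); control pairs are excluded and logged.
    Invariant to within-pair ordering.
    """
    treated = pheno[pheno["arm"].isin(TREATED_ARMS)]
    n_control_pairs = pheno.loc[~pheno["arm"].isin(TREATED_ARMS), "ewe_id"].nunique()
    if n_control_pairs:
        log.info("pair_response_concordance: excluded %d control pair(s)", n_control_pairs)
    if not treated["responder"].isin(["yes", "no"]).all():
        raise UndefinedStatisticError(
            "pair_response_concordance: treated fetuses must be classified"
        )
    per_pair = treated.groupby("ewe_id")["responder"].agg(["nunique", "size"])
    if (per_pair["size"] != 2).any():
        raise UndefinedStatisticError(
            "pair_response_concordance: every treated ewe must contribute 2 twins"
        )
    n_pairs = len(per_pair)
    if n_pairs == 0:
        raise InsufficientDataError("pair_response_concordance: no treated pairs")
    n_conc = int((per_pair["nunique"] == 1).sum())
    return ConcordanceResult(n_pairs=n_pairs, n_concordant=n_conc,
                             fraction=n_conc / n_pairs)


def _gee_design(treated: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    y = (treated["responder"] == "yes").to_numpy(dtype=float)
    cols = {
        "intercept": np.ones(len(treated)),
        "treatment[CS2 vs CS1]": (treated["arm"] == "CS2").to_numpy(dtype=float),
        "sex[female vs male]": (treated["sex"] == "F").to_numpy(dtype=float),
        "twin_type[MF vs MM]": (treated["twin_type"] == "MF").to_numpy(dtype=float),
        "twin_type[FF vs MM]": (treated["twin_type"] == "FF").to_numpy(dtype=float),
        "order[first vs second]": (treated["delivery_order"] == 1).to_numpy(dtype=float),
    }
    # drop constant columns (e.g. a single-arm cohort, or no FF pairs)
    names = [k for k in cols if k == "intercept" or np.ptp(cols[k]) > 0]
    X = np.column_stack([cols[k] for k in names])
    groups = treated["ewe_id"].to_numpy()
    return y, X, groups, names


def fit_gee(
    pheno: pd.DataFrame,
    covariates: tuple[str, ...] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """GEE of responder status on treatment, sex, twin type and order.

    Logit link, exchangeable working correlation within ewe, robust
    (sandwich) covariance.  The two steroid arms are pooled; control
    fetuses are excluded.  Single-fetus clusters are permitted (the
    model then reduces to ordinary logistic regression).  Returns one
    row per term: odds ratio, 95% CI bounds, p-value, plus a
    ``converged`` flag; non-convergence is flagged, not raised.

    ``covariates`` optionally restricts the design to a subset of
    :data:`GEE_TERMS` (the intercept is always kept).
    """
    treated = pheno[pheno["arm"].isin(TREATED_ARMS)].copy()
    if treated.empty or treated["ewe_id"].nunique() < 2:
        raise InsufficientDataError("fit_gee: need >= 2 clusters of treated fetuses")
    if "twin_type" not in treated.columns:
        sexes = treated.groupby("ewe_id")["sex"].apply(
            lambda s: "".join(sorted(s, reverse=True)).replace("FM", "MF")
        )
        treated["twin_type"] = treated["ewe_id"].map(sexes)
    y, X, groups, names = _gee_design(treated)
    if covariates is not None:
        keep = [i for i, n in enumerate(names) if n == "intercept" or n in covariates]
        X = X[:, keep]
        names = [names[i] for i in keep]

    model = sm.GEE(
        y, X, groups=groups,
        family=sm.families.Binomial(),
        cov_struct=sm.cov_struct.Exchangeable(),
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=200, ctol=1e-10)
        except Exception as exc:
            log.warning("fit_gee: did not converge (%s)", exc)
            converged = False
            res = model.fit(maxiter=1, first_dep_update=0)
    z = float(norm.ppf(1 - alpha / 2))
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    pvals = np.asarray(res.pvalues)
    return pd.DataFrame(
        {
            "term": names,
            "odds_ratio": np.exp(params),
            "ci_low": np.exp(params - z * bse),
            "ci_high": np.exp(params + z * bse),
            "p_value": pvals,
            "converged": converged,
        }
    )


def censor_lod(value: float, lod: float) -> float:
    """Apply the assay limit of detection to one concentration.

    Returns the value when detected, NaN when below the LOD.  A value
    exactly at the LOD counts as detected (the LOD is *defined as* that
    concentration).  Negative concentrations are rejected.
    """
    if lod <= 0:
        raise DomainError("censor_lod: lod must be positive")
    if value < 0:
        raise DomainError(f"censor_lod: negative concentration {value}")
    return float(value) if value >= lod else float("nan")


def twin_abs_difference(
    pheno: pd.DataFrame, variable: str, pairs: pd.DataFrame | None = None
) -> TwinDiffResult:
    """Mean absolute within-pair difference of a (possibly censored) variable.

    Pairs with any below-LOD (NaN) value are excluded from the mean and
    counted in ``n_pairs_excluded``.  Raises when no eligible pair
    remains.
    """
    grouped = pheno.groupby("ewe_id")[variable]
    sizes = grouped.size()
    if (sizes != 2).any():
        pheno = pheno[pheno["ewe_id"].isin(sizes.index[sizes == 2])]
        grouped = pheno.groupby("ewe_id")[variable]
    diffs = grouped.agg(lambda s: abs(s.iloc[0] - s.iloc[1]))
    eligible = diffs.dropna()
    n_excluded = int(len(diffs) - len(eligible))
    if eligible.empty:
        raise UndefinedStatisticError(
            f"twin_abs_difference({variable!r}): no pair with both values detected "
            f"({n_excluded} pair(s) excluded for below-LOD values)"
        )
    return TwinDiffResult(
        mean_abs_diff=float(eligible.mean()),
        n_pairs_used=int(len(eligible)),
        n_pairs_excluded=n_excluded,
    )


def summarize_pk(
    pheno: pd.DataFrame,
    config: AnalysisConfig | None = None,
    ewes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-arm betamethasone summaries mirroring the delivery PK table.

    For each arm × compartment (fetal plasma, lung tissue, and maternal
    plasma when an ewe table is supplied): n, mean and SD over detected
    values only, mean absolute twin difference (fetal compartments),
    and the below-LOD count.  With ``half_lod_substitution`` enabled in
    the config, below-LOD values enter the moments at LOD/2 instead of
    being excluded (they still count as below-LOD).
    """
    config = config or AnalysisConfig()
    rows = []

    def _summary(values: pd.Series, lod: float) -> dict:
        detected = values.dropna()
        n_below = int(values.isna().sum())
        if config.half_lod_substitution:
            detected = values.fillna(lod / 2.0)
        return {
            "n": int(len(values)),
            "n_detected": int(len(values) - n_below),
            "mean": float(detected.mean()) if len(detected) else np.nan,
            "sd": float(detected.std(ddof=1)) if len(detected) >= 2 else np.nan,
            "n_below_lod": n_below,
        }

    if ewes is not None:
        for arm, grp in ewes.groupby("arm", sort=False):
            raw = grp["maternal_plasma_beta_raw"].astype(float)
            censored = raw.where(raw >= config.lod_plasma)
            rows.append(
                {"group": arm, "compartment": "maternal plasma",
                 **_summary(censored, config.lod_plasma), "mean_abs_twin_diff": np.nan}
            )

    for arm, grp in pheno.groupby("arm", sort=False):
        for var, compartment, lod in (
            ("plasma_beta", "fetal plasma", config.lod_plasma),
            ("lung_beta", "lung tissue", config.lod_tissue),
        ):
            entry = {"group": arm, "compartment": compartment,
                     **_summary(grp[var], lod)}
            try:
                entry["mean_abs_twin_diff"] = twin_abs_difference(grp, var).mean_abs_diff
            except UndefinedStatisticError:
                entry["mean_abs_twin_diff"] = np.nan
            rows.append(entry)
    return pd.DataFrame(rows)
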