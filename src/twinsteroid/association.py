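"""Two-stage per-allele SNP association with steroid responsiveness.

Stage 1 screens every SNP with a Pearson chi-square test on the 2×2
allele-by-phenotype count table (each called fetus contributes its two
allele observations to its phenotype column) and shortlists SNPs at
p < 0.01 (strict).  Stage 2 fits, per shortlisted SNP, an additive
logistic regression of responder status on allele dosage (0/1/2 copies)
adjusting for fetal sex, and keeps terms at p < 0.05.  Each allele
passing both stages is categorized by its direction of association:
positive dosage log-odds mark a responder-associated allele, negative
mark a non-responder-associated one; the two alleles of a SNP are
mirror images under additive coding, so both rows are emitted.

No multiple-testing correction is applied beyond the staged raw-p
thresholds.  X-linked SNPs are treated as ordinary diploid calls, as
delivered by the chip format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .config import AnalysisConfig
from .errors import UndefinedStatisticError

__all__ = [
    "LogisticResult",
    "build_allele_tables",
    "chisq_allele_test",
    "stage1_scan",
    "shortlist",
    "logistic_allele_test",
    "two_stage_scan",
    "run_association",
    "ASSOC_COLUMNS",
]

ASSOC_COLUMNS = [
    "snp_id", "gene", "chromosome", "position", "effect", "allele",
    "chisq_stat", "chisq_p", "lr_beta", "lr_p", "direction",
]


@dataclass(frozen=True)
class LogisticResult:
    """One allele-dosage logistic fit: slope, p-value and health flags."""

    beta: float
    p: float
    separated: bool = False
    converged: bool = True


def _pearson_2x2(a, b, c, d):
    """Vectorised Pearson chi-square, 1 df, no continuity correction.

    Rows are alleles (A, B), columns phenotype classes (responder,
    non-responder).  Tables with a zero marginal yield NaN.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, np.nan)
    p = chi2.sf(stat, df=1)
    return stat, p


def chisq_allele_test(table) -> tuple[float, float]:
    """Pearson chi-square on one 2×2 allele-count table.

    ``table`` is array-like ``[[a_resp, a_non], [b_resp, b_non]]``.
    Raises :class:`UndefinedStatisticError` on a zero marginal (the
    scanning path skips and logs such SNPs instead).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise UndefinedStatisticError("chisq_allele_test: need a nonnegative 2x2 table")
    if t.sum() <= 0:
        raise UndefinedStatisticError("chisq_allele_test: empty table")
    stat, p = _pearson_2x2(t[0, 0], t[0, 1], t[1, 0], t[1, 1])
    if np.isnan(stat):
        raise UndefinedStatisticError("chisq_allele_test: zero marginal")
    return float(stat), float(p)


def _dosage_matrix(calls: pd.DataFrame, sample_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(samples × SNPs) allele-B dosage matrix (−1 = missing) from long calls."""
    sub = calls[calls["sample_id"].isin(sample_ids)].copy()
    sub["dosage"] = (sub["allele1"] == "B").astype(int) + (sub["allele2"] == "B").astype(int)
    sub.loc[sub["allele1"] == "-", "dosage"] = -1
    wide = sub.pivot_table(
        index="sample_id", columns="snp_id", values="dosage", aggfunc="first"
    ).reindex(sample_ids)
    wide = wide.fillna(-1)
    return wide.to_numpy(dtype=np.int8), wide.columns.to_numpy()


def build_allele_tables(calls: pd.DataFrame, phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP 2×2 allele counts from a call table and classified phenotypes.

    ``phenotypes`` must be restricted to steroid-treated fetuses with a
    ``responder`` column in {yes, no}.  Each called fetus contributes
    two allele observations to its phenotype column; missing calls
    contribute nothing.  Genotyped samples without a phenotype are
    excluded with a warning.  Returns a frame indexed by ``snp_id``
    with columns ``a_resp, a_non, b_resp, b_non``.
    """
    status = phenotypes.set_index("fetus_id")["responder"]
    if not status.isin(["yes", "no"]).all():
        raise UndefinedStatisticError(
            "build_allele_tables: phenotypes must be classified treated fetuses"
        )
    orphan = set(calls["sample_id"]) - set(status.index)
    if orphan:
        warnings.warn(
            f"build_allele_tables: {len(orphan)} genotyped sample(s) lack a "
            "phenotype and are excluded", stacklevel=2,
        )
    samples = [s for s in status.index if s in set(calls["sample_id"])]
    D, snp_ids = _dosage_matrix(calls, samples)
    resp = (status.loc[samples] == "yes").to_numpy()
    counts = _allele_counts(D, resp)
    counts.index = snp_ids
    counts.index.name = "snp_id"
    return counts


def _allele_counts(D: np.ndarray, resp: np.ndarray) -> pd.DataFrame:
    called = D >= 0
    Dc = np.where(called, D, 0)
    n_resp = called[resp].sum(axis=0)
    n_non = called[~resp].sum(axis=0)
    b_resp = Dc[resp].sum(axis=0)
    b_non = Dc[~resp].sum(axis=0)
    return pd.DataFrame(
        {
            "a_resp": 2 * n_resp - b_resp,
            "a_non": 2 * n_non - b_non,
            "b_resp": b_resp,
            "b_non": b_non,
        }
    )


def shortlist(results: pd.DataFrame, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Stage-1 retention: chisq_p strictly below the shortlist alpha."""
    config = config or AnalysisConfig()
    mask = results["chisq_p"] < config.stage1_alpha
    return results[mask.fillna(False)].copy()


def logistic_allele_test(
    dosages,
    phenotype,
    sex=None,
    test: str = "wald",
) -> LogisticResult:
    """Additive-dosage logistic fit: logit P(resp) = a + b·dosage [+ c·I(female)].

    ``dosages`` are per-fetus allele copy counts (0..2), ``phenotype``
    a binary responder indicator, ``sex`` an optional female indicator.
    Returns the dosage slope and its p-value (Wald by default,
    likelihood-ratio with ``test="lr"``).  Complete separation is
    flagged rather than raised: the result carries ``separated=True``
    and an undefined (NaN) p-value.
    """
    y = np.asarray(phenotype, dtype=float)
    d = np.asarray(dosages, dtype=float)
    cols = [np.ones_like(d), d]
    if sex is not None:
        cols.append(np.asarray(sex, dtype=float))
    X = np.column_stack(cols)
    if y.min() == y.max():
        raise UndefinedStatisticError("logistic_allele_test: one phenotype class only")
    if d.min() == d.max():
        raise UndefinedStatisticError("logistic_allele_test: no dosage variation")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:  # perfect separation or singular fit
            return LogisticResult(beta=np.nan, p=np.nan, separated=True, converged=False)
    beta = float(res.params[1])
    bse = float(res.bse[1])
    if not np.isfinite(beta) or not np.isfinite(bse) or abs(beta) > 30 or bse > 1e3:
        return LogisticResult(beta=beta, p=np.nan, separated=True,
                              converged=bool(res.mle_retvals.get("converged", False)))
    if test == "lr":
        X0 = np.delete(X, 1, axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res0 = sm.Logit(y, X0).fit(disp=0, maxiter=200)
        p = float(chi2.sf(2 * (res.llf - res0.llf), df=1))
    else:
        p = float(res.pvalues[1])
    return LogisticResult(beta=beta, p=p, separated=False,
                          converged=bool(res.mle_retvals.get("converged", True)))


def stage1_scan(
    D: np.ndarray, snp_ids: np.ndarray, responder: np.ndarray
) -> pd.DataFrame:
    """Chi-square allele screen over a dosage matrix.

    Returns one row per SNP with ``chisq_stat`` / ``chisq_p`` (NaN for
    SNPs with a zero allele-count marginal, which are never shortlisted).
    """
    responder = np.asarray(responder, dtype=bool)
    counts = _allele_counts(D, responder)
    stat, p = _pearson_2x2(
        counts["a_resp"], counts["a_non"], counts["b_resp"], counts["b_non"]
    )
    return pd.DataFrame({"snp_id": snp_ids, "chisq_stat": stat, "chisq_p": p})


def two_stage_scan(
    D: np.ndarray,
    snp_ids: np.ndarray,
    responder: np.ndarray,
    sex_female: np.ndarray,
    manifest: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Full two-stage scan on a dosage matrix; returns the association table.

    One row per (shortlisted SNP × allele); direction is ``responder``
    for a positive dosage log-odds, ``non-responder`` for a negative
    one, and ``none`` when the logistic stage is not significant (or
    separated).  SNPs with a zero allele-count marginal are skipped.
    """
    config = config or AnalysisConfig()
    responder = np.asarray(responder, dtype=bool)
    stage1 = stage1_scan(D, snp_ids, responder)
    kept = shortlist(stage1, config)

    anno = None
    if manifest is not None:
        anno = manifest.set_index("snp_id")

    rows = []
    id_to_col = {sid: j for j, sid in enumerate(snp_ids)}
    for rec in kept.itertuples():
        j = id_to_col[rec.snp_id]
        d = D[:, j].astype(float)
        mask = d >= 0
        try:
            fit_b = logistic_allele_test(
                d[mask], responder[mask], sex_female[mask], test=config.logistic_test
            )
        except UndefinedStatisticError:
            continue
        for allele, beta in (("B", fit_b.beta), ("A", -fit_b.beta if np.isfinite(fit_b.beta) else np.nan)):
            significant = (
                not fit_b.separated
                and np.isfinite(fit_b.p)
                and fit_b.p < config.stage2_alpha
            )
            direction = "none"
            if significant and beta > 0:
                direction = "responder"
            elif significant and beta < 0:
                direction = "non-responder"
            row = {
                "snp_id": rec.snp_id,
                "allele": allele,
                "chisq_stat": rec.chisq_stat,
                "chisq_p": rec.chisq_p,
                "lr_beta": beta,
                "lr_p": fit_b.p,
                "direction": direction,
                "separated": fit_b.separated,
            }
            if anno is not None and rec.snp_id in anno.index:
                a = anno.loc[rec.snp_id]
                row.update(
                    gene=a["gene"], chromosome=a["chromosome"],
                    position=int(a["position"]), effect=a["consequence"],
                )
            rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=ASSOC_COLUMNS + ["separated"])
    for col in ASSOC_COLUMNS:
        if col not in out.columns:
            out[col] = ""
    return out[ASSOC_COLUMNS + ["separated"]]


def run_association(
    calls: pd.DataFrame,
    manifest: pd.DataFrame,
    phenotypes: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Two-stage association from a post-QC call table.

    ``phenotypes`` is the classified phenotype table; only treated,
    classified fetuses enter the analysis.
    """
    config = config or AnalysisConfig()
    treated = phenotypes[phenotypes["responder"].isin(["yes", "no"])]
    status = treated.set_index("fetus_id")["responder"]
    sex = treated.set_index("fetus_id")["sex"]
    samples = [s for s in status.index if s in set(calls["sample_id"])]
    D, snp_ids = _dosage_matrix(calls, samples)
    return two_stage_scan(
        D,
        snp_ids,
        (status.loc[samples] == "yes").to_numpy(),
        (sex.loc[samples] == "F").to_numpy(),
        manifest=manifest,
        config=config,
    )
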