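"""End-to-end orchestration: simulate → classify → zygosity → assoc → twinstats.

One call (or ``twinsteroid run`` from the shell) executes every stage in
order against either a simulated cohort or user-supplied input files,
writes each module's outputs into the run directory, and assembles a
single JSON run report that is bit-identically regenerable from the
same config and seed (modulo the timestamp field).
"""

from __future__ import annotations

import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import run_association
from .config import (
    AnalysisConfig,
    CohortConfig,
    config_to_dict,
    load_run_config,
    with_seed,
)
from .errors import PipelineStageError
from .genotypes import (
    classify_pairs,
    qc_filter,
    read_genotype_report,
    read_snp_manifest,
)
from .physiology import classify_cohort, read_phenotypes, summarize_groups
from .syndata import simulate_cohort, write_cohort
from .twinstats import fit_gee, pair_response_concordance, summarize_pk

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "pairs_from_phenotypes"]


def pairs_from_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Reconstruct the twin-pair table from a phenotype table."""
    rows = []
    for ewe, grp in pheno.groupby("ewe_id", sort=True):
        grp = grp.sort_values("delivery_order")
        if len(grp) != 2:
            raise PipelineStageError(
                f"pairs: ewe {ewe} has {len(grp)} fetuses, expected 2"
            )
        sexes = "".join(sorted(grp["sex"], reverse=True)).replace("FM", "MF")
        rows.append(
            {
                "ewe_id": ewe,
                "arm": grp["arm"].iloc[0],
                "twin_type": sexes,
                "fetus_id_1": grp["fetus_id"].iloc[0],
                "fetus_id_2": grp["fetus_id"].iloc[1],
            }
        )
    return pd.DataFrame(rows)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
            return out
        return wrapped
    return deco


def run_pipeline(
    cohort_config: CohortConfig | None = None,
    analysis_config: AnalysisConfig | None = None,
    out_dir="run",
    seed: int | None = None,
    simulate: bool = True,
    inputs: dict | None = None,
    config_path=None,
) -> dict:
    """Run every stage and write the report bundle into ``out_dir``.

    Either ``simulate=True`` (default; generates a cohort from
    ``cohort_config``) or ``inputs`` with paths ``{"pheno", "geno",
    "manifest"}`` (and optionally ``"pairs"``, ``"ewes"``) must be
    provided.  ``seed`` overrides the config seed.  Returns the run
    report as a dict; partial outputs are retained on stage failure.
    """
    if config_path is not None:
        cohort_config, analysis_config = load_run_config(config_path)
    cohort_config = cohort_config or CohortConfig()
    analysis_config = analysis_config or AnalysisConfig()
    if seed is not None:
        cohort_config = with_seed(cohort_config, seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "software": {"package": "twinsteroid", "version": __version__},
        "seed": cohort_config.seed,
        "config": {
            "cohort": config_to_dict(cohort_config),
            "analysis": config_to_dict(analysis_config),
        },
    }

    if simulate and inputs is None:
        cohort = _stage("simulate")(simulate_cohort)(cohort_config, analysis_config)
        write_cohort(cohort, out)
        pheno, calls, manifest, pairs, ewes = (
            cohort.fetuses, cohort.genotype_calls, cohort.snp_manifest,
            cohort.pairs, cohort.ewes,
        )
        log.info("simulate: %d fetuses, %d pairs, %d SNPs",
                 len(pheno), len(pairs), len(manifest))
    elif inputs is not None:
        pheno = _stage("load")(read_phenotypes)(inputs["pheno"])
        calls = _stage("load")(read_genotype_report)(inputs["geno"])
        manifest = _stage("load")(read_snp_manifest)(inputs["manifest"])
        pairs = (
            pd.read_csv(inputs["pairs"]) if "pairs" in inputs
            else pairs_from_phenotypes(pheno)
        )
        ewes = pd.read_csv(inputs["ewes"]) if "ewes" in inputs else None
    else:
        raise PipelineStageError("run_pipeline: need simulate=True or input paths")

    if "twin_type" not in pheno.columns:
        pheno = pheno.merge(pairs[["ewe_id", "twin_type"]], on="ewe_id", how="left")

    # --- classify ---------------------------------------------------------
    classified, cutoff = _stage("classify")(classify_cohort)(pheno, analysis_config)
    classified.to_csv(out / "classified.csv", index=False)
    with open(out / "cutoff.json", "w") as fh:
        json.dump(cutoff.to_dict(), fh, indent=1)
    log.info("classify: cutoff %.2f mmHg from %d controls",
             cutoff.cutoff, cutoff.n_controls)

    summaries = _stage("classify")(summarize_groups)(
        classified, ["arm", "sex"]
    )
    summaries.to_csv(out / "summary_by_arm_sex.tsv", sep="\t", index=False)

    # --- zygosity ---------------------------------------------------------
    qc_calls, qc_report = _stage("zygosity")(qc_filter)(calls, manifest, analysis_config)
    zygosity = _stage("zygosity")(classify_pairs)(qc_calls, pairs, analysis_config)
    zygosity.to_csv(out / "zygosity.tsv", sep="\t", index=False)
    log.info("zygosity: %d/%d calls passed QC; %d MZ / %d DZ",
             qc_report.n_calls_pass_gc, qc_report.n_calls_input,
             (zygosity["zygosity"] == "MZ").sum(), (zygosity["zygosity"] == "DZ").sum())

    # --- association ------------------------------------------------------
    assoc = _stage("assoc")(run_association)(
        qc_calls, manifest, classified[classified["responder"].isin(["yes", "no"])],
        analysis_config,
    )
    assoc.to_csv(out / "association.tsv", sep="\t", index=False)
    log.info("assoc: %d allele rows, %d SNPs significant in both stages",
             len(assoc), assoc.loc[assoc["direction"] != "none", "snp_id"].nunique())

    # --- twinstats --------------------------------------------------------
    concordance = _stage("twinstats")(pair_response_concordance)(classified)
    gee = _stage("twinstats")(fit_gee)(classified)
    pk = _stage("twinstats")(summarize_pk)(classified, analysis_config, ewes=ewes)
    with open(out / "concordance.json", "w") as fh:
        json.dump(
            {"n_pairs": concordance.n_pairs, "n_concordant": concordance.n_concordant,
             "fraction": concordance.fraction, "percent": concordance.percent},
            fh, indent=1,
        )
    gee.to_csv(out / "gee.tsv", sep="\t", index=False)
    pk.to_csv(out / "pk_summary.tsv", sep="\t", index=False)

    report.update(
        {
            "cutoff": cutoff.to_dict(),
            "qc": qc_report.to_dict(),
            "n_fetuses": int(len(pheno)),
            "n_pairs": int(len(pairs)),
            "summaries_by_arm_sex": _records(summaries),
            "zygosity": _records(zygosity),
            "association": _records(assoc),
            "concordance": {
                "n_pairs": concordance.n_pairs,
                "n_concordant": concordance.n_concordant,
                "percent": concordance.percent,
            },
            "gee": _records(gee),
            "pk_summary": _records(pk),
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=_jsonable)
    return report


def _records(df: pd.DataFrame) -> list[dict]:
    return json.loads(df.to_json(orient="records"))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
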