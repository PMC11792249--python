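"""Synthetic twin-cohort generator.

Generates cohorts with the statistical structure the analysis assumes:
twin pairs nested in ewes across three treatment arms (single-dose CS1,
two-dose CS2, saline control), biallelic SNP genotypes with full-sib
Mendelian sharing for dizygotic pairs, a logistic responder model with
sex, delivery-order and optional planted per-allele SNP effects, Normal
control PaCO2, and terminal betamethasone levels censored at the assay
detection limits.

The genotype model: for each dizygotic pair, sire and dam genotypes are
drawn under Hardy–Weinberg equilibrium at each SNP independently (no
linkage), and each sib receives one transmitted allele from each parent,
independently per sib.  Monozygotic pairs are drawn once and duplicated.
Per-call allele-flip errors and missingness are applied afterwards.
Alleles are abstract A (reference) / B (alternate); "dosage" counts B.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from ._rng import stream_rngs
from .config import (
    ARMS,
    TREATED_ARMS,
    AnalysisConfig,
    CohortConfig,
    ScoreLaw,
    config_to_dict,
)
from .errors import ConfigError

__all__ = [
    "Cohort",
    "simulate_cohort",
    "simulate_pair_genotypes",
    "simulate_phenotypes",
    "dosages_to_calls",
    "write_cohort",
    "planted_recovery_config",
    "gee_recovery_config",
]

MISSING = -1  # dosage code for a no-call

_CONSEQUENCES = (
    "intron variant",
    "3' UTR variant",
    "downstream gene variant",
    "intergenic variant",
    "synonymous variant",
)


@dataclass
class Cohort:
    """A simulated cohort plus the ground truth used to generate it.

    ``dosages`` is an ``(n_fetuses, n_snps)`` int8 matrix counting copies
    of allele B per call (−1 = missing); ``genotype_calls`` is the same
    information in long final-report form.
    """

    fetuses: pd.DataFrame
    pairs: pd.DataFrame
    ewes: pd.DataFrame
    snp_manifest: pd.DataFrame
    genotype_calls: pd.DataFrame
    dosages: np.ndarray
    sample_ids: list[str]
    truth: dict = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_fetuses(self) -> int:
        return len(self.fetuses)


def simulate_pair_genotypes(
    mafs: np.ndarray, zygosity: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one twin pair's genotype dosage vectors (no errors applied).

    Dizygotic pairs are full siblings: sire and dam genotypes are drawn
    under Hardy–Weinberg at each SNP, and each sib independently receives
    one allele from each parent.  Monozygotic pairs are a single draw,
    duplicated.  ``mafs`` is the allele-B frequency per SNP, in (0, 0.5]
    (0 is tolerated and yields a monomorphic reference locus).
    """
    mafs = np.asarray(mafs, dtype=float)
    n = mafs.size
    if np.any((mafs < 0) | (mafs > 0.5)):
        raise ConfigError("simulate_pair_genotypes: mafs must lie in [0, 0.5]")
    if zygosity not in ("MZ", "DZ"):
        raise ConfigError(f"simulate_pair_genotypes: zygosity {zygosity!r}")

    sire = rng.random((2, n)) < mafs  # two parental allele copies, True = B
    dam = rng.random((2, n)) < mafs
    idx = np.arange(n)

    def child() -> np.ndarray:
        from_sire = sire[rng.integers(0, 2, size=n), idx]
        from_dam = dam[rng.integers(0, 2, size=n), idx]
        return (from_sire.astype(np.int8) + from_dam.astype(np.int8))

    g1 = child()
    g2 = g1.copy() if zygosity == "MZ" else child()
    return g1, g2


def _apply_call_noise(
    dosages: np.ndarray, error_rate: float, missing_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Symmetric single-allele flip errors, then missingness, per call."""
    out = dosages.copy()
    if error_rate > 0:
        err = rng.random(out.shape) < error_rate
        # flipping one uniformly chosen allele moves dosage by ±1
        direction = np.where(
            out == 0, 1, np.where(out == 2, -1, rng.choice([-1, 1], size=out.shape))
        ).astype(np.int8)
        out = np.where(err, out + direction, out).astype(np.int8)
    if missing_rate > 0:
        miss = rng.random(out.shape) < missing_rate
        out = np.where(miss, MISSING, out).astype(np.int8)
    return out


def _simulate_manifest(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_snps
    chroms = np.array([str(c) for c in range(1, 27)] + ["X"])
    probs = np.full(27, (1 - 0.04) / 26)
    probs[-1] = 0.04  # a small X-linked fraction, as on the real chip
    chromosome = rng.choice(chroms, size=n, p=probs)
    position = rng.integers(1, 100_000_000, size=n)
    gentrain = config.gentrain_law.draw(rng, n)
    has_gene = rng.random(n) < 0.6
    gene = np.where(has_gene, [f"GENE{i:05d}" for i in range(n)], "")
    consequence = np.where(
        has_gene, rng.choice(_CONSEQUENCES[:3], size=n), rng.choice(_CONSEQUENCES, size=n)
    )
    return pd.DataFrame(
        {
            "snp_id": [f"SNP{i:06d}" for i in range(n)],
            "chromosome": chromosome,
            "position": position.astype(np.int64),
            "gentrain": np.round(gentrain, 6),
            "gene": gene,
            "consequence": consequence,
        }
    )


def _simulate_design(config: CohortConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair-level and fetus-level design tables (arms, sexes, zygosity)."""
    arms = np.repeat(list(ARMS), config.pairs_per_arm)
    n_pairs = arms.size
    ewe_ids = [f"E{i + 1:03d}" for i in range(n_pairs)]
    zygosity = np.where(rng.random(n_pairs) < config.mz_fraction, "MZ", "DZ")

    if config.sex_pattern is not None:
        codes = [config.sex_pattern[i % len(config.sex_pattern)] for i in range(n_pairs)]
        sexes = np.array([[c[0], c[1]] for c in codes])
    else:
        sexes = np.where(rng.random((n_pairs, 2)) < 0.5, "F", "M")
    # MZ twins share sex by definition
    sexes[zygosity == "MZ", 1] = sexes[zygosity == "MZ", 0]

    twin_type = np.array(["".join(sorted(pair, reverse=True)) for pair in sexes])
    # canonical labels: MM, MF, FF
    twin_type = np.char.replace(twin_type, "FM", "MF")

    pairs = pd.DataFrame(
        {
            "ewe_id": ewe_ids,
            "arm": arms,
            "true_zygosity": zygosity,
            "twin_type": twin_type,
            "fetus_id_1": [f"{e}.1" for e in ewe_ids],
            "fetus_id_2": [f"{e}.2" for e in ewe_ids],
        }
    )
    fetuses = pd.DataFrame(
        {
            "fetus_id": np.concatenate([pairs.fetus_id_1, pairs.fetus_id_2]),
            "ewe_id": np.tile(ewe_ids, 2),
            "arm": np.tile(arms, 2),
            "sex": np.concatenate([sexes[:, 0], sexes[:, 1]]),
            "delivery_order": np.repeat([1, 2], n_pairs),
            "twin_type": np.tile(twin_type, 2),
        }
    )
    fetuses = fetuses.sort_values(["ewe_id", "delivery_order"], ignore_index=True)
    return pairs, fetuses


def simulate_phenotypes(
    skeleton: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
    dosages: np.ndarray | None = None,
    pk_rng: np.random.Generator | None = None,
    analysis: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Draw physiology and drug levels for a cohort skeleton.

    ``skeleton`` must carry ``fetus_id, ewe_id, arm, sex, delivery_order``
    (one row per fetus, twins adjacent by ewe).  Control fetuses draw
    PaCO2 from the control Normal; treated fetuses first draw a latent
    responder status from the logistic model
    ``logit p = b0 + b_sex·I(female) + b_order·I(second) + Σ b_k·dosage_k``
    and then PaCO2 from the responder or non-responder Normal.  Drug
    levels follow the hierarchical PK model and are censored at the
    assay LODs (censored values are returned as NaN).

    Returns a copy of the skeleton with ``paco2_30min, vei, birthweight_kg,
    cord_ph, cord_paco2, pip, peep, rate, plasma_beta, lung_beta`` plus a
    ``responder_true`` ground-truth column (treated arms only).
    """
    from .physiology import compute_vei

    analysis = analysis or AnalysisConfig()
    pk_rng = pk_rng if pk_rng is not None else rng
    out = skeleton.reset_index(drop=True).copy()
    n = len(out)
    treated = out["arm"].isin(TREATED_ARMS).to_numpy()

    eta = np.full(n, config.beta0)
    eta += config.beta_sex * (out["sex"].to_numpy() == "F")
    eta += config.beta_order * (out["delivery_order"].to_numpy() == 2)
    if config.planted_snps and dosages is not None:
        for snp_idx, beta in config.planted_snps:
            d = dosages[:, snp_idx].astype(float)
            d[d == MISSING] = 2 * 0.5  # neutral imputation for rare no-calls
            eta += beta * d
    responder_true = rng.random(n) < expit(eta)
    responder_true &= treated

    r_mean, r_sd = config.responder_paco2
    nr_mean, nr_sd = config.nonresponder_paco2
    c_mean, c_sd = config.control_paco2
    mean = np.where(treated, np.where(responder_true, r_mean, nr_mean), c_mean)
    sd = np.where(treated, np.where(responder_true, r_sd, nr_sd), c_sd)
    paco2 = np.maximum(rng.normal(mean, sd), config.paco2_floor)

    vent = config.ventilation
    out["birthweight_kg"] = np.round(rng.normal(*config.birthweight, size=n), 3)
    out["cord_ph"] = np.round(rng.normal(*config.cord_ph, size=n), 3)
    out["cord_paco2"] = np.round(rng.normal(*config.cord_paco2, size=n), 2)
    out["paco2_30min"] = np.round(paco2, 2)
    out["vei"] = compute_vei(vent, out["paco2_30min"].to_numpy())
    out["pip"] = vent.pip
    out["peep"] = vent.peep
    out["rate"] = vent.rate

    plasma_raw, lung_raw, maternal = _simulate_pk(out, config, pk_rng)
    out["plasma_beta_raw"] = plasma_raw
    out["lung_beta_raw"] = lung_raw
    out["plasma_beta"] = np.where(plasma_raw >= analysis.lod_plasma, plasma_raw, np.nan)
    out["lung_beta"] = np.where(lung_raw >= analysis.lod_tissue, lung_raw, np.nan)
    out["maternal_plasma_beta_raw"] = maternal
    out["responder_true"] = np.where(treated, responder_true, False)
    return out


def _simulate_pk(
    pheno: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maternal plasma per ewe; fetal plasma and lung per fetus (raw, ng/mL)."""
    pk = config.pk_params
    ewes = pheno["ewe_id"].drop_duplicates().to_list()
    ewe_arm = pheno.drop_duplicates("ewe_id").set_index("ewe_id")["arm"]

    maternal = {}
    pair_fm = {}
    pair_lp = {}
    for ewe in ewes:
        if ewe_arm[ewe] in TREATED_ARMS:
            maternal[ewe] = pk.maternal_plasma[ewe_arm[ewe]].draw(rng)
        else:
            maternal[ewe] = 0.0
        pair_fm[ewe] = pk.fetal_maternal_ratio.pair_law.draw(rng)
        pair_lp[ewe] = pk.lung_plasma_ratio.pair_law.draw(rng)

    n = len(pheno)
    m = pheno["ewe_id"].map(maternal).to_numpy(dtype=float)
    fm = pheno["ewe_id"].map(pair_fm).to_numpy() * pk.fetal_maternal_ratio.fetus_law.draw(rng, n)
    lp = pheno["ewe_id"].map(pair_lp).to_numpy() * pk.lung_plasma_ratio.fetus_law.draw(rng, n)
    plasma = m * fm
    lung = plasma * lp
    maternal_per_fetus = m
    return np.round(plasma, 4), np.round(lung, 4), np.round(maternal_per_fetus, 4)


def dosages_to_calls(
    dosages: np.ndarray,
    sample_ids: list[str],
    snp_ids: np.ndarray,
    gc_scores: np.ndarray,
) -> pd.DataFrame:
    """Long final-report-style call table from a dosage matrix.

    Allele pairs are reported in sorted order (AA / AB / BB); missing
    calls as ``-,-``.
    """
    n_samples, n_snps = dosages.shape
    # dosage 0 -> (A,A); 1 -> (A,B); 2 -> (B,B); missing -> (-,-)
    a1 = np.full(dosages.shape, "A", dtype="<U1")
    a2 = np.full(dosages.shape, "A", dtype="<U1")
    a2[dosages >= 1] = "B"
    a1[dosages == 2] = "B"
    a1[dosages == MISSING] = "-"
    a2[dosages == MISSING] = "-"
    return pd.DataFrame(
        {
            "sample_id": np.repeat(sample_ids, n_snps),
            "snp_id": np.tile(snp_ids, n_samples),
            "allele1": a1.ravel(),
            "allele2": a2.ravel(),
            "gc_score": np.round(gc_scores, 6).ravel(),
        }
    )


def simulate_cohort(
    config: CohortConfig, analysis: AnalysisConfig | None = None
) -> Cohort:
    """Simulate a full twin cohort from a :class:`CohortConfig`.

    Identical config (including its seed) yields bit-identical output.
    The returned :class:`Cohort` carries a ``truth`` record with planted
    parameters: per-pair zygosity, per-fetus latent responder status,
    per-SNP allele frequencies and the planted SNP effects.
    """
    config.validate()
    analysis = analysis or AnalysisConfig()
    rngs = stream_rngs(config.seed)

    pairs, fetuses = _simulate_design(config, rngs["design"])
    manifest = _simulate_manifest(config, rngs["design"])
    mafs = config.maf_law.draw(rngs["design"], config.n_snps)

    g_rng = rngs["genotypes"]
    sample_ids = fetuses["fetus_id"].to_list()
    order = {fid: i for i, fid in enumerate(sample_ids)}
    dosages = np.empty((len(sample_ids), config.n_snps), dtype=np.int8)
    for row in pairs.itertuples():
        g1, g2 = simulate_pair_genotypes(mafs, row.true_zygosity, g_rng)
        dosages[order[row.fetus_id_1]] = g1
        dosages[order[row.fetus_id_2]] = g2
    dosages = _apply_call_noise(
        dosages, config.genotype_error_rate, config.missing_rate, g_rng
    )

    gc = config.gc_law.draw(rngs["scores"], dosages.shape)
    calls = dosages_to_calls(dosages, sample_ids, manifest["snp_id"].to_numpy(), gc)

    pheno = simulate_phenotypes(
        fetuses, config, rngs["phenotypes"], dosages=dosages,
        pk_rng=rngs["pk"], analysis=analysis,
    )

    ewes = pairs[["ewe_id", "arm"]].copy()
    ewes["maternal_plasma_beta_raw"] = (
        pheno.drop_duplicates("ewe_id").set_index("ewe_id")["maternal_plasma_beta_raw"]
        .reindex(ewes["ewe_id"]).to_numpy()
    )

    truth = {
        "seed": config.seed,
        "config": config_to_dict(config),
        "mafs": np.round(mafs, 6).tolist(),
        "true_zygosity": dict(zip(pairs["ewe_id"], pairs["true_zygosity"])),
        "true_responder": dict(
            zip(pheno["fetus_id"], pheno["responder_true"].astype(bool).tolist())
        ),
        "planted_snps": [
            {"index": int(i), "snp_id": f"SNP{int(i):06d}", "log_odds": float(b)}
            for i, b in config.planted_snps
        ],
    }
    return Cohort(
        fetuses=pheno,
        pairs=pairs,
        ewes=ewes,
        snp_manifest=manifest,
        genotype_calls=calls,
        dosages=dosages,
        sample_ids=sample_ids,
        truth=truth,
    )


def _low_noise_overrides() -> dict:
    """Phenotyping settings for planted-effect power scenarios.

    Well-separated responder / non-responder PaCO2 laws and clean
    genotyping scores, so that recovery measures the association and
    GEE machinery rather than responder-misclassification attenuation.
    """
    return dict(
        responder_paco2=(55.0, 10.0),
        nonresponder_paco2=(130.0, 20.0),
        control_paco2=(130.0, 20.0),
        gentrain_law=ScoreLaw(1.0, 0.75, 1.0, 0.3, 0.7),
        gc_law=ScoreLaw(1.0, 0.2, 1.0, 0.0, 0.15),
    )


def planted_recovery_config(
    n_ans_pairs: int = 500,
    n_control_pairs: int = 50,
    n_snps: int = 600,
    n_planted: int = 13,
    effect: float = math.log(6.0),
    seed: int = 0,
) -> CohortConfig:
    """Planted-effect scenario: ``n_planted`` SNPs with per-allele
    log-odds ±``effect`` (alternating signs, positives first) spread
    evenly over the panel, on a low-noise phenotyping background.

    The intercept offsets the planted effects' expected contribution
    (mean dosage 2·E[maf] = 0.6 under the default maf law) and the sex
    and delivery-order effects, keeping the cohort near a balanced
    responder fraction.
    """
    idx = np.linspace(0, n_snps - 1, n_planted).round().astype(int)
    signs = [1 if k % 2 == 0 else -1 for k in range(n_planted)]
    planted = tuple((int(j), s * effect) for j, s in zip(idx, signs))
    beta_sex = math.log(7.786)
    beta_order = math.log(1 / 0.258)
    mean_dosage = 2 * 0.3
    beta0 = -(0.5 * beta_sex + 0.5 * beta_order + mean_dosage * effect * sum(signs))
    per_arm = max(1, n_ans_pairs // 2)
    return CohortConfig(
        pairs_per_arm=(per_arm, n_ans_pairs - per_arm, n_control_pairs),
        n_snps=n_snps,
        planted_snps=planted,
        beta0=beta0,
        beta_sex=beta_sex,
        beta_order=beta_order,
        seed=seed,
        **_low_noise_overrides(),
    )


def gee_recovery_config(
    n_ans_pairs: int = 500, n_control_pairs: int = 50, seed: int = 0
) -> CohortConfig:
    """Sex / delivery-order effect recovery scenario (no planted SNPs).

    Plants the marginal log-odds the analysis should recover —
    ln 7.786 for female sex, ln(1/0.258) for second delivery — on the
    low-noise phenotyping background, with a balanced intercept.
    """
    beta_sex = math.log(7.786)
    beta_order = math.log(1 / 0.258)
    per_arm = max(1, n_ans_pairs // 2)
    return CohortConfig(
        pairs_per_arm=(per_arm, n_ans_pairs - per_arm, n_control_pairs),
        n_snps=10,
        beta0=-(0.5 * beta_sex + 0.5 * beta_order),
        beta_sex=beta_sex,
        beta_order=beta_order,
        seed=seed,
        **_low_noise_overrides(),
    )


def write_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    """Write the pipeline's standard input files plus the truth record.

    Emits ``pheno.csv`` (phenotype table), ``geno.tsv`` (final-report
    calls), ``manifest.tsv`` (SNP manifest), ``pairs.csv``, ``ewes.csv``
    and ``truth.json``; returns the paths keyed by file role.
    """
    from .genotypes import write_genotype_report, write_snp_manifest
    from .physiology import write_phenotypes

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pheno": out / "pheno.csv",
        "geno": out / "geno.tsv",
        "manifest": out / "manifest.tsv",
        "pairs": out / "pairs.csv",
        "ewes": out / "ewes.csv",
        "truth": out / "truth.json",
    }
    write_phenotypes(cohort.fetuses, paths["pheno"])
    write_genotype_report(cohort.genotype_calls, paths["geno"])
    write_snp_manifest(cohort.snp_manifest, paths["manifest"])
    cohort.pairs[
        ["ewe_id", "arm", "twin_type", "fetus_id_1", "fetus_id_2"]
    ].to_csv(paths["pairs"], index=False)
    cohort.ewes.to_csv(paths["ewes"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1)
    return paths
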