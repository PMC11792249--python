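"""Configuration objects for the simulation and the analysis.

Two configs drive everything:

* :class:`CohortConfig` — every parameter of the synthetic twin cohort
  (design sizes, genotype model, phenotype model, drug-level model).
* :class:`AnalysisConfig` — every threshold and constant of the analysis
  (QC score cut-offs, two-stage association alphas, zygosity threshold,
  the 2-SD responder rule, assay detection limits).

Both can be loaded from a single YAML file with top-level blocks
``cohort:`` and ``analysis:`` (see :func:`load_run_config`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigError

ARMS = ("CS1", "CS2", "CONTROL")
TREATED_ARMS = ("CS1", "CS2")

__all__ = [
    "ARMS",
    "TREATED_ARMS",
    "Uniform",
    "LogNormal",
    "TwinSharedLogNormal",
    "ScoreLaw",
    "PkParams",
    "VentilationSettings",
    "CohortConfig",
    "AnalysisConfig",
    "load_run_config",
]


@dataclass(frozen=True)
class Uniform:
    """Uniform law on [low, high)."""

    low: float
    high: float

    def draw(self, rng: np.random.Generator, size=None) -> np.ndarray:
        return rng.uniform(self.low, self.high, size=size)


@dataclass(frozen=True)
class LogNormal:
    """Log-normal law parametrised by its arithmetic mean and CV.

    ``sigma^2 = ln(1 + cv^2)`` and ``mu = ln(mean) - sigma^2 / 2``, so
    the drawn values have expectation ``mean`` exactly.
    """

    mean: float
    cv: float

    @property
    def sigma(self) -> float:
        return math.sqrt(math.log1p(self.cv**2))

    @property
    def mu(self) -> float:
        return math.log(self.mean) - 0.5 * math.log1p(self.cv**2)

    def draw(self, rng: np.random.Generator, size=None) -> np.ndarray:
        return rng.lognormal(self.mu, self.sigma, size=size)


@dataclass(frozen=True)
class TwinSharedLogNormal:
    """Log-normal ratio with a pair-shared and a per-fetus component.

    A twin pair shares one ``LogNormal(mean, cv_between)`` draw; each
    fetus multiplies it by an independent ``LogNormal(1, cv_within)``
    jitter.  This keeps within-pair differences much smaller than
    between-pair spread, as observed for fetal drug exposure.
    """

    mean: float
    cv_between: float
    cv_within: float

    @property
    def pair_law(self) -> LogNormal:
        return LogNormal(self.mean, self.cv_between)

    @property
    def fetus_law(self) -> LogNormal:
        return LogNormal(1.0, self.cv_within)

    @property
    def sigma_total(self) -> float:
        """Log-scale SD of the full per-fetus ratio (components sum)."""
        return math.sqrt(self.pair_law.sigma**2 + self.fetus_law.sigma**2)

    @property
    def mu_total(self) -> float:
        return self.pair_law.mu + self.fetus_law.mu


@dataclass(frozen=True)
class ScoreLaw:
    """Mixture law for genotyping quality scores.

    With probability ``pass_rate`` a score is drawn uniformly from the
    passing range, otherwise from the failing range.  Used for both the
    SNP-level GenTrain score and the call-level GC score.
    """

    pass_rate: float
    pass_low: float
    pass_high: float
    fail_low: float
    fail_high: float

    def draw(self, rng: np.random.Generator, size) -> np.ndarray:
        passing = rng.random(size) < self.pass_rate
        lo = np.where(passing, self.pass_low, self.fail_low)
        hi = np.where(passing, self.pass_high, self.fail_high)
        return rng.uniform(lo, hi)


@dataclass(frozen=True)
class PkParams:
    """Terminal betamethasone concentration model.

    Maternal plasma is drawn per ewe from an arm-specific log-normal;
    fetal plasma is maternal × a fetal/maternal ratio; lung tissue is
    fetal plasma × a lung/plasma ratio.  Both ratios carry pair-shared
    and per-fetus components.  Control-arm animals carry zero drug.
    """

    maternal_plasma: Mapping[str, LogNormal] = field(
        default_factory=lambda: {
            "CS1": LogNormal(mean=14.8, cv=11.4 / 14.8),
            "CS2": LogNormal(mean=7.8, cv=2.2 / 7.8),
        }
    )
    fetal_maternal_ratio: TwinSharedLogNormal = TwinSharedLogNormal(
        mean=0.19, cv_between=0.40, cv_within=0.08
    )
    lung_plasma_ratio: TwinSharedLogNormal = TwinSharedLogNormal(
        mean=14.5, cv_between=0.35, cv_within=0.15
    )

    def fetal_plasma_lognorm(self, arm: str) -> tuple[float, float]:
        """(mu, sigma) of the marginal fetal-plasma law for a treated arm.

        Products of independent log-normals stay log-normal with summed
        log-scale parameters; used by censoring diagnostics.
        """
        m = self.maternal_plasma[arm]
        r = self.fetal_maternal_ratio
        return m.mu + r.mu_total, math.sqrt(m.sigma**2 + r.sigma_total**2)


@dataclass(frozen=True)
class VentilationSettings:
    """Fixed ventilator settings of the standardized 30-min protocol."""

    pip: float = 35.0  # peak inspiratory pressure, cmH2O
    peep: float = 5.0  # positive end-expiratory pressure, cmH2O
    rate: float = 50.0  # breaths per minute
    inspiratory_time: float = 0.5  # seconds
    vei_constant: float = 3800.0

    def validate(self) -> None:
        if not self.pip > self.peep >= 0:
            raise ConfigError("VentilationSettings: require pip > peep >= 0")
        if self.rate <= 0:
            raise ConfigError("VentilationSettings.rate must be positive")


def _as_pair(name: str, value) -> tuple[float, float]:
    mean, sd = float(value[0]), float(value[1])
    if sd <= 0:
        raise ConfigError(f"CohortConfig.{name}: sd must be > 0")
    return mean, sd


@dataclass(frozen=True)
class CohortConfig:
    """All parameters of the synthetic twin cohort.

    Defaults reproduce the design of the twin-lamb betamethasone study:
    11/10/10 twin pairs in the single-dose (CS1), two-dose (CS2) and
    saline-control arms, an all-dizygotic cohort, control 30-min PaCO2
    of roughly 130 ± 25 mmHg, and a logistic responder model with a
    strong female advantage (log-OR ln 7.786) and a second-delivered
    advantage (log-OR ln(1/0.258)).
    """

    pairs_per_arm: tuple[int, int, int] = (11, 10, 10)  # CS1, CS2, CONTROL
    n_snps: int = 5000
    maf_law: Uniform = Uniform(0.1, 0.5)
    mz_fraction: float = 0.0
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0
    gentrain_law: ScoreLaw = ScoreLaw(0.95, 0.70, 1.0, 0.30, 0.70)
    gc_law: ScoreLaw = ScoreLaw(0.98, 0.15, 1.0, 0.0, 0.15)

    control_paco2: tuple[float, float] = (130.0, 24.6)  # mmHg, mean/sd
    responder_paco2: tuple[float, float] = (60.0, 15.0)
    nonresponder_paco2: tuple[float, float] = (125.0, 25.0)
    paco2_floor: float = 10.0  # physiological lower clip, mmHg

    beta0: float = -1.4
    beta_sex: float = math.log(7.786)  # female vs male
    beta_order: float = math.log(1 / 0.258)  # second- vs first-delivered
    planted_snps: tuple[tuple[int, float], ...] = ()  # (snp index, per-allele log-odds)

    sex_pattern: tuple[str, ...] | None = None  # e.g. ("MF","MM",...) cycled over pairs

    birthweight: tuple[float, float] = (2.85, 0.40)  # kg
    cord_ph: tuple[float, float] = (7.27, 0.11)
    cord_paco2: tuple[float, float] = (61.0, 14.0)  # mmHg

    pk_params: PkParams = PkParams()
    ventilation: VentilationSettings = VentilationSettings()
    seed: int = 0

    def validate(self) -> None:
        if len(self.pairs_per_arm) != 3 or any(n < 1 for n in self.pairs_per_arm):
            raise ConfigError("CohortConfig.pairs_per_arm: three counts, each >= 1")
        if self.n_snps < 1:
            raise ConfigError("CohortConfig.n_snps must be >= 1")
        for name in ("mz_fraction", "genotype_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"CohortConfig.{name} must be in [0, 1]")
        if not 0.0 <= self.maf_law.low <= self.maf_law.high <= 0.5:
            raise ConfigError("CohortConfig.maf_law must be bounded within (0, 0.5]")
        for name in ("control_paco2", "responder_paco2", "nonresponder_paco2",
                     "birthweight", "cord_ph", "cord_paco2"):
            _as_pair(name, getattr(self, name))
        for idx, beta in self.planted_snps:
            if not 0 <= int(idx) < self.n_snps:
                raise ConfigError(
                    f"CohortConfig.planted_snps: index {idx} outside [0, n_snps)"
                )
            float(beta)
        if self.sex_pattern is not None:
            for code in self.sex_pattern:
                if code not in ("MM", "MF", "FM", "FF"):
                    raise ConfigError(
                        f"CohortConfig.sex_pattern: invalid pair code {code!r}"
                    )
        self.ventilation.validate()

    @property
    def n_pairs(self) -> int:
        return sum(self.pairs_per_arm)

    @property
    def n_fetuses(self) -> int:
        return 2 * self.n_pairs


@dataclass(frozen=True)
class AnalysisConfig:
    """Every threshold and constant of the analysis.

    Defaults are the published constants: GenTrain > 0.7 and GC > 0.15
    QC filters (both strict), chi-square shortlist at p < 0.01, logistic
    stage at p < 0.05, monozygosity at concordance > 0.9, responder
    cut-off at control mean − 2 SD, and assay detection limits of
    0.5 ng/mL (plasma) and 1.0 ng/mL (lung tissue).
    """

    gentrain_min: float = 0.70
    gc_min: float = 0.15
    stage1_alpha: float = 0.01
    stage2_alpha: float = 0.05
    zygosity_threshold: float = 0.90
    sd_multiplier: float = 2.0
    lod_plasma: float = 0.5  # ng/mL
    lod_tissue: float = 1.0  # ng/g-equivalent
    logistic_test: str = "wald"  # or "lr"
    half_lod_substitution: bool = False

    def validate(self) -> None:
        for name in ("gentrain_min", "gc_min", "zygosity_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"AnalysisConfig.{name} must be in [0, 1]")
        for name in ("stage1_alpha", "stage2_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"AnalysisConfig.{name} must be in (0, 1)")
        if self.sd_multiplier <= 0:
            raise ConfigError("AnalysisConfig.sd_multiplier must be positive")
        if self.lod_plasma <= 0 or self.lod_tissue <= 0:
            raise ConfigError("AnalysisConfig LODs must be positive")
        if self.logistic_test not in ("wald", "lr"):
            raise ConfigError("AnalysisConfig.logistic_test must be 'wald' or 'lr'")


def _build(cls, mapping: Mapping) -> object:
    """Construct a config dataclass from a plain mapping, with nested laws."""
    kwargs = dict(mapping)
    converters = {
        "maf_law": lambda v: Uniform(**v) if isinstance(v, Mapping) else Uniform(*v),
        "gentrain_law": lambda v: ScoreLaw(**v),
        "gc_law": lambda v: ScoreLaw(**v),
        "ventilation": lambda v: VentilationSettings(**v),
        "pk_params": _build_pk,
    }
    for key, conv in converters.items():
        if key in kwargs and isinstance(kwargs[key], (Mapping, Sequence)) and not isinstance(kwargs[key], str):
            if key == "maf_law" or isinstance(kwargs[key], Mapping):
                kwargs[key] = conv(kwargs[key])
    for key in ("pairs_per_arm", "control_paco2", "responder_paco2",
                "nonresponder_paco2", "birthweight", "cord_ph", "cord_paco2"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if "planted_snps" in kwargs:
        kwargs["planted_snps"] = tuple(
            (int(i), float(b)) for i, b in kwargs["planted_snps"]
        )
    if kwargs.get("sex_pattern") is not None and "sex_pattern" in kwargs:
        kwargs["sex_pattern"] = tuple(kwargs["sex_pattern"])
    try:
        obj = cls(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"{cls.__name__}: {exc}") from exc
    obj.validate()
    return obj


def _build_pk(mapping: Mapping) -> PkParams:
    kwargs = dict(mapping)
    if "maternal_plasma" in kwargs:
        kwargs["maternal_plasma"] = {
            arm: LogNormal(**law) for arm, law in kwargs["maternal_plasma"].items()
        }
    for key in ("fetal_maternal_ratio", "lung_plasma_ratio"):
        if key in kwargs:
            kwargs[key] = TwinSharedLogNormal(**kwargs[key])
    return PkParams(**kwargs)


def cohort_config_from_dict(mapping: Mapping) -> CohortConfig:
    return _build(CohortConfig, mapping)


def analysis_config_from_dict(mapping: Mapping) -> AnalysisConfig:
    cfg = AnalysisConfig(**dict(mapping))
    cfg.validate()
    return cfg


def load_run_config(path) -> tuple[CohortConfig, AnalysisConfig]:
    """Load ``cohort:`` and ``analysis:`` blocks from one YAML file.

    Either block may be omitted; missing fields take their defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort = cohort_config_from_dict(raw.get("cohort", {}))
    analysis = analysis_config_from_dict(raw.get("analysis", {}))
    return cohort, analysis


def config_to_dict(cfg) -> dict:
    """Plain-JSON-able echo of a config dataclass (for run reports)."""
    return asdict(cfg)


def with_seed(cfg: CohortConfig, seed: int) -> CohortConfig:
    return replace(cfg, seed=int(seed))
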