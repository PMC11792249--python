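"""Ventilation-derived phenotyping.

The responder definition is control-referenced: treated lambs whose
30-minute PaCO2 falls below the saline-control mean minus a fixed
multiple (default 2) of the control SD are classed as steroid
responders; everything at or above the cut-off is a non-responder.
The ventilation efficacy index (VEI) integrates ventilator pressure,
rate and achieved gas exchange into one dimensionless number.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig, VentilationSettings
from .errors import DomainError, InsufficientDataError

__all__ = [
    "CutoffResult",
    "GroupSummary",
    "compute_vei",
    "derive_cutoff",
    "classify_responder",
    "classify_cohort",
    "pooled_moments",
    "summarize_groups",
    "read_phenotypes",
    "write_phenotypes",
    "PHENO_COLUMNS",
]

PHENO_COLUMNS = [
    "fetus_id", "ewe_id", "arm", "sex", "delivery_order", "birthweight_kg",
    "cord_ph", "cord_paco2", "paco2_30min", "pip", "peep", "rate",
    "plasma_beta", "lung_beta",
]

BELOW_LOD = "<LOD"


@dataclass(frozen=True)
class CutoffResult:
    """Control-referenced responder cut-off: mean − multiplier × SD."""

    control_mean: float
    control_sd: float
    sd_multiplier: float
    cutoff: float
    n_controls: int

    def to_dict(self) -> dict:
        return {
            "control_mean": self.control_mean,
            "control_sd": self.control_sd,
            "sd_multiplier": self.sd_multiplier,
            "cutoff": self.cutoff,
            "n_controls": self.n_controls,
        }


@dataclass(frozen=True)
class GroupSummary:
    """Per-stratum summary: n, PaCO2 moments, responder count and rate."""

    label: str
    n: int
    mean: float
    sd: float | None
    responders: int | None = None
    response_rate: float | None = None  # percent


def compute_vei(settings: VentilationSettings, paco2) -> np.ndarray | float:
    """Ventilation efficacy index: constant / [rate × (PIP − PEEP) × PaCO2].

    Strictly decreasing in rate, driving pressure and PaCO2; accepts a
    scalar or an array of PaCO2 values (mmHg).
    """
    if settings.pip <= settings.peep:
        raise DomainError("compute_vei: PIP must exceed PEEP")
    paco2 = np.asarray(paco2, dtype=float)
    if np.any(paco2 <= 0):
        raise DomainError("compute_vei: PaCO2 must be positive")
    vei = settings.vei_constant / (settings.rate * (settings.pip - settings.peep) * paco2)
    return vei.item() if vei.ndim == 0 else vei


def derive_cutoff(
    control_paco2, sd_multiplier: float = 2.0
) -> CutoffResult:
    """Responder cut-off from raw control 30-min PaCO2 values.

    Uses the sample SD (n−1 denominator).  Requires at least two
    control values.
    """
    values = np.asarray(list(control_paco2), dtype=float)
    if values.size < 2:
        raise InsufficientDataError(
            f"derive_cutoff: need >= 2 control values, got {values.size}"
        )
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return CutoffResult(
        control_mean=mean,
        control_sd=sd,
        sd_multiplier=float(sd_multiplier),
        cutoff=mean - float(sd_multiplier) * sd,
        n_controls=int(values.size),
    )


def classify_responder(paco2: float, cutoff: float) -> str:
    """'responder' iff PaCO2 is strictly below the cut-off.

    A value exactly at the cut-off is a non-responder: the responder
    definition is strictly "more extreme than" the 2-SD bound.
    """
    if paco2 <= 0 or cutoff <= 0:
        raise DomainError("classify_responder: values must be positive")
    return "responder" if paco2 < cutoff else "non-responder"


def classify_cohort(
    pheno: pd.DataFrame, config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, CutoffResult]:
    """Derive the control cut-off and classify every treated fetus.

    Controls from both sexes are pooled to derive the cut-off.  Returns
    a copy of the phenotype table with a ``responder`` column taking
    values ``yes`` / ``no`` for treated fetuses and ``not-applicable``
    for controls, plus the :class:`CutoffResult`.
    """
    config = config or AnalysisConfig()
    controls = pheno.loc[pheno["arm"] == "CONTROL", "paco2_30min"]
    cut = derive_cutoff(controls, sd_multiplier=config.sd_multiplier)
    out = pheno.copy()
    treated = out["arm"] != "CONTROL"
    out["responder"] = np.where(
        ~treated,
        "not-applicable",
        np.where(out["paco2_30min"] < cut.cutoff, "yes", "no"),
    )
    return out, cut


def pooled_moments(groups: list[GroupSummary], label: str = "pooled") -> GroupSummary:
    """Combine per-group means/SDs/ns into the overall mean and SD.

    The pooled mean is the n-weighted mean; the pooled variance combines
    within-group sums of squares and between-group mean dispersion:

        s² = [Σ(nᵢ−1)sᵢ² + Σnᵢ(mᵢ−m̄)²] / (N−1)

    which equals the sample variance of the concatenated raw values.
    Groups of size 1 contribute no within-group term (their SD may be
    None).
    """
    if not groups:
        raise InsufficientDataError("pooled_moments: empty group list")
    for g in groups:
        if g.n < 1:
            raise InsufficientDataError(f"pooled_moments: group {g.label} has n < 1")
        if g.n >= 2 and g.sd is None:
            raise InsufficientDataError(
                f"pooled_moments: group {g.label} with n >= 2 lacks an SD"
            )
    total_n = sum(g.n for g in groups)
    mean = sum(g.n * g.mean for g in groups) / total_n
    if total_n < 2:
        return GroupSummary(label=label, n=total_n, mean=mean, sd=None)
    within = sum((g.n - 1) * g.sd**2 for g in groups if g.n >= 2)
    between = sum(g.n * (g.mean - mean) ** 2 for g in groups)
    sd = float(np.sqrt((within + between) / (total_n - 1)))
    responders = (
        sum(g.responders for g in groups)
        if all(g.responders is not None for g in groups)
        else None
    )
    rate = 100.0 * responders / total_n if responders is not None else None
    return GroupSummary(
        label=label, n=total_n, mean=float(mean), sd=sd,
        responders=responders, response_rate=rate,
    )


def summarize_groups(records: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    """Per-stratum PaCO2 moments and response rates, Table-3 style.

    Strata are defined by ``keys`` (e.g. ``["arm", "sex"]``).  Response
    rates are computed over classified fetuses only (``responder`` in
    {yes, no}); a stratum of pure controls gets no rate.  Rates are
    carried as exact percentages; rounding is a display concern.
    """
    if records.empty:
        raise InsufficientDataError("summarize_groups: no records")
    for key in keys:
        if key not in records.columns:
            raise KeyError(f"summarize_groups: unknown grouping key {key!r}")

    rows = []
    for label, grp in records.groupby(keys, sort=True, observed=True):
        label = label if isinstance(label, tuple) else (label,)
        n = len(grp)
        paco2 = grp["paco2_30min"].astype(float)
        classified = grp["responder"].isin(["yes", "no"]) if "responder" in grp else pd.Series(False, index=grp.index)
        n_classified = int(classified.sum())
        responders = int((grp.loc[classified, "responder"] == "yes").sum()) if n_classified else None
        rows.append(
            {
                **dict(zip(keys, label)),
                "n": n,
                "mean": float(paco2.mean()),
                "sd": float(paco2.std(ddof=1)) if n >= 2 else None,
                "responders": responders,
                "n_classified": n_classified if n_classified else None,
                "response_rate": (100.0 * responders / n_classified) if n_classified else None,
            }
        )
    return pd.DataFrame(rows)


def write_phenotypes(pheno: pd.DataFrame, path) -> Path:
    """Write the standard phenotype CSV (below-LOD drug values as ``<LOD``).

    Only the canonical columns are written; in-memory extras (truth,
    VEI) stay in memory.
    """
    out = pheno.copy()
    for col in ("plasma_beta", "lung_beta"):
        out[col] = out[col].map(
            lambda v: BELOW_LOD if pd.isna(v) else format(float(v), "g")
        )
    out[PHENO_COLUMNS].to_csv(path, index=False)
    return Path(path)


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype CSV; ``<LOD`` drug entries become NaN with flags.

    Adds boolean ``plasma_below_lod`` / ``lung_below_lod`` columns so
    censoring survives the round trip.
    """
    df = pd.read_csv(path, dtype={"fetus_id": str, "ewe_id": str})
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"read_phenotypes: missing columns {missing}")
    for col, flag in (("plasma_beta", "plasma_below_lod"), ("lung_beta", "lung_below_lod")):
        raw = df[col].astype(str).str.strip()
        df[flag] = raw == BELOW_LOD
        df[col] = pd.to_numeric(raw.where(~df[flag]), errors="raise")
    df["delivery_order"] = df["delivery_order"].astype(int)
    return df
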