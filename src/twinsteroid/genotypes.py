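"""Genotype I/O, QC filtering and twin zygosity classification.

File formats (tab-separated, plain text):

* SNP manifest — ``snp_id  chromosome  position  gentrain  gene  consequence``
* genotype final report — ``sample_id  snp_id  allele1  allele2  gc_score``

Alleles are abstract ``A``/``B`` chip calls; a no-call is ``-  -``.
QC follows the two published filters, both strict: drop every SNP whose
GenTrain score is not above 0.7 (removing all its calls), then drop any
remaining call whose GC score is not above 0.15.

Zygosity is called from post-QC genotype concordance between co-called
SNPs: pairs with unordered-genotype concordance strictly greater than
0.9 are monozygotic, all others dizygotic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import ParseError, UndefinedStatisticError

__all__ = [
    "MANIFEST_COLUMNS",
    "GENO_COLUMNS",
    "QCReport",
    "read_snp_manifest",
    "write_snp_manifest",
    "read_genotype_report",
    "write_genotype_report",
    "qc_filter",
    "pair_concordance",
    "classify_zygosity",
    "classify_pairs",
]

MANIFEST_COLUMNS = ["snp_id", "chromosome", "position", "gentrain", "gene", "consequence"]
GENO_COLUMNS = ["sample_id", "snp_id", "allele1", "allele2", "gc_score"]

_VALID_ALLELES = {"A", "B", "-"}


@dataclass(frozen=True)
class QCReport:
    """Record counts at each QC step."""

    n_snps_total: int
    n_snps_pass_gentrain: int
    n_calls_input: int
    n_calls_after_snp_filter: int
    n_calls_pass_gc: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def write_snp_manifest(manifest: pd.DataFrame, path) -> Path:
    manifest[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)
    return Path(path)


def read_snp_manifest(path) -> pd.DataFrame:
    """Parse and validate a SNP manifest TSV.

    Rejects a wrong header, duplicate SNP ids, non-positive positions
    and GenTrain scores outside [0, 1]; parse errors carry the 1-based
    line number of the offending row.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", dtype={"snp_id": str, "chromosome": str, "gene": str,
                                   "consequence": str},
            keep_default_na=False,
        )
    except Exception as exc:  # malformed TSV
        raise ParseError(f"{path}: cannot parse manifest: {exc}") from exc
    if list(df.columns) != MANIFEST_COLUMNS:
        raise ParseError(
            f"{path}: manifest header must be {MANIFEST_COLUMNS}, got {list(df.columns)}"
        )
    for col, caster in (("position", int), ("gentrain", float)):
        try:
            df[col] = df[col].map(caster)
        except (TypeError, ValueError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise ParseError(f"{path}: line {line}: bad {col} value") from exc
    dup = df["snp_id"].duplicated()
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise ParseError(f"{path}: line {line}: duplicate snp_id {df.loc[dup, 'snp_id'].iloc[0]!r}")
    bad_pos = df["position"] < 1
    if bad_pos.any():
        line = int(df.index[bad_pos][0]) + 2
        raise ParseError(f"{path}: line {line}: position must be >= 1")
    bad_gt = (df["gentrain"] < 0) | (df["gentrain"] > 1)
    if bad_gt.any():
        line = int(df.index[bad_gt][0]) + 2
        raise ParseError(f"{path}: line {line}: gentrain outside [0, 1]")
    return df


def write_genotype_report(calls: pd.DataFrame, path) -> Path:
    calls[GENO_COLUMNS].to_csv(path, sep="\t", index=False)
    return Path(path)


def read_genotype_report(path) -> pd.DataFrame:
    """Parse a final-report-style genotype TSV.

    Allele labels must come from {A, B, -}; the two alleles of a call
    must be both present or both missing; GC scores must lie in [0, 1].
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "snp_id": str,
                                                "allele1": str, "allele2": str})
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse genotype report: {exc}") from exc
    if list(df.columns) != GENO_COLUMNS:
        raise ParseError(
            f"{path}: genotype header must be {GENO_COLUMNS}, got {list(df.columns)}"
        )
    if df.empty:
        return df
    for col in ("allele1", "allele2"):
        bad = ~df[col].isin(_VALID_ALLELES)
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise ParseError(
                f"{path}: line {line}: allele label {df.loc[bad, col].iloc[0]!r} "
                "outside {A, B, -}"
            )
    half = (df["allele1"] == "-") != (df["allele2"] == "-")
    if half.any():
        line = int(df.index[half][0]) + 2
        raise ParseError(f"{path}: line {line}: alleles must be both present or both missing")
    gc = pd.to_numeric(df["gc_score"], errors="coerce")
    bad_gc = gc.isna() | (gc < 0) | (gc > 1)
    if bad_gc.any():
        line = int(df.index[bad_gc][0]) + 2
        raise ParseError(f"{path}: line {line}: gc_score outside [0, 1]")
    df["gc_score"] = gc
    return df


def qc_filter(
    calls: pd.DataFrame, manifest: pd.DataFrame, config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the two-step QC: SNP-level GenTrain, then call-level GC.

    Both thresholds are strict ("above"): a SNP at GenTrain exactly 0.7
    is dropped with all its calls, and a call at GC exactly 0.15 is
    dropped.  Idempotent by construction.
    """
    config = config or AnalysisConfig()
    gentrain = manifest.set_index("snp_id")["gentrain"]
    keep_snps = set(gentrain.index[gentrain > config.gentrain_min])
    n_calls_input = len(calls)
    after_snp = calls[calls["snp_id"].isin(keep_snps)]
    passed = after_snp[after_snp["gc_score"] > config.gc_min].reset_index(drop=True)
    report = QCReport(
        n_snps_total=int(len(manifest)),
        n_snps_pass_gentrain=int(len(keep_snps)),
        n_calls_input=n_calls_input,
        n_calls_after_snp_filter=int(len(after_snp)),
        n_calls_pass_gc=int(len(passed)),
    )
    return passed, report


def _genotype_codes(calls: pd.DataFrame) -> pd.Series:
    """Unordered genotype per call (AB ≡ BA), indexed by snp_id; no-calls dropped."""
    called = calls[(calls["allele1"] != "-") & (calls["allele2"] != "-")]
    a = called["allele1"].to_numpy(dtype="U1")
    b = called["allele2"].to_numpy(dtype="U1")
    swap = a > b
    lo = np.where(swap, b, a)
    hi = np.where(swap, a, b)
    return pd.Series(np.char.add(lo, hi), index=called["snp_id"].to_numpy())


def pair_concordance(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame
) -> tuple[float, int]:
    """Genotype concordance rate between two samples over co-called SNPs.

    Genotype identity is unordered allele-pair equality.  Symmetric in
    its arguments.  Raises if the samples share no called SNPs.
    """
    ga = _genotype_codes(calls_a)
    gb = _genotype_codes(calls_b)
    common = ga.index.intersection(gb.index)
    n = len(common)
    if n == 0:
        raise UndefinedStatisticError("pair_concordance: zero co-called SNPs")
    rate = float((ga.loc[common].to_numpy() == gb.loc[common].to_numpy()).mean())
    return rate, n


def concordance_from_dosages(d1: np.ndarray, d2: np.ndarray) -> tuple[float, int]:
    """Fast path on dosage vectors (−1 = missing)."""
    mask = (d1 >= 0) & (d2 >= 0)
    n = int(mask.sum())
    if n == 0:
        raise UndefinedStatisticError("pair_concordance: zero co-called SNPs")
    return float((d1[mask] == d2[mask]).mean()), n


def classify_zygosity(rate: float, config: AnalysisConfig | None = None) -> str:
    """MZ iff concordance is strictly greater than the threshold (0.9)."""
    config = config or AnalysisConfig()
    if not 0.0 <= rate <= 1.0:
        raise UndefinedStatisticError(f"classify_zygosity: rate {rate} outside [0, 1]")
    return "MZ" if rate > config.zygosity_threshold else "DZ"


def classify_pairs(
    calls: pd.DataFrame, pairs: pd.DataFrame, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Concordance and zygosity for every twin pair from a (post-QC) call table.

    ``pairs`` needs ``ewe_id, fetus_id_1, fetus_id_2``; the result adds
    ``concordance, n_compared, zygosity``.
    """
    config = config or AnalysisConfig()
    by_sample = dict(tuple(calls.groupby("sample_id", sort=False)))
    empty = calls.iloc[0:0]
    rows = []
    for row in pairs.itertuples():
        rate, n = pair_concordance(
            by_sample.get(row.fetus_id_1, empty), by_sample.get(row.fetus_id_2, empty)
        )
        rows.append(
            {
                "ewe_id": row.ewe_id,
                "fetus_id_1": row.fetus_id_1,
                "fetus_id_2": row.fetus_id_2,
                "concordance": rate,
                "n_compared": n,
                "zygosity": classify_zygosity(rate, config),
            }
        )
    out = pd.DataFrame(rows)
    for extra in ("arm", "twin_type"):
        if extra in pairs.columns:
            out[extra] = pairs[extra].to_numpy()
    return out
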