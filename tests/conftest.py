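import numpy as np
import pandas as pd
import pytest

from twinsteroid.config import AnalysisConfig, CohortConfig
from twinsteroid.syndata import simulate_cohort


@pytest.fixture(scope="session")
def analysis_cfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """Default-design cohort (31 pairs) on a small 300-SNP panel."""
    return simulate_cohort(CohortConfig(n_snps=300, seed=11))


@pytest.fixture(scope="session")
def noisy_cohort():
    """Cohort with call errors, missingness and a monozygotic fraction."""
    cfg = CohortConfig(
        n_snps=400, seed=5, genotype_error_rate=0.005, missing_rate=0.01,
        mz_fraction=0.3,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def toy_pheno():
    """Hand-built classified phenotype table: 3 treated pairs + 1 control pair."""
    rows = []
    data = [
        ("E1", "CS1", [("M", 1, "yes"), ("F", 2, "yes")]),
        ("E2", "CS1", [("F", 1, "yes"), ("M", 2, "no")]),
        ("E3", "CS2", [("M", 1, "no"), ("M", 2, "no")]),
        ("E4", "CONTROL", [("F", 1, "not-applicable"), ("F", 2, "not-applicable")]),
    ]
    for ewe, arm, twins in data:
        sexes = "".join(sorted((t[0] for t in twins), reverse=True)).replace("FM", "MF")
        for sex, order, resp in twins:
            rows.append(
                {
                    "fetus_id": f"{ewe}.{order}", "ewe_id": ewe, "arm": arm,
                    "sex": sex, "delivery_order": order, "twin_type": sexes,
                    "paco2_30min": 70.0 if resp == "yes" else 120.0,
                    "plasma_beta": np.nan if arm == "CONTROL" else 2.0,
                    "lung_beta": np.nan if arm == "CONTROL" else 30.0,
                    "responder": resp,
                }
            )
    return pd.DataFrame(rows)
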