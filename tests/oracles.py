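"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: exhaustive
enumeration for full-sib genotype sharing, scipy's contingency-table
test for the chi-square stage, and direct likelihood maximisation for
the logistic stage.
"""

from itertools import product

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2_contingency


def dz_concordance_expected(p: float) -> float:
    """Exact expected unordered-genotype concordance of full sibs at one SNP.

    Exhaustive enumeration over the four parental allele copies (each B
    with probability ``p`` under Hardy–Weinberg) and the 4 × 4 possible
    transmission choices of the two sibs.
    """
    total = 0.0
    for alleles in product([0, 1], repeat=4):  # sire a1 a2, dam a3 a4
        prob = 1.0
        for a in alleles:
            prob *= p if a else (1 - p)
        sire, dam = alleles[:2], alleles[2:]
        match = 0.0
        for i, j, k, l in product(range(2), repeat=4):
            s1 = sire[i] + dam[j]
            s2 = sire[k] + dam[l]
            match += (s1 == s2) / 16.0
        total += prob * match
    return total


def chisq_oracle(table) -> tuple[float, float]:
    """Pearson chi-square via scipy's contingency machinery (no correction)."""
    stat, p, _, _ = chi2_contingency(np.asarray(table, dtype=float), correction=False)
    return float(stat), float(p)


def logistic_mle_oracle(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Direct logistic maximum likelihood by numerical optimisation."""

    def nll(beta):
        eta = X @ beta
        return float(np.sum(np.log1p(np.exp(eta))) - y @ eta)

    best = None
    for start in (np.zeros(X.shape[1]), np.full(X.shape[1], 0.5)):
        res = minimize(nll, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        if best is None or res.fun < best.fun:
            best = res
    return best.x
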