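"""Generate a synthetic twin cohort and look at its structure.

The default configuration mirrors the twin-lamb betamethasone study
design: 11 + 10 + 10 twin pairs across single-dose (CS1), two-dose
(CS2) and saline-control arms, dizygotic twins, and a 5,000-SNP panel.
"""

from twinsteroid import CohortConfig, simulate_cohort

cohort = simulate_cohort(CohortConfig(n_snps=1000, seed=7))

print(f"fetuses: {cohort.n_fetuses}, twin pairs: {cohort.n_pairs}")
print(cohort.pairs["arm"].value_counts().to_string())
print("\nfirst twin pair (phenotypes):")
cols = ["fetus_id", "arm", "sex", "delivery_order", "paco2_30min", "plasma_beta"]
print(cohort.fetuses[cols].head(2).to_string(index=False))
print("\ntruth record keys:", sorted(cohort.truth)[:4], "...")
# PaCO2 is the 30-min ventilation outcome (mmHg, lower = more mature
# lungs); plasma_beta is fetal betamethasone at delivery (ng/mL, NaN =
# below the 0.5 ng/mL detection limit, e.g. all controls).
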