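"""Absolute quantification and stoichiometry by PRM with heavy peptides.

Simulates light/heavy chromatographic peak areas for USP30, TOMM20 and
TOMM70 (2, 2 and 6 heavy reference peptides) in purified mitochondria,
computes fmol per microgram for each protein, and derives the
USP30-to-translocon stoichiometry with propagated errors.  A stoichiometry
near 0.3 means roughly a third of translocon assemblies can carry an
associated USP30 molecule.
"""

from ubquant.flux import prm_abundance, stoichiometry
from ubquant.simulate import gen_prm_areas

table, truth = gen_prm_areas(
    proteins={"USP30": 3.0, "TOMM20": 10.0, "TOMM70": 8.0},
    peptides_per_protein={"USP30": 2, "TOMM20": 2, "TOMM70": 6},
    spike_fmol=50.0,
    noise_cv=0.02,
    seed=8,
)
abundances = {p: prm_abundance(g) for p, g in table.groupby("protein")}
print(f"{'protein':<8} {'fmol/ug':>9} {'SEM':>7} {'peptides':>9}")
for protein, (mean, sem) in abundances.items():
    n = (table["protein"] == protein).sum()
    print(f"{protein:<8} {mean:>9.2f} {sem:>7.3f} {n:>9}")

for ref in ("TOMM20", "TOMM70"):
    ratio, err = stoichiometry(abundances["USP30"], abundances[ref])
    print(f"USP30 : {ref} stoichiometry = {ratio:.3f} +/- {err:.3f}")
print("Both ratios sit near the planted values (0.30 and 0.375),")
print("recovered purely from light/heavy area ratios and the spike amount.")
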