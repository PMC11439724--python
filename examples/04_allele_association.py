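"""Case-control association of HLA alleles with a planted protective effect.

A synthetic cohort is generated with one allele (C*06:02-like, here labelled
A*02:01) given a true odds ratio of 0.4 for the CALR-mutant group.  Alleles
are screened (frequency >= 2%, exact Hardy-Weinberg p >= 0.1 in controls) and
tested in an additive logistic model with age and sex covariates.
"""

import numpy as np

from immunoedit import SimulationConfig, associate_alleles, simulate_cohort
from immunoedit.hla import Group, Locus

cfg = SimulationConfig(
    seed=7, n_calr=300, n_jak2=0, n_control=800,
    allele_spectra={Locus.A: {"A*01:01": 0.30, "A*02:01": 0.10,
                              "A*03:01": 0.35, "A*24:02": 0.25}},
    planted_effects={"CALR": {"A*02:01": float(np.log(0.4))}},
)
cohort = simulate_cohort(cfg)
table = associate_alleles(cohort, (Group.CALR, Group.CONTROL), loci=[Locus.A])
cols = ["term", "freq_case", "freq_control", "or", "ci_low", "ci_high", "p",
        "filter_status"]
print(table[cols].round(4).to_string(index=False))

hit = table.set_index("term").loc["A*02:01"]
print(f"\nplanted allele: OR {hit['or']:.2f} "
      f"(95% CI {hit['ci_low']:.2f}-{hit['ci_high']:.2f}), p = {hit['p']:.2e}")
# The planted protective allele is depleted among cases (case frequency below
# control frequency), its estimated OR sits near the true 0.4, and the other
# alleles stay near the null.
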