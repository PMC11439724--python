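"""Haplotype frequency estimation (EM) and score tests on unphased genotypes.

Phase is not observed, so two-locus haplotype frequencies are estimated by EM
under random mating; each haplotype is then tested with the imputed-dosage
score test (posterior expected copies against case status, adjusting for age
and sex under the null model).
"""

import numpy as np

from immunoedit import SimulationConfig, em_haplotype_frequencies, simulate_cohort
from immunoedit.haplotypes import haplotype_association_scan
from immunoedit.hla import Group, Locus

cfg = SimulationConfig(
    seed=17, n_calr=250, n_jak2=0, n_control=700,
    allele_spectra={Locus.A: {"A*01:01": 0.4, "A*02:01": 0.6},
                    Locus.B: {"B*07:02": 0.5, "B*08:01": 0.5},
                    Locus.C: {"C*06:02": 0.3, "C*07:01": 0.7}},
    planted_effects={"CALR": {"C*06:02": float(np.log(0.4))}},
)
cohort = simulate_cohort(cfg)

em = em_haplotype_frequencies(cohort, [Locus.A, Locus.C])
print("EM haplotype frequencies (A-C):")
for hap, freq in sorted(em.frequencies.items(), key=lambda kv: -kv[1]):
    print(f"  {'-'.join(str(a) for a in hap)}: {freq:.3f}")
print(f"EM converged in {len(em.log_likelihood_trace)} iterations")

scan = haplotype_association_scan(cohort, hla_class=1, arities=[2],
                                  comparison=(Group.CALR, Group.CONTROL))
top = scan.nsmallest(4, "p")[["loci", "haplotype", "freq", "score", "p"]]
print("\nmost associated bi-locus haplotypes:")
print(top.round(4).to_string(index=False))
# Haplotypes carrying the protective C*06:02 allele score negative (depleted
# in cases); the scan covers all three class I locus pairs.
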