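"""Score a subject's HLA class I genotype for neoantigen presentation.

Per allele the best rank (BR) is the minimum predictor percentile rank over a
mutation's peptides; per subject the PHBR is the harmonic mean of the six
class I allele BRs (homozygous alleles count twice).  A low PHBR means the
genotype presents at least one neoantigen from that mutation well.
"""

from immunoedit import (
    allele_best_ranks,
    calr_context,
    enumerate_neo_terminus,
    mock_rank_predictor,
    parse_allele,
    phbr,
)
from immunoedit.hla import Group, Locus, LocusGenotype, Subject

subject = Subject(
    "patient-1", "demo", Group.CALR, age=58, sex="F",
    genotypes={
        Locus.A: LocusGenotype(parse_allele("A*01:01"), parse_allele("A*02:01")),
        Locus.B: LocusGenotype(parse_allele("B*07:02"), parse_allele("B*07:02")),
        Locus.C: LocusGenotype(parse_allele("C*06:02"), parse_allele("C*07:01")),
    },
)

pset = enumerate_neo_terminus(calr_context())
alleles = subject.class_i_alleles()
# stand-in for an external predictor run; plant one strong binder
ranks = mock_rank_predictor(alleles, pset.peptide_strings(), seed=42,
                            planted={(parse_allele("C*06:02"), "RMMRTKMRM"): 0.12})

brs = allele_best_ranks(ranks, pset, alleles)
for allele, br in sorted(brs.items()):
    print(f"{allele}: BR = {br.br:6.3f}%  ({br.category.value})")

result = phbr(subject, brs, "CALRmut")
print(f"\nPHBR(CALRmut) = {result.phbr:.3f}% over {result.n_alleles_used} alleles")
# The harmonic mean sits near the smallest BR: one strong-binding allele
# (here the planted C*06:02 at rank 0.12%) is enough to pull the subject's
# presentation score down, i.e. the genotype can present this neoantigen.
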