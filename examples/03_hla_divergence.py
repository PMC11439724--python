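"""HLA evolutionary divergence (HED) from binding-groove sequences.

HED for a locus is the mean Grantham amino-acid distance across the aligned
positions of its two allele sequences: zero for homozygotes, larger the more
chemically different the two molecules are — a proxy for the breadth of the
peptide repertoire the locus can present.
"""

from immunoedit import (
    grantham_distance,
    parse_allele,
    simulate_sequences,
    subject_hed,
)
from immunoedit.hla import Group, Locus, LocusGenotype, Subject

print(f"Grantham d(L, I) = {grantham_distance('L', 'I'):.0f}   (similar residues)")
print(f"Grantham d(S, R) = {grantham_distance('S', 'R'):.0f}  (dissimilar residues)")

alleles = [parse_allele(s) for s in
           ("A*01:01", "A*02:01", "B*07:02", "B*08:01", "C*06:02", "C*07:01")]
db = simulate_sequences(alleles, length=90, divergence_scale=0.25, seed=3)

subject = Subject(
    "demo", "demo", Group.CONTROL,
    genotypes={
        Locus.A: LocusGenotype(alleles[0], alleles[1]),  # heterozygous
        Locus.B: LocusGenotype(alleles[2], alleles[3]),  # heterozygous
        Locus.C: LocusGenotype(alleles[4], alleles[4]),  # homozygous -> HED 0
    },
)
res = subject_hed(subject, db)
for locus, value in res.per_locus.items():
    print(f"HED {locus.value}: {value:.2f}")
print(f"mean class I HED: {res.mean_class_i:.2f}")
# The homozygous C locus contributes exactly 0; the class I mean averages the
# three locus values, so homozygosity directly lowers genotype diversity.
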