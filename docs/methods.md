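# Methods

`immunoedit` implements an immunogenetic restriction analysis for
myeloproliferative neoplasm (MPN) driver mutations: it asks whether a
person's HLA class I genotype, through its predicted ability to present
mutation-derived neoantigens, shapes which driver mutation (CALR exon 9
frameshift vs JAK2 V617F) can establish a clone. The package covers the full
desk-side analysis: neoantigen candidate enumeration, presentation scoring,
genotype-diversity quantification, case-control association with QC filters,
haplotype inference and testing, multi-cohort pooling, and a synthetic-data
generator that makes every stage testable without patient data.

## Neoantigen candidate enumeration

Two mutant-sequence shapes occur. The recurrent CALR exon 9 frameshifts
converge on one shared novel ("neomorphic") C-terminal tail of 44 residues,
shipped as a built-in constant; every k-mer window of the tail (k = 8..11
for class I, 44 − k + 1 windows per k, 142 in total) is a candidate. JAK2
V617F is a point substitution, so only windows covering the mutated residue
qualify: with full flanks that is k windows per length, 38 in total for
k = 8..11; near sequence ends the set is clipped to valid windows. A 15-mer
mode produces class II predictor input.

Counts are *positional* — windows at distinct (start, length) are distinct
even when the repetitive arginine/methionine-rich tail repeats a substring —
because the combinatorial identities above hold for windows, not for unique
strings. Peptides are deduplicated only when handed to a predictor.
Coordinates are 1-based and inclusive everywhere.

The JAK2 context constant covers residues 591–640 of the human protein with
phenylalanine substituted at 617. Window counts depend only on the mutated
residue having at least 10 flanking residues on each side, which any
user-supplied context can also satisfy.

## Presentation scoring

Binding predictions enter as percentile ranks in (0, 100] per (allele,
peptide) pair — the package never re-implements a neural binding predictor;
it parses the external predictor's tab export or a plain
`allele / peptide / percent_rank` TSV, and ships a deterministic hash-based
mock predictor for tests. Per allele and mutation the **best rank** (BR) is
the minimum rank over the mutation's peptides. Per subject the **PHBR**
(patient harmonic-mean best rank) is the harmonic mean of the six class I
allele BRs, homozygous alleles contributing twice:

    PHBR = 6 / Σ_i (1 / BR_i),   i over the subject's six class I alleles.

The harmonic mean is dominated by its smallest term, so one well-presenting
allele is enough to give a low (good) PHBR — the intended biology. Missing
predictions fail loudly by default; an opt-in flag treats missing peptides
as rank 100 for robustness experiments. Binder categories use the
predictor's standard thresholds with inclusive boundaries: SB iff BR ≤ 0.5,
WB iff 0.5 < BR ≤ 2.0, NB otherwise.

One wording ambiguity was resolved deliberately: BR is computed per
*allele* (not per locus), and PHBR aggregates the six allele BRs — the
construction used throughout the PHBR literature; a per-locus minimum would
discard the homozygosity penalty that PHBR is designed to carry.

## HLA evolutionary divergence (HED)

HED for one locus is the mean Grantham distance across aligned positions of
the two allele sequences; it is 0 for homozygotes by definition, and class
means average the three class I or four class II locus values (suppressed if
any constituent locus is missing). The shipped 20×20 integer matrix is
generated from Grantham's 1974 formula

    D(a,b) = ρ [α(c_a−c_b)² + β(p_a−p_b)² + γ(v_a−v_b)²]^½

with the published composition/polarity/volume values, α = 1.833,
β = 0.1018, γ = 0.000399, ρ = 50.723 (mean over the 190 pairs = 100),
rounded to the nearest integer; the unrounded formula is exposed as the
validation oracle and the declared rounding tolerance is 0.5. A few entries
differ by one unit from the historical printed table, which rounded
inconsistently; the formula is taken as ground truth.

Sequence input is an IMGT-style protein FASTA; per two-field allele the
first full-length record wins (reference-allele convention). The
binding-groove residue range to extract is configurable per locus and
defaults to the full loaded sequence — published HED pipelines restrict to
the peptide-binding domains (α1/α2 for class I), and users reproducing that
behaviour should pass the corresponding ranges; records with indels (length
mismatch after extraction) are rejected with the offending alleles listed
rather than aligned on the fly.

## Allele and category association

Per locus, each allele is coded additively (0/1/2 copies) and screened
before testing: overall frequency ≥ 2% and exact Hardy–Weinberg p ≥ 0.1 in
the control stratum (configurable). The HWE rule is read as *excluding*
alleles that deviate significantly from equilibrium — the standard QC
direction; the literal opposite reading would discard exactly the
well-behaved alleles. The exact test is the conditional test on heterozygote
counts given allele counts, computed by a numerically stable two-sided
recurrence from the distribution's mode; the p-value sums all configurations
no more likely than the observed one, with a 10⁻⁷ relative tie guard so
mathematically tied configurations are never split by rounding.

Tested alleles enter a logistic model
`logit P(case) = β₀ + β_d·dosage + β_age·age + β_sex·sex` (sex a single
M=1 indicator; subjects missing a covariate are dropped from that model
only), fitted by maximum likelihood via statsmodels, with a two-sided Wald
test and ±1.96·SE confidence bounds on β_d. Separation and non-convergence
(including SE > 50 on the log-odds scale) yield a `NOT_CONVERGED` row
without estimates; excluded alleles keep rows with their exclusion reason so
filter provenance survives into the output. p-values are reported
unadjusted at α = 0.05 (the study design's convention), with a
Benjamini–Hochberg column provided alongside.

Category association replaces allele dosage by the number of the subject's
six class I alleles annotated SB/WB/NB for a mutation (so per mutation each
complete subject's category dosages sum to 6) and applies no
frequency/HWE exclusion. Zero-variance categories are flagged, not tested.

## Haplotype analysis

Unphased genotypes over 2–4 loci are expanded into their 2^(h−1) consistent
diplotypes (h heterozygous loci; a safety cap guards pathological inputs).
EM alternates posterior diplotype assignment (product of haplotype
frequencies under random mating, ×2 for distinct ordered pairs) with
frequency re-estimation from expected counts; initialization is the
deterministic product of marginal allele frequencies, which also resolves
likelihood ties reproducibly. The log-likelihood is non-decreasing by
construction and iteration stops at a change < 10⁻⁸ or 1000 iterations;
haplotypes below 10⁻⁶ are pruned and frequencies renormalized.

Association uses the imputed-dosage score test: with the null logistic model
(intercept + age + sex) fitted once, each haplotype's posterior expected
dosage d gives the score U = Σ dᵢ(yᵢ − p̂ᵢ) with variance
V = dᵀWd − dᵀWX (XᵀWX)⁻¹ XᵀWd (W = diag(p̂(1−p̂))), and U²/V is χ²₁ under
the null; the signed z = U/√V and a one-step effect U/V are reported. This
is the score construction of the established haplotype-association method;
exact small-sample behaviour of that package's permutation options is not
replicated. Haplotypes below 1% estimated frequency are not tested (the
reporting convention for non-rare haplotypes); the threshold is an argument.
The scan runs every locus combination of the requested arities within one
HLA class, subjects being dropped per combination (not globally) when
untyped at a scanned locus.

## Pooling and the presentation trade-off

Multi-cohort pooling concatenates cohorts, prefixes subject ids, and keeps
the cohort label; pooled association adds fixed-effect cohort indicator
covariates so between-cohort frequency differences cannot masquerade as
case-control effects (with a single cohort the indicator is dropped and the
result equals the single-cohort analysis). No random-effects meta-analysis
is attempted. Note that pooling populations with different allele
frequencies induces a Wahlund heterozygote deficit; if the HWE screen is
applied to the pooled sample it will legitimately exclude such alleles, so
pooled analyses default to screening within the comparison sample and users
can relax `hwe_alpha` when the deficit is by design.

The cross-mutation analysis computes, per group, the two-sided Pearson
correlation between subjects' PHBR for the CALR neo-tail and for JAK2
V617F (t-distribution p; raw PHBR scale by default, log10 optional). A
negative correlation means genotypes good at presenting one mutation's
neoantigens tend to be worse at the other's.

## Synthetic-data generator

The generator's defaults mirror the analysed study design: group sizes
42 CALR-mutant / 158 JAK2 V617F / 1,083 controls; seven-locus genotypes
drawn from explicit spectra or Dirichlet-sampled skewed spectra (default
concentration 0.4 over 8–25 alleles per locus, the shape of real HLA
spectra); optional multi-locus haplotype frequencies to induce LD; an
inbreeding knob f that copies the second allele with probability f per
locus, producing the heterozygote deficit the HWE filter exists to catch.

Phenotypes follow a multinomial-logistic model with CONTROL as reference:
planted per-allele log-odds ratios, an age effect of 0.02/year and a male
effect of 0.3 on each patient group, ages normal (mean 55, SD 15) truncated
to [18, 95], sexes balanced. The two patient groups together occupy 5% of
the source population (MPNs are rare; this keeps the control stratum
representative, so planted effects do not distort control-group HWE through
outcome-dependent sampling), and quotas are filled by rejection sampling —
which preserves covariate-conditional odds ratios exactly, the classic
case-control property the association analysis relies on.

Rank tables plant the presentation trade-off at the allele level (PHBR
depends on ranks only through allele BRs): per allele a latent bivariate
normal with correlation ρ (default −0.6) is mapped through its CDF to
log10-uniform BRs in [0.01, 100] per mutation, and peptide ranks are filled
so the minimum over each mutation's peptides equals the drawn BR exactly —
making the drawn truth mechanically recoverable. Sequences for HED tests
are per-locus random bases with per-site substitution probability equal to
the divergence scale. All draws funnel through one integer seed; the
fixture-suite manifest records every planted parameter.

What the generator does *not* emulate: real HLA linkage structure beyond
one explicit haplotype table, population stratification within a cohort,
genotyping error/ambiguity, realistic per-allele binding biology (ranks are
exchangeable given the planted BR), or age/sex-dependent allele
frequencies. Passing tests therefore demonstrate statistical correctness of
the machinery under its stated model, not field performance on real
cohorts.

## Problem sizes and numerical conventions

The simulation-backed checks use desk-scale designs chosen once: null
calibration over 2,000 replicates of 200 cases / 400 controls at one locus
with four common alleles (0.4/0.3/0.2/0.1); CI coverage over 200 replicates
of 400 / 1,000 with a planted OR 0.4 at 10% frequency; trade-off recovery
over 50 seeds of 200 subjects with ρ = −0.6. The exact-HWE oracle
comparison covers every genotype triple with total ≤ 200 by grouping
triples that share a conditional distribution. Pipeline outputs format
floats as `%.10g` with deterministic row order, and the run manifest
records parameters, seed and input SHA-256 checksums but no timestamps, so
identical config + inputs ⇒ byte-identical outputs.

## Known limitations

Two-field allele resolution is the entire universe; G/P-groups and
higher-field distinctions are out of scope, as is calling genotypes from
sequencing reads. Class II PHBR is not computed (enumeration only). The
Wald-based inference is asymptotic; very rare alleles that survive the 2%
filter in small cohorts can still yield unstable fits, which are flagged
rather than silently dropped. The EM treats subjects as unrelated and
mating as random; the score test conditions on the EM point estimate and
ignores haplotype-frequency uncertainty, as the cited methodology does.
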