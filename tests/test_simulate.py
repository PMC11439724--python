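import numpy as np
import pytest

from immunoedit.association import hwe_exact_test, hwe_genotype_counts, filter_alleles
from immunoedit.hed import locus_hed
from immunoedit.hla import (
    CLASS_I_LOCI,
    Group,
    Locus,
    parse_allele,
    read_genotype_table,
    read_imgt_protein_fasta,
)
from immunoedit.peptides import (
    calr_context,
    enumerate_neo_terminus,
    enumerate_point_mutation,
    jak2_context,
)
from immunoedit.presentation import best_rank, read_rank_table
from immunoedit.simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_genotypes,
    simulate_rank_table,
    simulate_sequences,
)


class TestDeterminism:
    def test_genotypes_reproducible(self):
        cfg = SimulationConfig(seed=5)
        c1 = simulate_genotypes(cfg, n=50)
        c2 = simulate_genotypes(cfg, n=50)
        for s1, s2 in zip(c1, c2):
            assert s1.genotypes == s2.genotypes

    def test_cohort_reproducible(self):
        cfg = SimulationConfig(seed=5, n_calr=10, n_jak2=15, n_control=40)
        c1, c2 = simulate_cohort(cfg), simulate_cohort(cfg)
        assert [(s.subject_id, s.group, s.age, s.sex) for s in c1] == \
               [(s.subject_id, s.group, s.age, s.sex) for s in c2]

    def test_rank_table_reproducible(self):
        cfg = SimulationConfig(seed=5)
        psets = {"CALRmut": enumerate_neo_terminus(calr_context()),
                 "JAK2V617F": enumerate_point_mutation(jak2_context())}
        alleles = [parse_allele(f"A*{i:02d}:01") for i in range(1, 6)]
        t1, truth1 = simulate_rank_table(alleles, psets, cfg)
        t2, truth2 = simulate_rank_table(alleles, psets, cfg)
        assert truth1 == truth2
        for mut in psets:
            assert dict(t1[mut].items()) == dict(t2[mut].items())


class TestGenotypeStructure:
    def test_hwe_consistent_without_inbreeding(self):
        """Under f = 0 the per-allele HWE exact p-values behave like a null
        test: few fall under 0.05 (the exact test is conservative)."""
        spectrum = {Locus.A: {"A*01:01": 0.5, "A*02:01": 0.3, "A*03:01": 0.2}}
        ps = []
        for seed in range(60):
            cfg = SimulationConfig(seed=seed, allele_spectra=spectrum, inbreeding_f=0.0)
            cohort = simulate_genotypes(cfg, n=400)
            for name in spectrum[Locus.A]:
                ps.append(hwe_exact_test(*hwe_genotype_counts(cohort, parse_allele(name))))
        ps = np.array(ps)
        assert (ps < 0.05).mean() < 0.10
        assert ps.mean() > 0.3  # far from degenerate

    def test_inbreeding_produces_het_deficit_and_triggers_filter(self):
        spectrum = {Locus.A: {"A*01:01": 0.5, "A*02:01": 0.5}}
        cfg = SimulationConfig(seed=1, allele_spectra=spectrum, inbreeding_f=0.3)
        cohort = simulate_genotypes(cfg, n=500)
        n_aa, n_ab, n_bb = hwe_genotype_counts(cohort, parse_allele("A*01:01"))
        n = n_aa + n_ab + n_bb
        p = (2 * n_aa + n_ab) / (2 * n)
        assert n_ab / n < 2 * p * (1 - p) * 0.85  # marked heterozygote deficit
        filt = filter_alleles(cohort, hwe_group=None, loci=[Locus.A])
        assert (filt["status"] == "EXCLUDED_HWE").all()

    def test_haplotype_table_induces_ld(self):
        freqs = {("A*01:01", "B*07:02"): 0.45, ("A*02:01", "B*08:01"): 0.45,
                 ("A*01:01", "B*08:01"): 0.05, ("A*02:01", "B*07:02"): 0.05}
        cfg = SimulationConfig(seed=4, haplotype_loci=(Locus.A, Locus.B),
                               haplotype_freqs=freqs,
                               allele_spectra={Locus.A: {"A*01:01": 0.5, "A*02:01": 0.5},
                                               Locus.B: {"B*07:02": 0.5, "B*08:01": 0.5}})
        cohort = simulate_genotypes(cfg, n=400)
        # coupled alleles co-occur far more often than under independence
        both = sum(1 for s in cohort
                   if s.genotypes[Locus.A].dosage(parse_allele("A*01:01")) == 2
                   and s.genotypes[Locus.B].dosage(parse_allele("B*07:02")) == 2)
        assert both / 400 > 0.10  # independence would give ~0.0625 * 0.0625


class TestPhenotypes:
    def test_null_effects_equal_frequencies(self):
        spectrum = {Locus.A: {"A*01:01": 0.5, "A*02:01": 0.5}}
        diffs = []
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, n_calr=200, n_jak2=0, n_control=200,
                                   allele_spectra=spectrum)
            cohort = simulate_cohort(cfg)
            freq = {}
            for grp in (Group.CALR, Group.CONTROL):
                sub = [s for s in cohort if s.group is grp]
                freq[grp] = np.mean([s.genotypes[Locus.A].dosage(parse_allele("A*01:01"))
                                     for s in sub]) / 2
            diffs.append(freq[Group.CALR] - freq[Group.CONTROL])
        assert abs(np.mean(diffs)) < 0.02

    def test_protective_effect_lowers_case_frequency(self):
        spectrum = {Locus.A: {"A*01:01": 0.2, "A*02:01": 0.8}}
        cfg = SimulationConfig(seed=8, n_calr=400, n_jak2=0, n_control=800,
                               allele_spectra=spectrum,
                               planted_effects={"CALR": {"A*01:01": float(np.log(0.4))}})
        cohort = simulate_cohort(cfg)
        freq = {}
        for grp in (Group.CALR, Group.CONTROL):
            sub = [s for s in cohort if s.group is grp]
            freq[grp] = np.mean([s.genotypes[Locus.A].dosage(parse_allele("A*01:01"))
                                 for s in sub]) / 2
        assert freq[Group.CALR] < freq[Group.CONTROL] - 0.03

    def test_ages_within_bounds_and_groups_exact(self):
        cfg = SimulationConfig(seed=2, n_calr=30, n_jak2=40, n_control=100)
        cohort = simulate_cohort(cfg)
        counts = cohort.group_counts()
        assert counts[Group.CALR] == 30
        assert counts[Group.JAK2] == 40
        assert counts[Group.CONTROL] == 100
        assert all(18 <= s.age <= 95 for s in cohort)
        assert all(s.sex in ("M", "F") for s in cohort)


class TestRankModel:
    def _psets(self):
        return {"CALRmut": enumerate_neo_terminus(calr_context()),
                "JAK2V617F": enumerate_point_mutation(jak2_context())}

    def test_best_rank_recovers_drawn_brs_exactly(self):
        cfg = SimulationConfig(seed=6)
        alleles = [parse_allele(f"B*{i:02d}:01") for i in range(1, 21)]
        psets = self._psets()
        tables, truth = simulate_rank_table(alleles, psets, cfg)
        for allele in alleles:
            for mut, pset in psets.items():
                assert best_rank(tables[mut], allele, pset).br == truth[allele][mut]

    def test_degenerate_rho_minus_one(self):
        cfg = SimulationConfig(seed=7, rank_correlation_rho=-1.0)
        alleles = [parse_allele(f"A*{i:02d}:01") for i in range(1, 60)]
        _, truth = simulate_rank_table(alleles, self._psets(), cfg)
        x = np.log10([truth[a]["CALRmut"] for a in alleles])
        y = np.log10([truth[a]["JAK2V617F"] for a in alleles])
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(-1.0, abs=0.02)

    def test_rho_recovered_within_sampling_error(self):
        cfg = SimulationConfig(seed=8, rank_correlation_rho=-0.6)
        alleles = [parse_allele(f"A*{i:02d}:01") for i in range(1, 201)]
        _, truth = simulate_rank_table(alleles, self._psets(), cfg)
        x = np.log10([truth[a]["CALRmut"] for a in alleles])
        y = np.log10([truth[a]["JAK2V617F"] for a in alleles])
        # rank correlation of the log-uniform BRs tracks the latent normal rho
        assert abs(np.corrcoef(x, y)[0, 1] - (-0.6)) < 0.15

    def test_empty_peptide_set_rejected(self):
        from immunoedit.peptides import PeptideSet

        cfg = SimulationConfig(seed=1)
        empty = {"CALRmut": PeptideSet("CALRmut", []),
                 "JAK2V617F": self._psets()["JAK2V617F"]}
        with pytest.raises(ValueError, match="empty"):
            simulate_rank_table([parse_allele("A*01:01")], empty, cfg)


class TestSequences:
    def test_zero_divergence_identical(self):
        alleles = [parse_allele("A*01:01"), parse_allele("A*02:01")]
        db = simulate_sequences(alleles, length=60, divergence_scale=0.0, seed=1)
        assert db[alleles[0]] == db[alleles[1]]
        assert locus_hed(db[alleles[0]], db[alleles[1]]) == 0.0

    def test_mean_hed_monotone_in_scale(self):
        alleles = [parse_allele(f"A*{i:02d}:01") for i in range(1, 11)]
        means = []
        for scale in (0.05, 0.2, 0.5):
            db = simulate_sequences(alleles, length=80, divergence_scale=scale, seed=2)
            import itertools

            vals = [locus_hed(db[a], db[b]) for a, b in itertools.combinations(alleles, 2)]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_reproducible(self):
        alleles = [parse_allele("C*07:01")]
        d1 = simulate_sequences(alleles, seed=3)
        d2 = simulate_sequences(alleles, seed=3)
        assert d1[alleles[0]] == d2[alleles[0]]


class TestFixtureSuite:
    def test_loads_through_every_reader(self, fixture_suite):
        out, manifest = fixture_suite
        cohorts = [read_genotype_table(out / f) for f in manifest["files"]["genotypes"]]
        assert all(len(c) > 0 for c in cohorts)
        db = read_imgt_protein_fasta(out / manifest["files"]["sequences"])
        assert len(db) > 0
        for f in manifest["files"]["ranks"]:
            table = read_rank_table(out / f, "simple_tsv")
            assert len(table) > 0

    def test_manifest_records_planted_truth(self, fixture_suite):
        _, manifest = fixture_suite
        assert manifest["seed"] == 11
        assert manifest["planted_odds_ratio"] == 0.4
        assert manifest["rank_correlation_rho"] == -0.6
        assert manifest["planted_protective_allele"] == "C*06:02"
        assert len(manifest["br_truth"]) > 0

    def test_rank_tables_cover_all_class_i_alleles(self, fixture_suite):
        out, manifest = fixture_suite
        cohorts = [read_genotype_table(out / f) for f in manifest["files"]["genotypes"]]
        alleles = {a for c in cohorts for s in c for l, gt in s.genotypes.items()
                   if l in CLASS_I_LOCI for a in gt.alleles}
        table = read_rank_table(out / manifest["files"]["ranks"][0], "simple_tsv")
        assert alleles <= set(table.alleles())
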