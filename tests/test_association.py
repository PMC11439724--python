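import numpy as np
import pytest
from scipy.special import gammaln

from immunoedit.association import (
    FilterStatus,
    associate_alleles,
    associate_categories,
    dosage_matrix,
    filter_alleles,
    fit_additive_glm,
    hwe_exact_test,
)
from immunoedit.hla import Cohort, Group, Locus
from immunoedit.presentation import BinderCategory
from immunoedit.simulate import SimulationConfig, simulate_cohort, simulate_genotypes

from .conftest import mk_allele, mk_subject


def hwe_oracle(n_aa, n_ab, n_bb):
    """Independent enumeration oracle: conditional probability of every
    heterozygote count via log-factorials, summed over the tail."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n - n_a
    hets = np.arange(min(n_a, n_b) % 2, min(n_a, n_b) + 1, 2)
    aa = (n_a - hets) // 2
    bb = (n_b - hets) // 2
    logp = (
        gammaln(n + 1) - gammaln(aa + 1) - gammaln(hets + 1) - gammaln(bb + 1)
        + hets * np.log(2.0)
        + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_ab)]
    return min(float(probs[probs <= p_obs * (1 + 1e-7)].sum()), 1.0)


class TestDosageMatrix:
    def _cohort(self):
        return Cohort("t", [
            mk_subject("hom", {"A": (2, 2)}),
            mk_subject("het", {"A": (1, 2)}),
            mk_subject("none", {"A": (3, 3)}),
            mk_subject("untyped", {"B": (7, 8)}),
        ])

    def test_dosage_coding(self):
        d = dosage_matrix(self._cohort(), Locus.A)
        assert d.loc["hom", "A*02:01"] == 2
        assert d.loc["het", "A*02:01"] == 1
        assert d.loc["none", "A*02:01"] == 0
        assert np.isnan(d.loc["untyped", "A*02:01"])

    def test_typed_rows_sum_to_two(self):
        d = dosage_matrix(self._cohort(), Locus.A)
        sums = d.sum(axis=1, skipna=False)
        assert sums.loc[["hom", "het", "none"]].tolist() == [2.0, 2.0, 2.0]


class TestHweExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(0, 0, 100) == 1.0
        assert hwe_exact_test(100, 0, 0) == 1.0

    def test_total_heterozygote_deficit_tiny_p(self):
        assert hwe_exact_test(25, 0, 25) < 1e-10

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)

    @pytest.mark.parametrize("triple", [
        (5, 10, 5), (25, 0, 25), (1, 0, 99), (0, 1, 99), (3, 3, 3),
        (57, 14, 50), (0, 50, 50), (10, 1, 1), (2, 96, 2),
    ])
    def test_matches_enumeration_oracle(self, triple):
        assert hwe_exact_test(*triple) == pytest.approx(hwe_oracle(*triple), rel=1e-9)

    def test_random_triples_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 150))
            n_aa = int(rng.integers(0, n + 1))
            n_ab = int(rng.integers(0, n - n_aa + 1))
            n_bb = n - n_aa - n_ab
            assert hwe_exact_test(n_aa, n_ab, n_bb) == pytest.approx(
                hwe_oracle(n_aa, n_ab, n_bb), rel=1e-9)


class TestFilterAlleles:
    def test_rare_allele_excluded(self):
        subjects = [mk_subject(f"s{i}", {"A": (1, 1)}) for i in range(99)]
        subjects.append(mk_subject("rare", {"A": (1, 2)}))
        filt = filter_alleles(Cohort("t", subjects), hwe_group=None, loci=[Locus.A])
        status = dict(zip(filt["allele"], filt["status"]))
        assert status["A*02:01"] == FilterStatus.EXCLUDED_FREQ.value
        assert status["A*01:01"] == FilterStatus.TESTED.value

    def test_hwe_violation_excluded(self):
        # gross heterozygote deficit at 50/50 frequencies
        subjects = [mk_subject(f"a{i}", {"A": (1, 1)}) for i in range(50)]
        subjects += [mk_subject(f"b{i}", {"A": (2, 2)}) for i in range(50)]
        filt = filter_alleles(Cohort("t", subjects), hwe_group=None, loci=[Locus.A])
        assert set(filt["status"]) == {FilterStatus.EXCLUDED_HWE.value}

    def test_hwe_null_exclusion_rate(self):
        """With HWE-consistent simulation, the alpha = 0.1 filter excludes
        roughly 10% of common alleles (exact test is conservative, so at
        most ~10% plus Monte-Carlo slack)."""
        spectrum = {Locus.A: {"A*01:01": 0.4, "A*02:01": 0.35, "A*03:01": 0.25}}
        excluded = total = 0
        for seed in range(150):
            cfg = SimulationConfig(seed=seed, allele_spectra=spectrum)
            cohort = simulate_genotypes(cfg, n=300)
            filt = filter_alleles(cohort, hwe_group=None, loci=[Locus.A])
            excluded += (filt["status"] == FilterStatus.EXCLUDED_HWE.value).sum()
            total += len(filt)
        rate = excluded / total
        assert 0.03 < rate < 0.13

    def test_empty_designated_group_errors(self):
        cohort = Cohort("t", [mk_subject("s", {"A": (1, 2)}, Group.CALR)])
        with pytest.raises(ValueError, match="empty"):
            filter_alleles(cohort, hwe_group=Group.CONTROL)


class TestFitAdditiveGlm:
    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(1)
        n = 4000
        d = rng.binomial(2, 0.3, n).astype(float)
        logit = -1.0 + 0.8 * d
        y = rng.binomial(1, 1 / (1 + np.exp(-logit))).astype(float)
        r = fit_additive_glm(d, y, term="x")
        assert r.converged
        assert r.log_or == pytest.approx(0.8, abs=0.15)
        assert r.ci95_low < np.exp(0.8) < r.ci95_high

    def test_separation_not_converged(self):
        d = np.array([1.0] * 20 + [0.0] * 20)
        y = np.array([1.0] * 20 + [0.0] * 20)
        r = fit_additive_glm(d, y, term="sep")
        assert r.filter_status is FilterStatus.NOT_CONVERGED
        assert r.log_or is None

    def test_zero_variance_flagged(self):
        d = np.zeros(40)
        y = np.array([1.0] * 20 + [0.0] * 20)
        r = fit_additive_glm(d, y, term="const")
        assert r.filter_status is FilterStatus.NOT_CONVERGED

    def test_label_swap_negates_log_or(self):
        rng = np.random.default_rng(2)
        n = 500
        d = rng.binomial(2, 0.2, n).astype(float)
        y = rng.binomial(1, 0.4, n).astype(float)
        r1 = fit_additive_glm(d, y, term="x")
        r2 = fit_additive_glm(d, 1 - y, term="x")
        assert r1.log_or == pytest.approx(-r2.log_or, abs=1e-6)

    def test_missing_covariates_dropped(self):
        rng = np.random.default_rng(3)
        n = 200
        d = rng.binomial(2, 0.3, n).astype(float)
        y = rng.binomial(1, 0.5, n).astype(float)
        age = rng.normal(50, 10, n)
        age[:50] = np.nan
        r = fit_additive_glm(d, y, age=age, term="x")
        assert r.n_case + r.n_control == 150


class TestAssociateAlleles:
    def test_planted_protective_allele_has_smallest_p(self):
        spectrum = {Locus.A: {"A*01:01": 0.30, "A*02:01": 0.10, "A*03:01": 0.35,
                              "A*24:02": 0.25}}
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(
                seed=seed * 7 + 1, n_calr=300, n_jak2=0, n_control=700,
                allele_spectra=spectrum,
                planted_effects={"CALR": {"A*02:01": float(np.log(0.3))}})
            cohort = simulate_cohort(cfg)
            table = associate_alleles(cohort, (Group.CALR, Group.CONTROL), loci=[Locus.A])
            tested = table[table["p"].notna()]
            best = tested.loc[tested["p"].idxmin()]
            if best["term"] == "A*02:01" and best["log_or"] < 0:
                hits += 1
        assert hits >= 9

    def test_null_no_excess_significance(self):
        spectrum = {Locus.A: {"A*01:01": 0.5, "A*02:01": 0.5}}
        ps = []
        for seed in range(40):
            cfg = SimulationConfig(seed=900 + seed, n_calr=150, n_jak2=0, n_control=350,
                                   allele_spectra=spectrum)
            cohort = simulate_cohort(cfg)
            table = associate_alleles(cohort, (Group.CALR, Group.CONTROL), loci=[Locus.A])
            ps += table.loc[table["p"].notna(), "p"].tolist()
        assert (np.array(ps) < 0.05).mean() < 0.15

    def test_empty_case_group_errors(self):
        cohort = Cohort("t", [mk_subject("s", {"A": (1, 2)}, Group.CONTROL)])
        with pytest.raises(ValueError, match="case"):
            associate_alleles(cohort, (Group.CALR, Group.CONTROL))

    def test_excluded_rows_carry_no_estimates(self):
        subjects = [mk_subject(f"s{i}", {"A": (1, 1)}, Group.CONTROL, 50.0, "F")
                    for i in range(60)]
        subjects += [mk_subject(f"c{i}", {"A": (1, 2)}, Group.CALR, 50.0, "F")
                     for i in range(1)]
        subjects += [mk_subject(f"c{i+10}", {"A": (1, 1)}, Group.CALR, 50.0, "F")
                     for i in range(39)]
        table = associate_alleles(Cohort("t", subjects), (Group.CALR, Group.CONTROL),
                                  loci=[Locus.A])
        excluded = table[table["filter_status"] != "TESTED"]
        assert excluded["log_or"].isna().all()


class TestAssociateCategories:
    def _annotations(self, cohort, sb_alleles=(), wb_alleles=()):
        alleles = {a for s in cohort for l, gt in s.genotypes.items()
                   if l.hla_class == 1 for a in gt.alleles}
        annot = {}
        for a in alleles:
            if str(a) in sb_alleles:
                annot[a] = BinderCategory.SB
            elif str(a) in wb_alleles:
                annot[a] = BinderCategory.WB
            else:
                annot[a] = BinderCategory.NB
        return {"CALRmut": annot}

    def _cohort(self, n=120, seed=5):
        cfg = SimulationConfig(seed=seed, n_calr=n // 3, n_jak2=0, n_control=2 * n // 3)
        return simulate_cohort(cfg)

    def test_dosages_sum_to_six(self):
        from immunoedit.association import category_dosages

        cohort = self._cohort()
        annot = self._annotations(cohort, sb_alleles=("A*01:01",))
        dosages, skipped = category_dosages(cohort, annot)
        assert not skipped
        sums = dosages[[f"CALRmut_{c.value}" for c in BinderCategory]].sum(axis=1)
        assert (sums == 6).all()

    def test_all_nb_zero_variance_flagged(self):
        cohort = self._cohort()
        table = associate_categories(cohort, self._annotations(cohort),
                                     (Group.CALR, Group.CONTROL))
        nb = table.set_index("term").loc["CALRmut_NB"]
        assert nb["filter_status"] == "NOT_CONVERGED"

    def test_unannotated_allele_errors(self):
        cohort = self._cohort()
        with pytest.raises(ValueError, match="not annotated"):
            associate_categories(cohort, {"CALRmut": {}}, (Group.CALR, Group.CONTROL))

    def test_planted_sb_depletion_recovered(self):
        """Cases depleted of an allele annotated SB -> negative SB log-OR."""
        spectrum = {Locus.A: {"A*01:01": 0.2, "A*02:01": 0.8},
                    Locus.B: {"B*07:02": 1.0}, Locus.C: {"C*07:01": 1.0}}
        signs = []
        for seed in range(5):
            cfg = SimulationConfig(
                seed=seed + 400, n_calr=250, n_jak2=0, n_control=600,
                allele_spectra=spectrum,
                planted_effects={"CALR": {"A*01:01": float(np.log(0.3))}})
            cohort = simulate_cohort(cfg)
            annot = self._annotations(cohort, sb_alleles=("A*01:01",))
            table = associate_categories(cohort, annot, (Group.CALR, Group.CONTROL))
            sb = table.set_index("term").loc["CALRmut_SB"]
            signs.append(sb["log_or"] < 0)
        assert sum(signs) >= 4
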