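"""Case-control association of HLA alleles and binder categories.

Per-allele analysis follows the study design: per locus, alleles are coded
additively (0/1/2 copies), pre-filtered on overall frequency (>= 2%) and on
an exact Hardy-Weinberg equilibrium test in the control stratum (alleles
with HWE p < 0.1, i.e. significant deviation, are excluded as likely typing
or sampling artifacts), then tested one at a time in a logistic model

    logit P(case) = b0 + b_d * dosage + b_age * age + b_sex * sex

with a two-sided Wald test on the dosage coefficient.  Category analysis
replaces allele dosage with the number of the subject's six class I alleles
annotated SB/WB/NB for a mutation and applies no pre-filtering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .hla import CLASS_I_LOCI, Cohort, Group, HlaAllele, Locus
from .presentation import BinderCategory

logger = logging.getLogger(__name__)

WALD_Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class FilterStatus(str, Enum):
    TESTED = "TESTED"
    EXCLUDED_FREQ = "EXCLUDED_FREQ"
    EXCLUDED_HWE = "EXCLUDED_HWE"
    NOT_CONVERGED = "NOT_CONVERGED"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


@dataclass
class AssociationResult:
    term: str
    comparison: str
    n_case: int
    n_control: int
    freq_case: float | None = None
    freq_control: float | None = None
    log_or: float | None = None
    se: float | None = None
    or_: float | None = None
    ci95_low: float | None = None
    ci95_high: float | None = None
    p_wald: float | None = None
    converged: bool = False
    filter_status: FilterStatus = FilterStatus.TESTED
    hwe_p: float | None = None


def dosage_matrix(cohort: Cohort, locus: Locus) -> pd.DataFrame:
    """Subjects x alleles additive dosage table for one locus.

    Entries are 0/1/2 copies; subjects untyped at the locus get NaN rows.
    Typed rows sum to 2.
    """
    alleles = sorted({
        a for s in cohort if (gt := s.genotypes.get(locus)) is not None for a in gt.alleles
    })
    if not alleles:
        raise ValueError(f"no subject typed at locus {locus}")
    data = np.full((len(cohort), len(alleles)), np.nan)
    for i, s in enumerate(cohort):
        gt = s.genotypes.get(locus)
        if gt is None:
            continue
        data[i, :] = 0.0
        for a in gt.alleles:
            data[i, alleles.index(a)] += 1.0
    return pd.DataFrame(
        data, index=[s.subject_id for s in cohort], columns=[str(a) for a in alleles]
    )


def _hwe_het_distribution(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count given n genotypes
    and n_a copies of allele A, under Hardy-Weinberg (random mating).

    Returns (het_counts, probabilities), computed by the stable two-sided
    recurrence from the distribution's mode.
    """
    n_b = 2 * n - n_a
    rare = min(n_a, n_b)
    if rare == 0:
        return np.array([0]), np.array([1.0])
    # heterozygote count shares parity with the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    # start near the mode to avoid under/overflow in the recurrence
    mode = rare * (2 * n - rare) / (2.0 * n)
    start = int(hets[np.argmin(np.abs(hets - mode))])
    logp = {start: 0.0}
    h = start
    while h - 2 >= hets[0]:
        n_aa = (n_a - h) // 2
        n_bb = (n_b - h) // 2
        # P(h-2)/P(h) = h(h-1) / (4 (n_aa+1)(n_bb+1))
        logp[h - 2] = logp[h] + np.log(h * (h - 1)) - np.log(4.0 * (n_aa + 1) * (n_bb + 1))
        h -= 2
    h = start
    while h + 2 <= hets[-1]:
        n_aa = (n_a - h) // 2
        n_bb = (n_b - h) // 2
        # P(h+2)/P(h) = 4 n_aa n_bb / ((h+2)(h+1))
        logp[h + 2] = logp[h] + np.log(4.0 * n_aa * n_bb) - np.log((h + 2.0) * (h + 1.0))
        h += 2
    logs = np.array([logp[int(h)] for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    return hets, probs


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test for a biallelic genotype triple.

    Sums the conditional probabilities of all heterozygote counts whose
    probability does not exceed the observed one (with a small relative
    guard so mathematically tied configurations are always included).
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("negative genotype count")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_aa + n_ab
    hets, probs = _hwe_het_distribution(n, n_a)
    p_obs = probs[np.searchsorted(hets, n_ab)]
    p = float(probs[probs <= p_obs * (1.0 + 1e-7)].sum())
    return min(p, 1.0)


def hwe_genotype_counts(
    cohort: Cohort, allele: HlaAllele
) -> tuple[int, int, int]:
    """Collapsed biallelic genotype counts (AA, AB, BB) for one allele,
    pooling all other alleles at its locus."""
    n_aa = n_ab = n_bb = 0
    for s in cohort:
        gt = s.genotypes.get(allele.locus)
        if gt is None:
            continue
        d = gt.dosage(allele)
        if d == 2:
            n_aa += 1
        elif d == 1:
            n_ab += 1
        else:
            n_bb += 1
    return n_aa, n_ab, n_bb


def filter_alleles(
    cohort: Cohort,
    min_freq: float = 0.02,
    hwe_alpha: float = 0.1,
    hwe_group: Group | None = Group.CONTROL,
    loci: Sequence[Locus] | None = None,
) -> pd.DataFrame:
    """Per-allele filter table: tested iff overall frequency >= min_freq and
    exact HWE p >= hwe_alpha in the designated stratum (None = full sample).

    Columns: locus, allele, frequency, hwe_p, status.
    """
    if hwe_group is not None:
        stratum = cohort.subset([hwe_group], name="hwe_stratum")
        if len(stratum) == 0:
            raise ValueError(f"designated HWE group {hwe_group} is empty")
    else:
        stratum = cohort
    from .hla import allele_counts  # local import to avoid cycle at module load

    rows = []
    for locus in loci or list(Locus):
        try:
            counts = allele_counts(cohort, locus)
        except ValueError:
            continue
        for rec in counts.itertuples(index=False):
            from .hla import parse_allele

            allele = parse_allele(rec.allele)
            freq = rec.frequency
            if freq < min_freq:
                rows.append({"locus": locus.value, "allele": rec.allele,
                             "frequency": freq, "hwe_p": None,
                             "status": FilterStatus.EXCLUDED_FREQ.value})
                continue
            hwe_p = hwe_exact_test(*hwe_genotype_counts(stratum, allele))
            status = (FilterStatus.TESTED if hwe_p >= hwe_alpha
                      else FilterStatus.EXCLUDED_HWE)
            rows.append({"locus": locus.value, "allele": rec.allele,
                         "frequency": freq, "hwe_p": hwe_p, "status": status.value})
    return pd.DataFrame(rows, columns=["locus", "allele", "frequency", "hwe_p", "status"])


def fit_additive_glm(
    dosage: np.ndarray,
    case: np.ndarray,
    age: np.ndarray | None = None,
    sex: np.ndarray | None = None,
    extra_covariates: pd.DataFrame | None = None,
    term: str = "dosage",
    comparison: str = "",
) -> AssociationResult:
    """Logistic model of case status on additive dosage with covariates.

    Subjects with a missing dosage or covariate are dropped (logged).  Sex is
    a single indicator (M = 1, F = 0).  Non-convergence or separation yields
    a NOT_CONVERGED result without estimates.
    """
    dosage = np.asarray(dosage, dtype=float)
    case = np.asarray(case, dtype=float)
    cols = {"dosage": dosage}
    if age is not None:
        cols["age"] = np.asarray(age, dtype=float)
    if sex is not None:
        sex_arr = np.asarray(
            [np.nan if s is None else (1.0 if s == "M" else (0.0 if s == "F" else float(s)))
             for s in sex], dtype=float)
        cols["sex"] = sex_arr
    X = pd.DataFrame(cols)
    if extra_covariates is not None:
        X = pd.concat([X, extra_covariates.reset_index(drop=True)], axis=1)
    keep = ~(X.isna().any(axis=1) | np.isnan(case))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d subjects with missing dosage/covariates", term, n_dropped)
    X = X.loc[keep]
    y = case[keep.to_numpy()]
    n_case = int(y.sum())
    n_control = int(len(y) - n_case)
    res = AssociationResult(term=term, comparison=comparison,
                            n_case=n_case, n_control=n_control)
    if n_case == 0 or n_control == 0:
        raise ValueError(f"{term}: need at least one case and one control after dropping")
    d = X["dosage"].to_numpy()
    res.freq_case = float(d[y == 1].sum() / (2 * n_case))
    res.freq_control = float(d[y == 0].sum() / (2 * n_control))
    if np.ptp(d) == 0:
        logger.warning("%s: zero-variance dosage; not testable", term)
        res.filter_status = FilterStatus.NOT_CONVERGED
        return res
    design = sm.add_constant(X.to_numpy(), prepend=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", False))
        beta = float(fit.params[1])
        se = float(fit.bse[1])
    except Exception:  # PerfectSeparationError and numerical failures
        converged = False
        beta = se = np.nan
    if not converged or not np.isfinite(beta) or not np.isfinite(se) or se > 50:
        res.filter_status = FilterStatus.NOT_CONVERGED
        res.converged = False
        return res
    res.converged = True
    res.log_or = beta
    res.se = se
    res.or_ = float(np.exp(beta))
    res.ci95_low = float(np.exp(beta - WALD_Z_95 * se))
    res.ci95_high = float(np.exp(beta + WALD_Z_95 * se))
    z = beta / se
    from scipy.stats import norm

    res.p_wald = float(2 * norm.sf(abs(z)))
    return res


def _results_frame(results: list[AssociationResult], extra: Mapping[str, list] | None = None
                   ) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "term": r.term, "comparison": r.comparison,
            "n_case": r.n_case, "n_control": r.n_control,
            "freq_case": r.freq_case, "freq_control": r.freq_control,
            "log_or": r.log_or, "se": r.se, "or": r.or_,
            "ci_low": r.ci95_low, "ci_high": r.ci95_high,
            "p": r.p_wald, "hwe_p": r.hwe_p,
            "filter_status": r.filter_status.value,
        })
    df = pd.DataFrame(rows, columns=["term", "comparison", "n_case", "n_control",
                                     "freq_case", "freq_control", "log_or", "se", "or",
                                     "ci_low", "ci_high", "p", "hwe_p", "filter_status"])
    # BH-adjusted column over the terms that produced a p-value
    df["p_bh"] = np.nan
    mask = df["p"].notna()
    if mask.any():
        df.loc[mask, "p_bh"] = multipletests(df.loc[mask, "p"], method="fdr_bh")[1]
    return df


def _case_control_arrays(cohort: Cohort, comparison: tuple[Group, Group]):
    case_group, control_group = comparison
    sub = cohort.subset([case_group, control_group], name="assoc")
    if not any(s.group is case_group for s in sub):
        raise ValueError(f"empty case group {case_group}")
    if not any(s.group is control_group for s in sub):
        raise ValueError(f"empty control group {control_group}")
    y = np.array([1.0 if s.group is case_group else 0.0 for s in sub])
    age = np.array([np.nan if s.age is None else s.age for s in sub])
    sex = [s.sex for s in sub]
    return sub, y, age, sex


def associate_alleles(
    cohort: Cohort,
    comparison: tuple[Group, Group],
    min_freq: float = 0.02,
    hwe_alpha: float = 0.1,
    hwe_group: Group | None = Group.CONTROL,
    loci: Sequence[Locus] | None = None,
    extra_covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-allele filtered additive-GLM association table.

    Each locus is analysed independently; exclusions and non-convergences are
    reported as rows without estimates so filter provenance is never lost.
    """
    sub, y, age, sex = _case_control_arrays(cohort, comparison)
    comp_label = f"{comparison[0].value} vs {comparison[1].value}"
    if hwe_group is not None and hwe_group not in (comparison[0], comparison[1]):
        raise ValueError(f"HWE stratum {hwe_group} not part of comparison {comp_label}")
    filt = filter_alleles(sub, min_freq=min_freq, hwe_alpha=hwe_alpha,
                          hwe_group=hwe_group, loci=loci)
    from .hla import parse_allele

    results: list[AssociationResult] = []
    for locus in loci or list(Locus):
        locus_filt = filt[filt["locus"] == locus.value]
        if locus_filt.empty:
            continue
        dmat = dosage_matrix(sub, locus)
        for rec in locus_filt.itertuples(index=False):
            status = FilterStatus(rec.status)
            if status is not FilterStatus.TESTED:
                r = AssociationResult(
                    term=rec.allele, comparison=comp_label,
                    n_case=int(y.sum()), n_control=int(len(y) - y.sum()),
                    filter_status=status, hwe_p=rec.hwe_p,
                )
                results.append(r)
                continue
            d = dmat[rec.allele].to_numpy()
            r = fit_additive_glm(d, y, age, sex, extra_covariates,
                                 term=rec.allele, comparison=comp_label)
            r.hwe_p = rec.hwe_p
            results.append(r)
    return _results_frame(results)


def category_dosages(
    cohort: Cohort,
    br_annotations: Mapping[str, Mapping[HlaAllele, BinderCategory]],
) -> tuple[pd.DataFrame, list[str]]:
    """Per-subject counts of class I alleles in each (mutation, category).

    Returns (table indexed by subject_id with columns like ``CALRmut_SB``,
    skipped subject ids with incomplete class I genotype).  Per mutation the
    counts of a complete subject sum to 6.  An allele missing from an
    annotation raises.
    """
    rows = {}
    skipped = []
    for s in cohort:
        alleles = s.class_i_alleles()
        if alleles is None:
            skipped.append(s.subject_id)
            continue
        rec = {}
        for mut, annot in br_annotations.items():
            counts = {c: 0 for c in BinderCategory}
            for a in alleles:
                if a not in annot:
                    raise ValueError(f"allele {a} not annotated for {mut}")
                counts[annot[a]] += 1
            for c in BinderCategory:
                rec[f"{mut}_{c.value}"] = counts[c]
        rows[s.subject_id] = rec
    return pd.DataFrame.from_dict(rows, orient="index"), skipped


def associate_categories(
    cohort: Cohort,
    br_annotations: Mapping[str, Mapping[HlaAllele, BinderCategory]],
    comparison: tuple[Group, Group],
    extra_covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Binder-category association: dosage = number of the subject's six class I
    alleles in the category.  No frequency or HWE exclusion is applied."""
    sub, y, age, sex = _case_control_arrays(cohort, comparison)
    comp_label = f"{comparison[0].value} vs {comparison[1].value}"
    dosages, skipped = category_dosages(sub, br_annotations)
    if skipped:
        logger.warning("category association: %d subjects with incomplete class I skipped",
                       len(skipped))
    keep = np.array([s.subject_id in dosages.index for s in sub])
    subjects = [s for s in sub if s.subject_id in dosages.index]
    dosages = dosages.loc[[s.subject_id for s in subjects]]
    y = y[keep]
    age = np.array([np.nan if s.age is None else s.age for s in subjects])
    sex = [s.sex for s in subjects]
    extra = None
    if extra_covariates is not None:
        extra = extra_covariates.loc[keep].reset_index(drop=True)
    results = []
    for term in dosages.columns:
        d = dosages[term].to_numpy(dtype=float)
        # category "frequency" per spec output schema: mean fraction of the 6 alleles
        r = fit_additive_glm(d, y, age, sex, extra, term=term, comparison=comp_label)
        results.append(r)
    return _results_frame(results)
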