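"""Multi-cohort pooling, pooled association, and cross-mutation PHBR correlation.

Pooling concatenates cohorts with the cohort label preserved; the pooled
association model adds fixed-effect cohort indicator covariates so that
between-cohort frequency differences (population structure, typing depth)
cannot masquerade as case-control effects.  The correlation analysis asks,
per group of subjects, whether the genotype's capability to present one
driver mutation's neoantigens (low PHBR) trades off against the other —
a negative Pearson correlation between the two per-subject PHBRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import associate_alleles, associate_categories
from .hla import Cohort, Group, Locus, Subject

logger = logging.getLogger(__name__)


def pool_cohorts(cohorts: Sequence[Cohort], name: str = "pooled") -> Cohort:
    """Concatenate cohorts into one, prefixing subject ids with the cohort name.

    The per-subject ``cohort`` label is preserved so stratified analyses and
    fixed-effect adjustment remain possible.
    """
    if len(cohorts) < 2:
        raise ValueError("pooling needs at least two cohorts")
    names = [c.name for c in cohorts]
    if len(set(names)) != len(names):
        raise ValueError(f"cohort names must be unique for pooling, got {names}")
    subjects = []
    for c in cohorts:
        for s in c:
            subjects.append(Subject(
                subject_id=f"{c.name}:{s.subject_id}",
                cohort=c.name,
                group=s.group,
                age=s.age,
                sex=s.sex,
                genotypes=dict(s.genotypes),
            ))
    pooled = Cohort(name, subjects)
    counts = pooled.group_counts()
    logger.info("pooled %d cohorts: %s subjects (%s)", len(cohorts), len(pooled),
                {g.value: n for g, n in counts.items() if n})
    return pooled


def _cohort_dummies(cohort: Cohort) -> pd.DataFrame | None:
    """Fixed-effect indicator columns for all but the first cohort label."""
    labels = [s.cohort for s in cohort]
    levels = sorted(set(labels))
    if len(levels) < 2:
        return None
    data = {f"cohort_{lv}": [1.0 if l == lv else 0.0 for l in labels] for lv in levels[1:]}
    return pd.DataFrame(data)


def pooled_association(
    pooled: Cohort,
    comparison: tuple[Group, Group],
    min_freq: float = 0.02,
    hwe_alpha: float = 0.1,
    hwe_group: Group | None = None,
    loci: Sequence[Locus] | None = None,
    adjust_cohort: bool = True,
) -> pd.DataFrame:
    """Per-allele association on a pooled sample with cohort fixed effects.

    With a single cohort label present the cohort covariate is dropped
    automatically and the result equals ``associate_alleles``.  ``hwe_group``
    defaults to None (HWE screened on the full pooled comparison sample)
    because pooled patient-only comparisons may have no control group.
    """
    sub = pooled.subset(comparison, name="pooled_assoc")
    dummies = _cohort_dummies(sub) if adjust_cohort else None
    return associate_alleles(
        sub, comparison, min_freq=min_freq, hwe_alpha=hwe_alpha,
        hwe_group=hwe_group, loci=loci, extra_covariates=dummies,
    )


def pooled_category_association(
    pooled: Cohort,
    br_annotations,
    comparison: tuple[Group, Group],
    adjust_cohort: bool = True,
) -> pd.DataFrame:
    """Binder-category association on a pooled sample with cohort fixed effects."""
    sub = pooled.subset(comparison, name="pooled_cat")
    dummies = _cohort_dummies(sub) if adjust_cohort else None
    return associate_categories(sub, br_annotations, comparison, extra_covariates=dummies)


@dataclass
class CorrelationResult:
    group: str
    n: int
    r: float
    p: float


def phbr_correlation(
    phbr_table: pd.DataFrame,
    mutation_x: str,
    mutation_y: str,
    group_by: Sequence[str] = ("cohort", "group"),
    log10_scale: bool = False,
) -> pd.DataFrame:
    """Per-group Pearson correlation between two mutations' subject PHBRs.

    ``phbr_table`` is the tidy output of ``cohort_phbr_table`` (columns
    subject_id, cohort, group, mutation_id, phbr).  Groups with fewer than 3
    subjects carrying both PHBRs are skipped (logged); zero-variance vectors
    raise.  ``log10_scale`` correlates log10 PHBR instead of raw values.
    """
    wide = phbr_table.pivot_table(
        index=["subject_id", *group_by], columns="mutation_id", values="phbr"
    ).reset_index()
    for mut in (mutation_x, mutation_y):
        if mut not in wide.columns:
            raise ValueError(f"no PHBR values for mutation {mut!r}")
    rows = []
    for key, sub in wide.groupby(list(group_by)):
        sub = sub.dropna(subset=[mutation_x, mutation_y])
        label = key if isinstance(key, str) else "/".join(map(str, key))
        if len(sub) < 3:
            logger.warning("correlation group %s: only %d subjects; skipped", label, len(sub))
            continue
        x = sub[mutation_x].to_numpy(dtype=float)
        y = sub[mutation_y].to_numpy(dtype=float)
        if log10_scale:
            x, y = np.log10(x), np.log10(y)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"correlation group {label}: zero-variance PHBR vector")
        r, p = stats.pearsonr(x, y)
        rows.append({"group": label, "n": int(len(sub)), "r": float(r), "p": float(p)})
    return pd.DataFrame(rows, columns=["group", "n", "r", "p"])
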