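"""HLA evolutionary divergence (HED) via Grantham distance.

HED for one locus is the mean Grantham amino-acid distance across the
aligned positions of the two allele sequences — zero by definition for a
homozygous locus, larger the more chemically divergent the two binding
grooves are.  Subjects with higher HED can, in principle, present a wider
peptide repertoire through that locus.

The shipped integer distance matrix (``data/grantham.tsv``) is generated
from Grantham's 1974 formula

    D(a, b) = rho * [alpha (c_a - c_b)^2 + beta (p_a - p_b)^2
                     + gamma (v_a - v_b)^2]^(1/2)

with composition c, polarity p and side-chain volume v per residue, weights
alpha = 1.833, beta = 0.1018, gamma = 0.000399, and rho = 50.723 scaling the
mean over the 190 residue pairs to 100; entries are rounded to the nearest
integer (declared rounding tolerance 0.5).  ``grantham_formula`` exposes the
unrounded formula so the table can be validated against it.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
from scipy import stats

from .hla import (
    CLASS_I_LOCI,
    CLASS_II_LOCI,
    AlleleSequenceDB,
    Cohort,
    Locus,
    Subject,
)

logger = logging.getLogger(__name__)

GRANTHAM_ALPHA = 1.833
GRANTHAM_BETA = 0.1018
GRANTHAM_GAMMA = 0.000399
GRANTHAM_RHO = 50.723
GRANTHAM_ROUNDING_TOL = 0.5  # table entries are the formula rounded to integers

# (composition, polarity, volume) per residue, Grantham 1974
GRANTHAM_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32), "R": (0.65, 10.5, 124), "L": (0.0, 4.9, 111),
    "P": (0.39, 8.0, 32.5), "T": (0.71, 8.6, 61), "A": (0.0, 8.1, 31),
    "V": (0.0, 5.9, 84), "G": (0.74, 9.0, 3), "I": (0.0, 5.2, 111),
    "F": (0.0, 5.2, 132), "Y": (0.20, 6.2, 136), "C": (2.75, 5.5, 55),
    "H": (0.58, 10.4, 96), "Q": (0.89, 10.5, 85), "N": (1.33, 11.6, 56),
    "K": (0.33, 11.3, 119), "D": (1.38, 13.0, 54), "E": (0.92, 12.3, 83),
    "M": (0.0, 5.7, 105), "W": (0.13, 5.4, 170),
}


def grantham_formula(a: str, b: str) -> float:
    """Unrounded Grantham distance from the physico-chemical formula."""
    try:
        ca, pa, va = GRANTHAM_PROPERTIES[a]
        cb, pb, vb = GRANTHAM_PROPERTIES[b]
    except KeyError as exc:
        raise ValueError(f"nonstandard residue {exc.args[0]!r}") from None
    return GRANTHAM_RHO * math.sqrt(
        GRANTHAM_ALPHA * (ca - cb) ** 2
        + GRANTHAM_BETA * (pa - pb) ** 2
        + GRANTHAM_GAMMA * (va - vb) ** 2
    )


def _load_matrix() -> dict[tuple[str, str], float]:
    text = resources.files("immunoedit.data").joinpath("grantham.tsv").read_text()
    lines = [ln.split("\t") for ln in text.splitlines() if ln]
    residues = lines[0][1:]
    table: dict[tuple[str, str], float] = {}
    for row in lines[1:]:
        a = row[0]
        for b, value in zip(residues, row[1:]):
            table[(a, b)] = float(value)
    for a, b in itertools.combinations(residues, 2):
        assert table[(a, b)] == table[(b, a)], f"asymmetric matrix entry {a}/{b}"
    return table


_MATRIX: dict[tuple[str, str], float] | None = None


def grantham_distance(a: str, b: str) -> float:
    """Integer-matrix Grantham distance; 0 on the diagonal, symmetric."""
    global _MATRIX
    if _MATRIX is None:
        _MATRIX = _load_matrix()
    try:
        return _MATRIX[(a, b)]
    except KeyError:
        raise ValueError(f"nonstandard residue in pair ({a!r}, {b!r})") from None


def locus_hed(seq1: str, seq2: str) -> float:
    """Mean per-site Grantham distance between two equal-length sequences."""
    if len(seq1) != len(seq2):
        raise ValueError(f"sequence length mismatch: {len(seq1)} vs {len(seq2)}")
    if not seq1:
        raise ValueError("empty sequences")
    return sum(grantham_distance(a, b) for a, b in zip(seq1, seq2)) / len(seq1)


@dataclass
class HedResult:
    subject_id: str
    per_locus: dict[Locus, float] = field(default_factory=dict)
    mean_class_i: float | None = None
    mean_class_ii: float | None = None


def subject_hed(subject: Subject, db: AlleleSequenceDB) -> HedResult:
    """Per-locus HED and class means for one subject.

    Homozygous loci short-circuit to 0 without a sequence lookup.  A locus
    whose sequences are missing from the DB is omitted (logged) and the
    class mean containing it is suppressed.
    """
    per_locus: dict[Locus, float] = {}
    for locus, gt in sorted(subject.genotypes.items(), key=lambda kv: kv[0].value):
        if gt.homozygous:
            per_locus[locus] = 0.0
            continue
        s1, s2 = db.get(gt.allele1), db.get(gt.allele2)
        if s1 is None or s2 is None:
            missing = gt.allele1 if s1 is None else gt.allele2
            logger.warning("subject %s: no sequence for %s; locus %s omitted from HED",
                           subject.subject_id, missing, locus.value)
            continue
        per_locus[locus] = locus_hed(s1, s2)
    result = HedResult(subject.subject_id, per_locus)
    if all(l in per_locus for l in CLASS_I_LOCI):
        result.mean_class_i = sum(per_locus[l] for l in CLASS_I_LOCI) / len(CLASS_I_LOCI)
    if all(l in per_locus for l in CLASS_II_LOCI):
        result.mean_class_ii = sum(per_locus[l] for l in CLASS_II_LOCI) / len(CLASS_II_LOCI)
    return result


def cohort_hed_table(cohort: Cohort, db: AlleleSequenceDB) -> pd.DataFrame:
    """Per-subject HED values as a tidy table (one row per subject)."""
    rows = []
    for s in cohort:
        res = subject_hed(s, db)
        rec: dict = {"subject_id": s.subject_id, "cohort": s.cohort, "group": s.group.value}
        for locus in Locus:
            rec[f"hed_{locus.value}"] = res.per_locus.get(locus)
        rec["hed_class_I"] = res.mean_class_i
        rec["hed_class_II"] = res.mean_class_ii
        rows.append(rec)
    return pd.DataFrame(rows)


def cohort_hed_comparison(
    hed_table: pd.DataFrame, value_column: str, group_column: str = "group"
) -> pd.DataFrame:
    """Group summaries plus pairwise Welch t-tests on one HED column.

    Returns a table with one row per group pair: per-group n/mean/SD and the
    two-sided Welch p-value.  Each group needs >= 2 non-missing subjects.
    """
    values = hed_table[[group_column, value_column]].dropna()
    groups = {g: sub[value_column].to_numpy() for g, sub in values.groupby(group_column)}
    if len(groups) < 2:
        raise ValueError("need at least two groups with HED values")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects with {value_column}")
    rows = []
    for g1, g2 in itertools.combinations(sorted(groups), 2):
        v1, v2 = groups[g1], groups[g2]
        t, p = stats.ttest_ind(v1, v2, equal_var=False)
        rows.append({
            "value": value_column, "group1": g1, "group2": g2,
            "n1": len(v1), "n2": len(v2),
            "mean1": float(v1.mean()), "mean2": float(v2.mean()),
            "sd1": float(v1.std(ddof=1)), "sd2": float(v2.std(ddof=1)),
            "t": float(t), "p": float(p),
        })
    return pd.DataFrame(rows)
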