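"""Multi-locus haplotype frequency estimation (EM) and score tests.

Genotypes are unphased: a subject heterozygous at h of the requested loci is
consistent with 2^(h-1) diplotype resolutions.  The EM algorithm alternates
between assigning each subject posterior probabilities over its consistent
diplotypes (product of haplotype frequencies under random mating, x2 for
distinct ordered pairs) and re-estimating frequencies from expected
haplotype counts.  The log-likelihood is non-decreasing by construction.

Per-haplotype association uses the *imputed-dosage score test*: with the
null logistic model (intercept + covariates, no haplotype term) fitted once,
each haplotype's subject-level expected dosage d_i (posterior expected
copies) gives the score U = sum d_i (y_i - p_i) with variance corrected for
the estimated nuisance parameters; U^2/V is chi-square(1) under the null.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .hla import CLASS_I_LOCI, CLASS_II_LOCI, Cohort, Group, HlaAllele, Locus

logger = logging.getLogger(__name__)

Haplotype = tuple[HlaAllele, ...]


def haplotype_label(hap: Haplotype) -> str:
    return "-".join(str(a) for a in hap)


@dataclass
class HaplotypeFreqs:
    loci: tuple[Locus, ...]
    frequencies: dict[Haplotype, float]
    log_likelihood_trace: list[float] = field(default_factory=list)
    n_subjects: int = 0
    converged: bool = False
    # per-subject diplotype posteriors, kept for dosage imputation:
    # list over subjects of (subject_id, [(hap1, hap2, posterior), ...])
    posteriors: list[tuple[str, list[tuple[Haplotype, Haplotype, float]]]] = field(
        default_factory=list, repr=False
    )

    def expected_dosages(self) -> pd.DataFrame:
        """Posterior expected haplotype copies per subject (rows sum to 2)."""
        haps = sorted(self.frequencies)
        idx = {h: j for j, h in enumerate(haps)}
        data = np.zeros((len(self.posteriors), len(haps)))
        ids = []
        for i, (sid, dips) in enumerate(self.posteriors):
            ids.append(sid)
            for h1, h2, w in dips:
                if h1 in idx:
                    data[i, idx[h1]] += w
                if h2 in idx:
                    data[i, idx[h2]] += w
        return pd.DataFrame(data, index=ids, columns=[haplotype_label(h) for h in haps])


def _diplotype_expansions(
    genotypes: Sequence[tuple[HlaAllele, HlaAllele]]
) -> list[tuple[Haplotype, Haplotype]]:
    """All phase resolutions of per-locus unordered allele pairs.

    Unordered diplotypes: for each heterozygous locus beyond the first one
    both assignments are enumerated (2^(h-1) resolutions).
    """
    het_idx = [i for i, (a1, a2) in enumerate(genotypes) if a1 != a2]
    out = []
    flips = itertools.product((False, True), repeat=max(0, len(het_idx) - 1))
    for flip in flips:
        h1, h2 = [], []
        flip_at = dict(zip(het_idx[1:], flip))
        for i, (a1, a2) in enumerate(genotypes):
            if i in flip_at and flip_at[i]:
                h1.append(a2), h2.append(a1)
            else:
                h1.append(a1), h2.append(a2)
        out.append((tuple(h1), tuple(h2)))
    return out


def em_haplotype_frequencies(
    cohort: Cohort,
    loci: Sequence[Locus],
    tol: float = 1e-8,
    max_iter: int = 1000,
    prune_freq: float = 1e-6,
    expansion_cap: int = 4096,
) -> HaplotypeFreqs:
    """EM estimate of haplotype frequencies over the requested loci.

    Subjects untyped at any requested locus are dropped (logged).  The
    initial guess is the product of marginal allele frequencies, a
    deterministic start that also resolves likelihood ties reproducibly.
    Haplotypes ending below ``prune_freq`` are dropped and the remainder
    renormalized.
    """
    loci = tuple(loci)
    usable = []
    for s in cohort:
        if all(l in s.genotypes for l in loci):
            usable.append(s)
        else:
            logger.info("EM: subject %s untyped at some of %s; dropped",
                        s.subject_id, [l.value for l in loci])
    if not usable:
        raise ValueError(f"no subject typed at all of {[l.value for l in loci]}")
    expansions = []
    for s in usable:
        pairs = [s.genotypes[l].alleles for l in loci]
        exp = _diplotype_expansions(pairs)
        if len(exp) > expansion_cap:
            raise ValueError(
                f"subject {s.subject_id}: {len(exp)} diplotype expansions exceed cap "
                f"{expansion_cap}"
            )
        expansions.append((s.subject_id, exp))

    # deterministic initialization: product of marginal allele frequencies
    marginals: list[dict[HlaAllele, float]] = []
    for j, locus in enumerate(loci):
        counts: dict[HlaAllele, int] = {}
        for s in usable:
            for a in s.genotypes[locus].alleles:
                counts[a] = counts.get(a, 0) + 1
        total = sum(counts.values())
        marginals.append({a: c / total for a, c in counts.items()})
    hap_universe = sorted({h for _, exp in expansions for pair in exp for h in pair})
    freqs = {
        h: float(np.prod([marginals[j][a] for j, a in enumerate(h)])) for h in hap_universe
    }
    z = sum(freqs.values())
    freqs = {h: f / z for h, f in freqs.items()}

    n = len(usable)
    trace: list[float] = []
    converged = False
    posteriors: list[tuple[str, list[tuple[Haplotype, Haplotype, float]]]] = []
    for _ in range(max_iter):
        # E-step: posterior over diplotypes per subject
        expected: dict[Haplotype, float] = {h: 0.0 for h in freqs}
        loglik = 0.0
        posteriors = []
        for sid, exp in expansions:
            weights = []
            for h1, h2 in exp:
                p = freqs.get(h1, 0.0) * freqs.get(h2, 0.0)
                if h1 != h2:
                    p *= 2.0
                weights.append(p)
            total = sum(weights)
            if total <= 0:
                # all consistent diplotypes pruned to zero; re-seed uniformly
                weights = [1.0] * len(exp)
                total = float(len(exp))
            loglik += float(np.log(total))
            post = []
            for (h1, h2), w in zip(exp, weights):
                w /= total
                if w > 0:
                    expected[h1] = expected.get(h1, 0.0) + w
                    expected[h2] = expected.get(h2, 0.0) + w
                    post.append((h1, h2, w))
            posteriors.append((sid, post))
        trace.append(loglik)
        # M-step
        freqs = {h: c / (2.0 * n) for h, c in expected.items()}
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    pruned = {h: f for h, f in freqs.items() if f >= prune_freq}
    z = sum(pruned.values())
    pruned = {h: f / z for h, f in pruned.items()}
    return HaplotypeFreqs(loci, pruned, trace, n, converged, posteriors)


@dataclass
class HaploScoreResult:
    haplotype: str
    frequency: float
    effect: float  # one-step estimate U/V on the log-odds scale
    score: float  # signed score statistic U/sqrt(V)
    p: float
    n_used: int


def haplotype_score_test(
    cohort: Cohort,
    loci: Sequence[Locus],
    comparison: tuple[Group, Group],
    prune_freq: float = 0.01,
    use_covariates: bool = True,
    em_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Imputed-dosage score tests for each common haplotype over ``loci``.

    EM frequencies are estimated on the pooled case+control sample; per
    retained haplotype (frequency >= prune_freq) the score test contrasts
    case status against the posterior expected dosage, adjusting for
    intercept, age and sex fitted under the null.
    """
    case_group, control_group = comparison
    sub = cohort.subset([case_group, control_group], name="haplo")
    em = em_haplotype_frequencies(sub, loci, **(em_kwargs or {}))
    dosages = em.expected_dosages()
    subjects = {s.subject_id: s for s in sub}
    used_ids = [sid for sid in dosages.index]
    y = np.array([1.0 if subjects[sid].group is case_group else 0.0 for sid in used_ids])
    covs = [np.ones(len(used_ids))]
    if use_covariates:
        age = np.array([np.nan if subjects[sid].age is None else subjects[sid].age
                        for sid in used_ids])
        sex = np.array([np.nan if subjects[sid].sex is None
                        else (1.0 if subjects[sid].sex == "M" else 0.0)
                        for sid in used_ids])
        covs += [age, sex]
    X = np.column_stack(covs)
    keep = ~np.isnan(X).any(axis=1)
    X, y = X[keep], y[keep]
    D_all = dosages.to_numpy()[keep]
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need both cases and controls with complete covariates")
    try:
        null_fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not null_fit.mle_retvals.get("converged", False):
            raise ValueError("null logistic model did not converge")
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError(f"null logistic model failed: {exc}") from None
    p_hat = null_fit.predict(X)
    w = p_hat * (1 - p_hat)
    XtWX_inv = np.linalg.inv(X.T @ (X * w[:, None]))
    rows = []
    freqs = {haplotype_label(h): f for h, f in em.frequencies.items()}
    for j, label in enumerate(dosages.columns):
        freq = freqs[label]
        if freq < prune_freq:
            continue
        d = D_all[:, j]
        U = float(d @ (y - p_hat))
        xwd = X.T @ (d * w)
        V = float(d @ (d * w) - xwd @ XtWX_inv @ xwd)
        if V <= 0:
            logger.warning("haplotype %s: non-positive score variance; skipped", label)
            continue
        z = U / np.sqrt(V)
        rows.append({
            "loci": "-".join(l.value for l in loci),
            "haplotype": label,
            "freq": freq,
            "effect": U / V,
            "score": z,
            "p": float(2 * stats.norm.sf(abs(z))),
            "n_used": int(len(y)),
        })
    return pd.DataFrame(rows, columns=["loci", "haplotype", "freq", "effect",
                                       "score", "p", "n_used"])


def haplotype_association_scan(
    cohort: Cohort,
    hla_class: int,
    arities: Sequence[int],
    comparison: tuple[Group, Group],
    **kwargs,
) -> pd.DataFrame:
    """Score tests over every locus combination of the requested arities
    within one HLA class; output is volcano-ready (adds -log10 p)."""
    class_loci = CLASS_I_LOCI if hla_class == 1 else CLASS_II_LOCI
    frames = []
    for arity in arities:
        if arity < 2 or arity > len(class_loci):
            raise ValueError(f"arity {arity} invalid for class with {len(class_loci)} loci")
        for combo in itertools.combinations(class_loci, arity):
            frames.append(haplotype_score_test(cohort, combo, comparison, **kwargs))
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if not out.empty:
        out["neglog10_p"] = -np.log10(out["p"])
    return out
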