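"""Synthetic cohorts, sequences, and rank tables with the statistical
structure the analysis assumes.

The generator emulates what the real study measured, at desk scale:

* per-locus HLA allele frequency spectra (explicit, or Dirichlet-sampled so
  spectra are skewed the way HLA spectra are), optional multi-locus
  haplotype frequencies to induce linkage disequilibrium, and an inbreeding
  knob ``f`` that produces the heterozygote deficit a failing HWE filter
  should catch;
* logistic case/control assignment with planted per-allele log-odds ratios
  plus age and sex covariate effects, filled to target group sizes by
  rejection sampling;
* per-allele best ranks for the two driver mutations drawn from a latent
  bivariate normal with correlation ``rho``, so the reported inverse
  CALRmut/JAK2 presentation trade-off can be planted and recovered.

Every draw funnels through one integer seed; the manifest of a generated
fixture suite records all planted parameters for mechanical truth-checking.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.stats import norm

from .hla import Cohort, Group, HlaAllele, Locus, LocusGenotype, Subject, parse_allele
from .hla import AlleleSequenceDB, write_genotype_table
from .peptides import PeptideSet, calr_context, jak2_context
from .peptides import enumerate_neo_terminus, enumerate_point_mutation
from .presentation import RankTable

logger = logging.getLogger(__name__)

# modest desk-scale spectrum sizes, skewed like real HLA loci
DEFAULT_N_ALLELES = {
    Locus.A: 15, Locus.B: 25, Locus.C: 15,
    Locus.DPB1: 10, Locus.DQA1: 8, Locus.DQB1: 8, Locus.DRB1: 12,
}


@dataclass
class SimulationConfig:
    """Parameters of one simulated study; defaults mirror the analysed cohort
    design (42 CALRmut+ / 158 JAK2 V617F+ / 1,083 controls)."""

    seed: int = 0
    n_calr: int = 42
    n_jak2: int = 158
    n_control: int = 1083
    # explicit spectra: {locus: {allele string: frequency}}; None -> Dirichlet
    allele_spectra: dict[Locus, dict[str, float]] | None = None
    n_alleles_per_locus: dict[Locus, int] = field(
        default_factory=lambda: dict(DEFAULT_N_ALLELES))
    dirichlet_concentration: float = 0.4
    # optional LD: (loci order, {allele-string tuple: frequency})
    haplotype_loci: tuple[Locus, ...] | None = None
    haplotype_freqs: dict[tuple[str, ...], float] | None = None
    inbreeding_f: float = 0.0
    # planted effects: {"CALR": {allele string: log OR}, "JAK2": {...}}
    planted_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    # combined population fraction of the two patient groups: MPNs are rare,
    # so cases are heavily oversampled relative to the source population and
    # the control stratum stays representative of it (population genotype
    # frequencies, HWE) even when allele effects are planted
    population_case_fraction: float = 0.05
    beta_age: float = 0.02  # per year, both patient groups (incidence rises with age)
    beta_sex: float = 0.3  # male indicator
    age_mean: float = 55.0
    age_sd: float = 15.0
    sex_ratio: float = 0.5  # fraction male
    # rank model: log10 BR range per mutation and the planted allele-level
    # correlation between the two mutations' BRs
    br_log10_range: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"CALRmut": (-2.0, 2.0), "JAK2V617F": (-2.0, 2.0)})
    rank_correlation_rho: float = -0.6

    def __post_init__(self) -> None:
        if not (0 <= self.inbreeding_f < 1):
            raise ValueError(f"inbreeding f {self.inbreeding_f} outside [0, 1)")
        if not (-1 <= self.rank_correlation_rho <= 1):
            raise ValueError(f"rho {self.rank_correlation_rho} outside [-1, 1]")
        if min(self.n_calr, self.n_jak2, self.n_control) < 0:
            raise ValueError("group sizes must be non-negative")
        if self.allele_spectra:
            for locus, spec in self.allele_spectra.items():
                total = sum(spec.values())
                if abs(total - 1.0) > 1e-6:
                    raise ValueError(f"{locus}: spectrum sums to {total}, not 1")
        if (self.haplotype_loci is None) != (self.haplotype_freqs is None):
            raise ValueError("haplotype_loci and haplotype_freqs go together")
        if self.haplotype_freqs:
            total = sum(self.haplotype_freqs.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"haplotype table sums to {total}, not 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["allele_spectra"] = (
            {l.value: dict(v) for l, v in self.allele_spectra.items()}
            if self.allele_spectra else None)
        d["n_alleles_per_locus"] = {l.value: n for l, n in self.n_alleles_per_locus.items()}
        d["haplotype_loci"] = ([l.value for l in self.haplotype_loci]
                               if self.haplotype_loci else None)
        d["haplotype_freqs"] = ({"|".join(k): v for k, v in self.haplotype_freqs.items()}
                                if self.haplotype_freqs else None)
        d["br_log10_range"] = {m: list(r) for m, r in self.br_log10_range.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if d.get("allele_spectra"):
            d["allele_spectra"] = {Locus(l): dict(v) for l, v in d["allele_spectra"].items()}
        if d.get("n_alleles_per_locus"):
            d["n_alleles_per_locus"] = {
                Locus(l): int(n) for l, n in d["n_alleles_per_locus"].items()}
        if d.get("haplotype_loci"):
            d["haplotype_loci"] = tuple(Locus(l) for l in d["haplotype_loci"])
        if d.get("haplotype_freqs"):
            d["haplotype_freqs"] = {
                tuple(k.split("|")): float(v) for k, v in d["haplotype_freqs"].items()}
        if d.get("br_log10_range"):
            d["br_log10_range"] = {m: tuple(r) for m, r in d["br_log10_range"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _spectra(config: SimulationConfig, rng: np.random.Generator
             ) -> dict[Locus, tuple[list[HlaAllele], np.ndarray]]:
    """Resolved per-locus spectra: (alleles, frequency vector)."""
    out = {}
    if config.allele_spectra:
        for locus, spec in config.allele_spectra.items():
            alleles = [parse_allele(a) for a in spec]
            out[locus] = (alleles, np.array(list(spec.values()), dtype=float))
        return out
    for locus, k in config.n_alleles_per_locus.items():
        freqs = rng.dirichlet(np.full(k, config.dirichlet_concentration))
        alleles = [HlaAllele(locus, i + 1, 1) for i in range(k)]
        out[locus] = (alleles, freqs)
    return out


def _draw_haplotypes(
    spectra: Mapping[Locus, tuple[list[HlaAllele], np.ndarray]],
    config: SimulationConfig,
    rng: np.random.Generator,
    n: int,
) -> list[dict[Locus, tuple[HlaAllele, HlaAllele]]]:
    """n subjects' unordered per-locus allele pairs."""
    loci = list(spectra)
    hap_loci = tuple(config.haplotype_loci or ())
    # per-locus columns of allele indices for haplotype 1 and 2, vectorized
    col1: dict[Locus, np.ndarray] = {}
    col2: dict[Locus, np.ndarray] = {}
    allele_lists: dict[Locus, list[HlaAllele]] = {}
    if config.haplotype_freqs:
        hap_alleles = [tuple(parse_allele(a) for a in k) for k in config.haplotype_freqs]
        hap_probs = np.array(list(config.haplotype_freqs.values()), dtype=float)
        draws = rng.choice(len(hap_alleles), size=(n, 2), p=hap_probs)
        for j, locus in enumerate(hap_loci):
            allele_lists[locus] = [h[j] for h in hap_alleles]
            col1[locus] = draws[:, 0]
            col2[locus] = draws[:, 1]
    for locus in loci:
        if locus in col1:
            continue
        alleles, probs = spectra[locus]
        draws = rng.choice(len(alleles), size=(n, 2), p=probs)
        allele_lists[locus] = list(alleles)
        col1[locus], col2[locus] = draws[:, 0], draws[:, 1]
    if config.inbreeding_f > 0:
        for locus in col1:
            copy_mask = rng.random(n) < config.inbreeding_f
            col2[locus] = np.where(copy_mask, col1[locus], col2[locus])
    all_loci = list(col1)
    subjects = []
    for i in range(n):
        subjects.append({
            l: (allele_lists[l][col1[l][i]], allele_lists[l][col2[l][i]])
            for l in all_loci
        })
    return subjects


def simulate_genotypes(config: SimulationConfig, n: int | None = None,
                       name: str = "simulated") -> Cohort:
    """Simulate a cohort of genotypes only (all subjects labelled CONTROL)."""
    rng = np.random.default_rng(config.seed)
    spectra = _spectra(config, rng)
    n = n if n is not None else config.n_calr + config.n_jak2 + config.n_control
    pairs = _draw_haplotypes(spectra, config, rng, n)
    subjects = [
        Subject(f"S{i:05d}", name, Group.CONTROL,
                genotypes={l: LocusGenotype(a1, a2) for l, (a1, a2) in p.items()})
        for i, p in enumerate(pairs)
    ]
    return Cohort(name, subjects)


def simulate_phenotypes(cohort: Cohort, config: SimulationConfig) -> Cohort:
    """Assign groups, ages and sexes to a pool of genotyped subjects by
    rejection sampling until the configured group sizes are met.

    The pool must be large enough; an exhausted pool raises with the
    shortfall so callers can regenerate with a bigger pool.
    """
    rng = np.random.default_rng(config.seed + 1)
    targets = {"CALR": config.n_calr, "JAK2": config.n_jak2, "CONTROL": config.n_control}
    # population intercepts: the two patient groups together make up
    # population_case_fraction of the source population, split in proportion
    # to the target sizes; quotas are then filled by rejection
    pcf = config.population_case_fraction
    n_cases = max(config.n_calr + config.n_jak2, 1)
    base = {}
    for grp, n_g in (("CALR", config.n_calr), ("JAK2", config.n_jak2)):
        frac = pcf * max(n_g, 0) / n_cases
        base[grp] = np.log(frac / (1 - pcf)) if frac > 0 else -np.inf
    filled = {g: 0 for g in targets}
    kept: list[Subject] = []
    planted = set()
    for grp_effects in config.planted_effects.values():
        planted.update(grp_effects)
    subjects = list(cohort)
    n = len(subjects)
    ages = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18, 95)
    males = rng.random(n) < config.sex_ratio
    dosage_cols = {}
    for a_str in planted:
        allele = parse_allele(a_str)
        dosage_cols[a_str] = np.array([
            (gt.dosage(allele) if (gt := s.genotypes.get(allele.locus)) else 0)
            for s in subjects], dtype=float)
    etas = {}
    for grp in ("CALR", "JAK2"):
        eta = np.full(n, base[grp])
        eta += config.beta_age * (ages - config.age_mean)
        eta += config.beta_sex * males
        for a_str, log_or in config.planted_effects.get(grp, {}).items():
            eta += log_or * dosage_cols[a_str]
        etas[grp] = eta
    with np.errstate(over="ignore"):
        w = np.column_stack([np.exp(etas["CALR"]), np.exp(etas["JAK2"]), np.ones(n)])
    probs = w / w.sum(axis=1, keepdims=True)
    u = rng.random(n)
    cum = np.cumsum(probs, axis=1)
    group_idx = (u[:, None] > cum).sum(axis=1)
    names = ("CALR", "JAK2", "CONTROL")
    for i, s in enumerate(subjects):
        if all(filled[g] >= targets[g] for g in targets):
            break
        grp = names[group_idx[i]]
        if filled[grp] >= targets[grp]:
            continue  # rejection: quota for this group already met
        filled[grp] += 1
        kept.append(Subject(s.subject_id, s.cohort, Group(grp), float(ages[i]),
                            "M" if males[i] else "F", dict(s.genotypes)))
    shortfall = {g: targets[g] - filled[g] for g in targets if filled[g] < targets[g]}
    if shortfall:
        raise ValueError(f"pool exhausted before group sizes met; missing {shortfall}")
    return Cohort(cohort.name, kept)


def simulate_cohort(config: SimulationConfig, name: str = "simulated",
                    pool_margin: float = 1.4) -> Cohort:
    """Genotypes + phenotypes in one call, growing the pool until targets fill.

    The pool must be large enough that the rare patient groups fill at the
    configured population case fraction.
    """
    pcf = config.population_case_fraction
    n_cases = config.n_calr + config.n_jak2
    need = max(n_cases / pcf if n_cases else 0.0,
               config.n_control / max(1 - pcf, 1e-9))
    factor = pool_margin
    for attempt in range(4):
        pool = simulate_genotypes(config, n=int(need * factor) + 50, name=name)
        try:
            return simulate_phenotypes(pool, config)
        except ValueError:
            factor *= 2
    raise ValueError("could not meet group sizes; check planted effects/intercepts")


def simulate_rank_table(
    alleles: Sequence[HlaAllele],
    psets: Mapping[str, PeptideSet],
    config: SimulationConfig,
) -> tuple[dict[str, RankTable], dict[HlaAllele, dict[str, float]]]:
    """Rank tables per mutation with planted allele-level BR correlation.

    Per allele a latent bivariate normal with correlation ``rho`` is mapped
    through its CDF to a log10-uniform BR in the configured range per
    mutation.  Peptide ranks are then filled so the minimum over the
    mutation's peptides equals the drawn BR exactly (one carrier peptide,
    the rest uniformly above).  Returns (tables, drawn BR truth).
    """
    if len(psets) != 2:
        raise ValueError("rank model plants a correlation between exactly two mutations")
    for mut, pset in psets.items():
        if len(pset.peptide_strings()) == 0:
            raise ValueError(f"empty peptide set for {mut}")
    rng = np.random.default_rng(config.seed + 2)
    rho = config.rank_correlation_rho
    cov = np.array([[1.0, rho], [rho, 1.0]])
    muts = sorted(psets)
    tables = {m: RankTable() for m in muts}
    truth: dict[HlaAllele, dict[str, float]] = {}
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
    for allele in sorted(set(alleles)):
        z = L @ rng.standard_normal(2)
        truth[allele] = {}
        for m, zm in zip(muts, z):
            lo, hi = config.br_log10_range[m]
            br = float(10.0 ** (lo + norm.cdf(zm) * (hi - lo)))
            br = min(br, 100.0)
            truth[allele][m] = br
            peptides = psets[m].peptide_strings()
            carrier = int(rng.integers(len(peptides)))
            for i, pep in enumerate(peptides):
                if i == carrier:
                    rank = br
                else:
                    rank = float(br + rng.random() * (100.0 - br))
                    rank = max(rank, br)
                tables[m].add(allele, pep, min(rank, 100.0))
    return tables, truth


def simulate_sequences(
    alleles: Sequence[HlaAllele],
    length: int = 90,
    divergence_scale: float = 0.2,
    seed: int = 0,
) -> AlleleSequenceDB:
    """Random equal-length binding-groove sequences per locus.

    Each locus gets a random base sequence; each allele substitutes every
    site independently with probability ``divergence_scale``, so expected
    pairwise divergence (hence HED) grows monotonically with the scale.
    """
    rng = np.random.default_rng(seed)
    residues = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    db = AlleleSequenceDB({})
    by_locus: dict[Locus, list[HlaAllele]] = {}
    for a in sorted(set(alleles)):
        by_locus.setdefault(a.locus, []).append(a)
    for locus in sorted(by_locus, key=lambda l: l.value):
        base = rng.choice(residues, size=length)
        for allele in by_locus[locus]:
            seq = base.copy()
            mask = rng.random(length) < divergence_scale
            seq[mask] = rng.choice(residues, size=int(mask.sum()))
            db.add(allele, "".join(seq))
    return db


def generate_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict:
    """Write a complete miniature study to ``out_dir`` and return its manifest.

    Three cohorts with a planted protective allele (C*06:02, OR 0.4 for the
    CALR group), sequence FASTA, per-mutation rank tables with BR correlation
    -0.6, and a YAML/JSON manifest recording every planted parameter.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    protective = "C*06:02"
    spectra = {
        Locus.A: _named_spectrum(Locus.A, ["01:01", "02:01", "03:01", "11:01", "24:02"],
                                 [0.25, 0.30, 0.15, 0.15, 0.15]),
        Locus.B: _named_spectrum(Locus.B, ["07:02", "08:01", "18:01", "35:01", "44:02", "51:01"],
                                 [0.20, 0.15, 0.15, 0.20, 0.15, 0.15]),
        Locus.C: _named_spectrum(Locus.C, ["01:02", "04:01", "06:02", "07:01", "07:02"],
                                 [0.20, 0.20, 0.10, 0.25, 0.25]),
        Locus.DQB1: _named_spectrum(Locus.DQB1, ["02:01", "03:01", "05:01", "06:02"],
                                    [0.3, 0.3, 0.2, 0.2]),
        Locus.DRB1: _named_spectrum(Locus.DRB1, ["01:01", "03:01", "07:01", "15:01"],
                                    [0.25, 0.25, 0.25, 0.25]),
    }
    planted_or = 0.4
    cohort_sizes = {"ALPHA": (14, 30, 70), "BETA": (12, 26, 60), "GAMMA": (10, 22, 50)}
    cohorts = {}
    for i, (name, (nc, nj, nctl)) in enumerate(cohort_sizes.items()):
        cfg = SimulationConfig(
            seed=seed + 10 * i,
            n_calr=nc, n_jak2=nj, n_control=nctl,
            allele_spectra=spectra,
            planted_effects={"CALR": {protective: float(np.log(planted_or))}},
            rank_correlation_rho=-0.6,
        )
        cohorts[name] = (cfg, simulate_cohort(cfg, name=name))
        write_genotype_table(cohorts[name][1], out_dir / f"genotypes_{name}.tsv")
    class_i_alleles = sorted({
        a for _, c in cohorts.values() for s in c for l, gt in s.genotypes.items()
        if l.hla_class == 1 for a in gt.alleles
    })
    all_alleles = sorted({
        a for _, c in cohorts.values() for s in c for gt in s.genotypes.values()
        for a in gt.alleles
    })
    psets = {
        "CALRmut": enumerate_neo_terminus(calr_context()),
        "JAK2V617F": enumerate_point_mutation(jak2_context()),
    }
    rank_cfg = SimulationConfig(seed=seed + 500, rank_correlation_rho=-0.6)
    tables, truth = simulate_rank_table(class_i_alleles, psets, rank_cfg)
    for mut, table in tables.items():
        table.write_tsv(out_dir / f"ranks_{mut}.tsv")
    db = simulate_sequences(all_alleles, length=90, divergence_scale=0.2, seed=seed + 900)
    with (out_dir / "sequences.fasta").open("w") as fh:
        for allele in db.alleles():
            fh.write(f">{allele}\n{db[allele]}\n")
    manifest = {
        "seed": seed,
        "cohorts": {name: {"n_calr": cfg.n_calr, "n_jak2": cfg.n_jak2,
                           "n_control": cfg.n_control, "seed": cfg.seed}
                    for name, (cfg, _) in cohorts.items()},
        "planted_protective_allele": protective,
        "planted_odds_ratio": planted_or,
        "rank_correlation_rho": -0.6,
        "br_truth": {str(a): v for a, v in truth.items()},
        "files": {
            "genotypes": [f"genotypes_{n}.tsv" for n in cohort_sizes],
            "ranks": [f"ranks_{m}.tsv" for m in sorted(tables)],
            "sequences": "sequences.fasta",
        },
    }
    with (out_dir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _named_spectrum(locus: Locus, names: Sequence[str], freqs: Sequence[float]
                    ) -> dict[str, float]:
    assert abs(sum(freqs) - 1.0) < 1e-9
    return {f"{locus.value}*{n}": f for n, f in zip(names, freqs)}
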