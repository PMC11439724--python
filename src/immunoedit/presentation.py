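"""Percentile-rank ingestion and presentation scoring: BR, PHBR, SB/WB/NB.

A binding predictor assigns each (HLA allele, peptide) pair a percentile
rank in (0, 100] — the fraction of random natural peptides predicted to bind
better; lower is better.  Per allele and mutation the *best rank* (BR) is
the minimum rank over the mutation's peptide set.  Per subject the *PHBR*
(patient harmonic-mean best rank) is the harmonic mean of the six class I
allele BRs, with homozygous alleles contributing twice: a subject presents a
mutation well if ANY of their six alleles does, which the harmonic mean's
sensitivity to small terms captures.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .hla import CLASS_I_LOCI, Cohort, HlaAllele, Subject, parse_allele
from .peptides import PeptideSet

logger = logging.getLogger(__name__)

SB_THRESHOLD = 0.5  # percent rank; NetMHCpan-style strong-binder cutoff
WB_THRESHOLD = 2.0  # percent rank; weak-binder cutoff


class BinderCategory(str, Enum):
    SB = "SB"
    WB = "WB"
    NB = "NB"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


def categorize_allele(br_value: float) -> BinderCategory:
    """SB iff br <= 0.5, WB iff 0.5 < br <= 2.0, NB otherwise (boundaries inclusive)."""
    if br_value <= 0:
        raise ValueError(f"percent rank must be positive, got {br_value}")
    if br_value <= SB_THRESHOLD:
        return BinderCategory.SB
    if br_value <= WB_THRESHOLD:
        return BinderCategory.WB
    return BinderCategory.NB


class RankTable:
    """Mapping (allele, peptide) -> percent rank in (0, 100]."""

    def __init__(self, entries: Mapping[tuple[HlaAllele, str], float] | None = None):
        self._ranks: dict[tuple[HlaAllele, str], float] = {}
        if entries:
            for (allele, pep), rank in entries.items():
                self.add(allele, pep, rank)

    def add(self, allele: HlaAllele, peptide: str, rank: float) -> None:
        if not 0 < rank <= 100:
            raise ValueError(f"percent rank {rank} for ({allele}, {peptide}) outside (0, 100]")
        key = (allele, peptide)
        if key in self._ranks and self._ranks[key] != rank:
            raise ValueError(
                f"conflicting ranks for ({allele}, {peptide}): "
                f"{self._ranks[key]} vs {rank}"
            )
        self._ranks[key] = rank

    def __len__(self) -> int:
        return len(self._ranks)

    def __contains__(self, key: tuple[HlaAllele, str]) -> bool:
        return key in self._ranks

    def __getitem__(self, key: tuple[HlaAllele, str]) -> float:
        return self._ranks[key]

    def get(self, allele: HlaAllele, peptide: str, default=None):
        return self._ranks.get((allele, peptide), default)

    def items(self):
        return self._ranks.items()

    def alleles(self) -> list[HlaAllele]:
        return sorted({a for a, _ in self._ranks})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"allele": str(a), "peptide": p, "percent_rank": r}
            for (a, p), r in sorted(self._ranks.items(), key=lambda kv: (kv[0][0], kv[0][1]))
        ]
        return pd.DataFrame(rows, columns=["allele", "peptide", "percent_rank"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_rank_table(path: str | Path, dialect: str = "simple_tsv") -> RankTable:
    """Read (allele, peptide) percent ranks.

    ``simple_tsv``: columns allele, peptide, percent_rank.
    ``netmhcpan_tab``: the predictor's tab-delimited multi-allele export —
    a first line carrying allele names above their column blocks, a second
    line with per-block column headers including a rank column
    (``EL_Rank``/``Rank``/``%Rank``), then one row per peptide.
    """
    path = Path(path)
    table = RankTable()
    if dialect == "simple_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"allele": str, "peptide": str})
        for col in ("allele", "peptide", "percent_rank"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        for rec in df.itertuples(index=False):
            rank = float(rec.percent_rank)
            table.add(parse_allele(rec.allele), rec.peptide, rank)
        return table
    if dialect == "netmhcpan_tab":
        return _read_netmhcpan_tab(path)
    raise ValueError(f"unknown rank-table dialect {dialect!r}")


def _read_netmhcpan_tab(path: Path) -> RankTable:
    lines = [ln.rstrip("\n") for ln in path.open() if ln.strip() and not ln.startswith("#")]
    if len(lines) < 3:
        raise ValueError(f"{path}: not a multi-allele tab export (needs 2 header lines + data)")
    allele_line = lines[0].split("\t")
    header = lines[1].split("\t")
    # allele names sit above the first column of each per-allele block
    allele_at: dict[int, HlaAllele] = {}
    for idx, cell in enumerate(allele_line):
        cell = cell.strip()
        if cell:
            allele_at[idx] = parse_allele(cell)
    rank_cols: list[tuple[int, HlaAllele]] = []
    current: HlaAllele | None = None
    for idx, name in enumerate(header):
        if idx in allele_at:
            current = allele_at[idx]
        if name.strip().lstrip("%").replace("_", "").lower() in ("elrank", "rank", "rankel"):
            if current is None:
                raise ValueError(f"{path}: rank column {idx} precedes any allele name")
            rank_cols.append((idx, current))
    if not rank_cols:
        raise ValueError(f"{path}: no rank column found in header {header}")
    try:
        pep_col = next(i for i, name in enumerate(header) if name.strip().lower() == "peptide")
    except StopIteration:
        raise ValueError(f"{path}: no Peptide column in header") from None
    table = RankTable()
    for ln in lines[2:]:
        cells = ln.split("\t")
        peptide = cells[pep_col].strip()
        for idx, allele in rank_cols:
            try:
                rank = float(cells[idx])
            except (IndexError, ValueError):
                raise ValueError(f"{path}: unparseable rank in row {cells!r}") from None
            table.add(allele, peptide, rank)
    return table


def mock_rank_predictor(
    alleles: Sequence[HlaAllele],
    peptides: Sequence[str],
    seed: int,
    planted: Mapping[tuple[HlaAllele, str], float] | None = None,
) -> RankTable:
    """Deterministic stand-in predictor for tests and simulations.

    Each (allele, peptide) rank is the quantile of a stable integer hash of
    (allele, peptide, seed), mapped to (0, 100]; identical inputs and seed
    reproduce identical tables bit-for-bit on any platform.  ``planted``
    entries override the hash draw.
    """
    planted = dict(planted or {})
    for key, rank in planted.items():
        if not 0 < rank <= 100:
            raise ValueError(f"planted rank {rank} for {key} outside (0, 100]")
    table = RankTable()
    for allele in alleles:
        for pep in peptides:
            if (allele, pep) in planted:
                rank = planted[(allele, pep)]
            else:
                digest = hashlib.blake2b(
                    f"{allele}|{pep}|{seed}".encode(), digest_size=8
                ).digest()
                u = int.from_bytes(digest, "big") / 2**64  # uniform [0, 1)
                rank = (1.0 - u) * 100.0  # uniform (0, 100]
            table.add(allele, pep, rank)
    return table


@dataclass(frozen=True)
class AlleleBR:
    allele: HlaAllele
    mutation_id: str
    br: float

    def __post_init__(self) -> None:
        if self.br <= 0:
            raise ValueError(f"best rank must be positive, got {self.br}")

    @property
    def category(self) -> BinderCategory:
        return categorize_allele(self.br)


def best_rank(
    table: RankTable,
    allele: HlaAllele,
    pset: PeptideSet,
    max_missing_fraction: float = 0.0,
    missing_rank: float = 100.0,
) -> AlleleBR:
    """Minimum percent rank over a mutation's (deduplicated) peptides for one allele.

    Peptides absent from the table beyond ``max_missing_fraction`` raise; the
    tolerated missing ones are treated as ``missing_rank`` (non-binding).
    """
    peptides = pset.peptide_strings()
    ranks = []
    missing = []
    for pep in peptides:
        r = table.get(allele, pep)
        if r is None:
            missing.append(pep)
        else:
            ranks.append(r)
    if not ranks and not missing:
        raise ValueError(f"empty peptide set for {pset.mutation_id}")
    if len(missing) / len(peptides) > max_missing_fraction:
        raise ValueError(
            f"allele {allele}: {len(missing)}/{len(peptides)} peptides of "
            f"{pset.mutation_id} missing from rank table (e.g. {missing[:3]})"
        )
    if missing:
        logger.warning("allele %s: %d missing peptides treated as rank %s",
                       allele, len(missing), missing_rank)
        ranks.extend([missing_rank] * len(missing))
    return AlleleBR(allele, pset.mutation_id, min(ranks))


@dataclass(frozen=True)
class PhbrResult:
    subject_id: str
    mutation_id: str
    phbr: float
    n_alleles_used: int


def phbr(
    subject: Subject,
    brs: Mapping[HlaAllele, AlleleBR],
    mutation_id: str,
) -> PhbrResult:
    """Harmonic mean of the six class I allele BRs of a subject.

    Homozygous alleles contribute their BR twice.  Any untyped class I locus
    or missing BR raises — no silent imputation.
    """
    values: list[float] = []
    for locus in CLASS_I_LOCI:
        gt = subject.genotypes.get(locus)
        if gt is None:
            raise ValueError(f"subject {subject.subject_id}: class I locus {locus} untyped")
        for allele in gt.alleles:  # homozygotes appear twice
            if allele not in brs:
                raise ValueError(
                    f"subject {subject.subject_id}: no BR for allele {allele} "
                    f"({mutation_id})"
                )
            values.append(brs[allele].br)
    n = len(values)
    hm = n / sum(1.0 / v for v in values)
    return PhbrResult(subject.subject_id, mutation_id, hm, n)


def allele_best_ranks(
    table: RankTable, pset: PeptideSet, alleles: Iterable[HlaAllele], **kwargs
) -> dict[HlaAllele, AlleleBR]:
    """best_rank over a collection of alleles, as a mapping."""
    return {a: best_rank(table, a, pset, **kwargs) for a in set(alleles)}


def cohort_phbr_table(
    cohort: Cohort,
    tables: Mapping[str, RankTable],
    psets: Mapping[str, PeptideSet],
    **kwargs,
) -> tuple[pd.DataFrame, list[dict]]:
    """One PHBR row per (subject, mutation); incomplete subjects are skipped and reported.

    Returns (table, skipped) where skipped records subject_id, mutation_id
    and the reason.
    """
    if set(tables) != set(psets):
        raise ValueError("tables and psets must cover the same mutation_ids")
    # BRs once per mutation for the class I alleles actually present in the cohort
    class_i_alleles = sorted({
        a for s in cohort for locus, gt in s.genotypes.items()
        if locus in CLASS_I_LOCI for a in gt.alleles
    })
    br_cache = {
        mut: allele_best_ranks(tables[mut], psets[mut], class_i_alleles, **kwargs)
        for mut in sorted(tables)
    }
    rows = []
    skipped = []
    for s in cohort:
        for mut in sorted(tables):
            try:
                res = phbr(s, br_cache[mut], mut)
            except ValueError as exc:
                skipped.append({"subject_id": s.subject_id, "mutation_id": mut,
                                "reason": str(exc)})
                continue
            rows.append({
                "subject_id": s.subject_id,
                "cohort": s.cohort,
                "group": s.group.value,
                "mutation_id": mut,
                "phbr": res.phbr,
                "n_alleles_used": res.n_alleles_used,
            })
    cols = ["subject_id", "cohort", "group", "mutation_id", "phbr", "n_alleles_used"]
    return pd.DataFrame(rows, columns=cols), skipped
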