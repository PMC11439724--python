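"""HLA nomenclature, genotypes, cohorts, and readers for the tabular/FASTA formats.

The analysis universe is two-field HLA resolution (allele group + protein,
e.g. ``C*06:02``) over the seven classical loci typed in the study design:
class I ``A``, ``B``, ``C`` and class II ``DPB1``, ``DQA1``, ``DQB1``,
``DRB1``.  Anything beyond two fields (synonymous/noncoding fields,
expression suffixes) is truncated or stripped at ingest.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class Locus(str, Enum):
    A = "A"
    B = "B"
    C = "C"
    DPB1 = "DPB1"
    DQA1 = "DQA1"
    DQB1 = "DQB1"
    DRB1 = "DRB1"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def hla_class(self) -> int:
        return 1 if self in CLASS_I_LOCI else 2


CLASS_I_LOCI = (Locus.A, Locus.B, Locus.C)
CLASS_II_LOCI = (Locus.DPB1, Locus.DQA1, Locus.DQB1, Locus.DRB1)


class Group(str, Enum):
    """Disease group of a subject: driver-mutation carriers or healthy controls."""

    CALR = "CALR"
    JAK2 = "JAK2"
    CONTROL = "CONTROL"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


class HlaParseError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class HlaAllele:
    """A two-field HLA allele, e.g. ``HlaAllele(Locus.C, 6, 2)`` == C*06:02.

    ``suffix_stripped`` records that an expression suffix (N/L/S/Q) was
    removed on parse; it does not take part in equality or hashing.
    """

    locus: Locus
    field1: int
    field2: int
    suffix_stripped: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.field1 < 0 or self.field2 < 0:
            raise HlaParseError(f"negative allele field in {self!r}")

    @property
    def hla_class(self) -> int:
        return self.locus.hla_class

    def __str__(self) -> str:
        return f"{self.locus.value}*{self.field1:02d}:{self.field2:02d}"


_ALLELE_RE = re.compile(
    r"^(?:HLA[-:])?"
    r"(?P<locus>[A-Z][A-Z0-9]*)"
    r"\*(?P<f1>\d+)"
    r":(?P<f2>\d+)"
    r"(?P<rest>(?::\d+)*)"
    r"(?P<suffix>[NLSQ]?)$"
)


def parse_allele(text: str) -> HlaAllele:
    """Parse an HLA allele string to two-field resolution.

    Accepts an optional ``HLA-`` prefix, higher-resolution fields (truncated),
    and expression suffixes N/L/S/Q (stripped, recorded on the allele).

    >>> str(parse_allele("HLA-A*02:01:01:02"))
    'A*02:01'
    """
    if not text or not text.strip():
        raise HlaParseError("empty allele string")
    token = text.strip()
    m = _ALLELE_RE.match(token)
    if m is None:
        raise HlaParseError(f"malformed HLA allele string: {token!r}")
    locus_str = m.group("locus")
    try:
        locus = Locus(locus_str)
    except ValueError:
        raise HlaParseError(f"unknown HLA locus {locus_str!r} in {token!r}") from None
    suffix = bool(m.group("suffix"))
    if suffix:
        logger.warning("stripped expression suffix %r from %r", m.group("suffix"), token)
    return HlaAllele(locus, int(m.group("f1")), int(m.group("f2")), suffix_stripped=suffix)


@dataclass(frozen=True)
class LocusGenotype:
    """An unordered pair of alleles at one locus."""

    allele1: HlaAllele
    allele2: HlaAllele

    def __post_init__(self) -> None:
        if self.allele1.locus is not self.allele2.locus:
            raise ValueError(
                f"genotype alleles at different loci: {self.allele1} / {self.allele2}"
            )
        # normalize order so equality/hash ignore input order
        if self.allele2 < self.allele1:
            a1, a2 = self.allele2, self.allele1
            object.__setattr__(self, "allele1", a1)
            object.__setattr__(self, "allele2", a2)

    @property
    def locus(self) -> Locus:
        return self.allele1.locus

    @property
    def homozygous(self) -> bool:
        return self.allele1 == self.allele2

    @property
    def alleles(self) -> tuple[HlaAllele, HlaAllele]:
        return (self.allele1, self.allele2)

    def dosage(self, allele: HlaAllele) -> int:
        return int(self.allele1 == allele) + int(self.allele2 == allele)


@dataclass
class Subject:
    subject_id: str
    cohort: str
    group: Group
    age: float | None = None
    sex: str | None = None  # "M" / "F"
    genotypes: dict[Locus, LocusGenotype] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age is not None and not (0 <= self.age <= 120):
            raise ValueError(f"subject {self.subject_id}: age {self.age} outside [0, 120]")
        if self.sex is not None and self.sex not in ("M", "F"):
            raise ValueError(f"subject {self.subject_id}: sex must be 'M' or 'F'")

    def class_i_alleles(self) -> list[HlaAllele] | None:
        """The six class I alleles (duplicates kept), or None if any locus is untyped."""
        out: list[HlaAllele] = []
        for locus in CLASS_I_LOCI:
            gt = self.genotypes.get(locus)
            if gt is None:
                return None
            out.extend(gt.alleles)
        return out


@dataclass
class Cohort:
    name: str
    subjects: list[Subject] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject_id(s) in cohort {self.name!r}: {dup}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def group_counts(self) -> dict[Group, int]:
        counts = {g: 0 for g in Group}
        for s in self.subjects:
            counts[s.group] += 1
        return counts

    def subset(self, groups: Iterable[Group], name: str | None = None) -> "Cohort":
        wanted = set(groups)
        return Cohort(name or self.name, [s for s in self.subjects if s.group in wanted])


GENOTYPE_META_COLUMNS = ["subject_id", "cohort", "group", "age", "sex"]


def _locus_columns() -> list[str]:
    cols = []
    for locus in Locus:
        cols += [f"{locus.value}_1", f"{locus.value}_2"]
    return cols


def read_genotype_table(path: str | Path, name: str | None = None) -> Cohort:
    """Read a cohort genotype TSV.

    Columns: ``subject_id, cohort, group, age, sex`` then ``<LOCUS>_1/<LOCUS>_2``
    allele pairs.  Empty cells and ``NA`` mean missing.  A locus with exactly
    one missing allele is dropped for that subject (logged): downstream scores
    need complete pairs and a single allele would fabricate homozygosity.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in GENOTYPE_META_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing mandatory column(s) {missing_cols}")
    subjects = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        group_raw = rec["group"].strip()
        try:
            group = Group(group_raw)
        except ValueError:
            raise ValueError(
                f"{path}: subject {rec['subject_id']!r}: unknown group {group_raw!r}"
            ) from None
        age_raw = rec.get("age", "").strip()
        age = None if age_raw in ("", "NA") else float(age_raw)
        sex_raw = rec.get("sex", "").strip()
        sex = None if sex_raw in ("", "NA") else sex_raw
        genotypes: dict[Locus, LocusGenotype] = {}
        for locus in Locus:
            a1 = rec.get(f"{locus.value}_1", "").strip()
            a2 = rec.get(f"{locus.value}_2", "").strip()
            present = [a for a in (a1, a2) if a not in ("", "NA")]
            if len(present) == 0:
                continue
            if len(present) == 1:
                logger.warning(
                    "subject %s: locus %s has one missing allele; locus dropped",
                    rec["subject_id"], locus.value,
                )
                continue
            genotypes[locus] = LocusGenotype(parse_allele(a1), parse_allele(a2))
        subjects.append(
            Subject(rec["subject_id"], rec["cohort"], group, age, sex, genotypes)
        )
    return Cohort(name or (subjects[0].cohort if subjects else path.stem), subjects)


def write_genotype_table(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort in the same TSV dialect `read_genotype_table` consumes."""
    rows = []
    for s in cohort:
        rec = {
            "subject_id": s.subject_id,
            "cohort": s.cohort,
            "group": s.group.value,
            "age": "" if s.age is None else format(s.age, "g"),
            "sex": s.sex or "",
        }
        for locus in Locus:
            gt = s.genotypes.get(locus)
            rec[f"{locus.value}_1"] = str(gt.allele1) if gt else ""
            rec[f"{locus.value}_2"] = str(gt.allele2) if gt else ""
        rows.append(rec)
    df = pd.DataFrame(rows, columns=GENOTYPE_META_COLUMNS + _locus_columns())
    df.to_csv(path, sep="\t", index=False)


class AlleleSequenceDB:
    """Amino-acid sequences per two-field allele (binding-groove segment).

    All sequences at one locus must have equal length so positions align
    site-by-site for divergence computation.
    """

    def __init__(self, sequences: Mapping[HlaAllele, str]):
        self._seqs: dict[HlaAllele, str] = {}
        for allele, seq in sequences.items():
            self.add(allele, seq)

    def add(self, allele: HlaAllele, seq: str) -> None:
        seq = seq.upper()
        bad = set(seq) - STANDARD_RESIDUES
        if bad:
            raise ValueError(f"{allele}: nonstandard residue(s) {sorted(bad)}")
        for other, oseq in self._seqs.items():
            if other.locus is allele.locus and len(oseq) != len(seq):
                raise ValueError(
                    f"locus {allele.locus}: sequence length mismatch "
                    f"({allele}: {len(seq)} vs {other}: {len(oseq)})"
                )
        self._seqs[allele] = seq

    def __getitem__(self, allele: HlaAllele) -> str:
        return self._seqs[allele]

    def __contains__(self, allele: HlaAllele) -> bool:
        return allele in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def alleles(self) -> list[HlaAllele]:
        return sorted(self._seqs)

    def get(self, allele: HlaAllele, default=None):
        return self._seqs.get(allele, default)


def read_imgt_protein_fasta(
    path: str | Path,
    locus_domain_spec: Mapping[Locus, tuple[int, int]] | None = None,
) -> AlleleSequenceDB:
    """Load allele protein sequences from an IMGT-style FASTA.

    Headers may look like ``HLA:HLA00001 A*01:01:01:01 365 bp`` or simply
    ``A*01:01``; the first token parseable as an allele is used.  Per
    two-field allele the FIRST full-length record wins (reference-allele
    convention).  ``locus_domain_spec`` maps a locus to a 1-based inclusive
    residue range extracted after load (default: whole sequence).
    Records with gap/unknown characters are rejected and logged.
    """
    path = Path(path)
    kept: dict[HlaAllele, str] = {}
    n_records = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        allele = None
        for token in (record.id, *record.description.split()):
            try:
                allele = parse_allele(token)
                break
            except HlaParseError:
                continue
        if allele is None:
            logger.warning("%s: no parseable allele name in header %r; record skipped",
                           path, record.description)
            continue
        allele = replace(allele, suffix_stripped=False)
        seq = str(record.seq).upper()
        if set(seq) - STANDARD_RESIDUES:
            logger.warning("%s: %s contains gap/unknown characters; record rejected",
                           path, allele)
            continue
        if locus_domain_spec and allele.locus in locus_domain_spec:
            start, end = locus_domain_spec[allele.locus]
            if end > len(seq):
                logger.warning("%s: %s shorter than domain range %s-%s; record rejected",
                               path, allele, start, end)
                continue
            seq = seq[start - 1 : end]
        if allele in kept:
            continue  # first full-length record per two-field allele wins
        kept[allele] = seq
    if n_records == 0:
        logger.warning("%s: empty FASTA, returning empty sequence DB", path)
    # build (and validate per-locus equal length) with offending alleles listed
    by_locus: dict[Locus, dict[int, list[HlaAllele]]] = {}
    for allele, seq in kept.items():
        by_locus.setdefault(allele.locus, {}).setdefault(len(seq), []).append(allele)
    errors = []
    for locus, lengths in by_locus.items():
        if len(lengths) > 1:
            detail = "; ".join(
                f"length {L}: {', '.join(map(str, sorted(v)))}" for L, v in sorted(lengths.items())
            )
            errors.append(f"locus {locus}: {detail}")
    if errors:
        raise ValueError(f"{path}: per-locus sequence length mismatch — " + " | ".join(errors))
    return AlleleSequenceDB(kept)


def allele_counts(cohort: Cohort, locus: Locus) -> pd.DataFrame:
    """Carrier counts, allele counts and frequencies at one locus.

    Frequency = allele count / (2 x number of subjects typed at the locus);
    frequencies sum to 1 over the locus.
    """
    counts: dict[HlaAllele, int] = {}
    carriers: dict[HlaAllele, int] = {}
    n_typed = 0
    for s in cohort:
        gt = s.genotypes.get(locus)
        if gt is None:
            continue
        n_typed += 1
        for a in set(gt.alleles):
            carriers[a] = carriers.get(a, 0) + 1
        for a in gt.alleles:
            counts[a] = counts.get(a, 0) + 1
    if n_typed == 0:
        raise ValueError(f"no subject typed at locus {locus}")
    rows = [
        {
            "allele": str(a),
            "carrier_count": carriers[a],
            "allele_count": counts[a],
            "frequency": counts[a] / (2 * n_typed),
        }
        for a in sorted(counts)
    ]
    return pd.DataFrame(rows)
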