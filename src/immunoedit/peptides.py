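"""Candidate neoantigen peptide enumeration for the two MPN driver-mutation modes.

Two shapes of mutant sequence occur:

* a *neo-terminus* — the frameshifted CALR exon 9 mutations all converge on
  one novel C-terminal protein tail, so every k-mer window of that tail is a
  candidate neoantigen;
* a *point substitution* — JAK2 V617F changes a single residue, so only
  windows overlapping the mutated position are candidates.

Windows are counted positionally (start, length), 1-based and inclusive:
repeated peptide strings at distinct positions are distinct windows, and
deduplication happens only when peptides are handed to a binding predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator

# The shared novel C-terminal tail produced by the recurrent frameshifting
# CALR exon 9 mutations (44 residues).
CALR_NEO_TERMINUS = "RRMMRTKMRMRRMRRTRRKMRRKMSPARPRTSCREACLQGWTEA"

# Human JAK2 pseudokinase-domain segment, residues 591-640, with the V617F
# substitution (F at local position 27).  Window counts depend only on the
# mutated residue having >=10 residues of flank on each side, which holds here.
JAK2_V617F_REGION = "SESFFEAASMMSKLSHKHLVLNYGVCFCGDENILVQEFVKFGSLDTYLKK"
JAK2_V617F_LOCAL_POSITION = 27


class MutationMode(str, Enum):
    NEO_TERMINUS = "NEO_TERMINUS"
    POINT_SUBSTITUTION = "POINT_SUBSTITUTION"


@dataclass(frozen=True)
class MutationContext:
    """A mutant protein context from which candidate peptides are cut.

    For POINT_SUBSTITUTION the sequence already carries the mutant residue at
    ``mutated_position`` (1-based).
    """

    mutation_id: str
    mode: MutationMode
    sequence: str
    mutated_position: int | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 8:
            raise ValueError(f"{self.mutation_id}: context shorter than 8 residues")
        if self.mode is MutationMode.POINT_SUBSTITUTION:
            if self.mutated_position is None:
                raise ValueError(f"{self.mutation_id}: POINT_SUBSTITUTION needs mutated_position")
            if not (1 <= self.mutated_position <= len(self.sequence)):
                raise ValueError(
                    f"{self.mutation_id}: mutated_position {self.mutated_position} "
                    f"outside sequence of length {len(self.sequence)}"
                )


def calr_context() -> MutationContext:
    """The built-in CALR neo-terminus context."""
    return MutationContext("CALRmut", MutationMode.NEO_TERMINUS, CALR_NEO_TERMINUS)


def jak2_context() -> MutationContext:
    """The built-in JAK2 V617F point-substitution context."""
    return MutationContext(
        "JAK2V617F",
        MutationMode.POINT_SUBSTITUTION,
        JAK2_V617F_REGION,
        JAK2_V617F_LOCAL_POSITION,
    )


@dataclass(frozen=True)
class Window:
    start: int  # 1-based
    length: int
    peptide: str


@dataclass
class PeptideSet:
    mutation_id: str
    windows: list[Window] = field(default_factory=list)
    k_range: tuple[int, int] = (8, 11)

    def __post_init__(self) -> None:
        k_min, k_max = self.k_range
        seen = set()
        for w in self.windows:
            if not (k_min <= w.length <= k_max):
                raise ValueError(f"window length {w.length} outside k range {self.k_range}")
            if (w.start, w.length) in seen:
                raise ValueError(f"duplicate window ({w.start}, {w.length})")
            seen.add((w.start, w.length))

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[Window]:
        return iter(self.windows)

    def peptide_strings(self) -> list[str]:
        """Deduplicated peptide strings in order of first occurrence (for predictors)."""
        seen = set()
        out = []
        for w in self.windows:
            if w.peptide not in seen:
                seen.add(w.peptide)
                out.append(w.peptide)
        return out


def _cut(context: MutationContext, start: int, k: int) -> Window:
    return Window(start, k, context.sequence[start - 1 : start - 1 + k])


def enumerate_neo_terminus(
    context: MutationContext, k_min: int = 8, k_max: int = 11
) -> PeptideSet:
    """All k-mer windows, k in [k_min, k_max], of a neo-terminus context.

    Window count is sum over k of (L - k + 1).  For the built-in 44-residue
    CALR tail at k 8..11 this gives 142 windows.
    """
    if context.mode is not MutationMode.NEO_TERMINUS:
        raise ValueError("enumerate_neo_terminus requires a NEO_TERMINUS context")
    L = len(context.sequence)
    if k_min > k_max:
        raise ValueError(f"k_min {k_min} > k_max {k_max}")
    if k_min > L:
        raise ValueError(f"k_min {k_min} exceeds context length {L}")
    windows = [
        _cut(context, start, k)
        for k in range(k_min, k_max + 1)
        for start in range(1, L - k + 2)
    ]
    return PeptideSet(context.mutation_id, windows, (k_min, k_max))


def enumerate_point_mutation(
    context: MutationContext, k_min: int = 8, k_max: int = 11
) -> PeptideSet:
    """All k-mer windows covering the mutated position of a point-substitution context.

    With >= k_max - 1 residues of flank on each side the count is sum over k
    of k (38 for k 8..11); near the ends the set is clipped to valid windows.
    """
    if context.mode is not MutationMode.POINT_SUBSTITUTION:
        raise ValueError("enumerate_point_mutation requires a POINT_SUBSTITUTION context")
    if k_min > k_max:
        raise ValueError(f"k_min {k_min} > k_max {k_max}")
    L = len(context.sequence)
    pos = context.mutated_position
    windows = []
    for k in range(k_min, k_max + 1):
        lo = max(1, pos - k + 1)
        hi = min(pos, L - k + 1)
        for start in range(lo, hi + 1):
            windows.append(_cut(context, start, k))
    return PeptideSet(context.mutation_id, windows, (k_min, k_max))


def enumerate_class_ii(context: MutationContext, k: int = 15) -> PeptideSet:
    """15-mer windows for class II prediction input (single fixed length)."""
    if len(context.sequence) < k:
        raise ValueError(
            f"{context.mutation_id}: context length {len(context.sequence)} < k = {k}"
        )
    if context.mode is MutationMode.NEO_TERMINUS:
        return enumerate_neo_terminus(
            MutationContext(context.mutation_id, MutationMode.NEO_TERMINUS, context.sequence),
            k, k,
        )
    pset = enumerate_point_mutation(context, k, k)
    return pset


def write_peptides(pset: PeptideSet, path: str | Path, format: str = "fasta") -> None:
    """Write a peptide set as FASTA (one record per window) or a deduplicated list."""
    path = Path(path)
    if format == "fasta":
        with path.open("w") as fh:
            for w in pset:
                fh.write(f">{pset.mutation_id}_{w.start}_{w.length}\n{w.peptide}\n")
    elif format == "list":
        with path.open("w") as fh:
            for pep in pset.peptide_strings():
                fh.write(pep + "\n")
    else:
        raise ValueError(f"unknown peptide output format {format!r}")
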