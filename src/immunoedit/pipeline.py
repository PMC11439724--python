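"""End-to-end study orchestration: enumerate -> score -> associate -> report.

``run_study`` executes the full analysis sequence on one or more cohort
genotype tables and writes one TSV per analysis plus a run manifest
(parameters, seed, input checksums).  Reruns with the same config and
inputs are byte-identical: all floats are formatted explicitly, row order
is deterministic, and the manifest carries no timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import associate_alleles, associate_categories
from .haplotypes import haplotype_association_scan
from .hed import cohort_hed_comparison, cohort_hed_table
from .hla import CLASS_I_LOCI, Cohort, Group, read_genotype_table, read_imgt_protein_fasta
from .meta import phbr_correlation, pool_cohorts, pooled_association
from .peptides import (
    calr_context,
    enumerate_neo_terminus,
    enumerate_point_mutation,
    jak2_context,
)
from .presentation import (
    allele_best_ranks,
    cohort_phbr_table,
    mock_rank_predictor,
    read_rank_table,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    genotypes: list[str]
    out_dir: str
    sequences: str | None = None
    ranks: dict[str, str] = field(default_factory=dict)  # mutation_id -> path
    rank_dialect: str = "simple_tsv"
    use_mock_predictor: bool = False
    seed: int = 0
    comparisons: list[tuple[str, str]] = field(
        default_factory=lambda: [("CALR", "CONTROL"), ("CALR", "JAK2")])
    min_freq: float = 0.02
    hwe_alpha: float = 0.1
    hwe_group: str | None = "CONTROL"
    haplo_arities: list[int] = field(default_factory=lambda: [2])
    haplo_prune_freq: float = 0.01
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["comparisons"] = [tuple(c) for c in raw.get("comparisons", [])] or None
        if raw["comparisons"] is None:
            raw.pop("comparisons")
        return cls(**raw)

    def validate(self) -> None:
        if not self.genotypes:
            raise ConfigError("no genotype tables configured")
        for p in self.genotypes:
            if not Path(p).exists():
                raise ConfigError(f"genotype table not found: {p}")
        if self.sequences and not Path(self.sequences).exists():
            raise ConfigError(f"sequence FASTA not found: {self.sequences}")
        if not self.ranks and not self.use_mock_predictor:
            raise ConfigError("no rank tables configured and mock predictor disabled")
        for mut, p in self.ranks.items():
            if not Path(p).exists():
                raise ConfigError(f"rank table for {mut} not found: {p}")
        for case, control in self.comparisons:
            Group(case), Group(control)
        if self.hwe_group is not None:
            Group(self.hwe_group)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def run_study(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest (also written to disk).

    Stages: peptide enumeration -> rank ingestion (or mock prediction) ->
    per-allele BR / binder categories -> per-subject PHBR -> HED ->
    allele and category association per comparison -> class I haplotype scan
    -> PHBR cross-mutation correlation.  Any stage failure aborts with the
    stage name.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    timings: dict[str, float] = {}
    try:
        t0 = time.perf_counter()
        cohorts = [read_genotype_table(p) for p in config.genotypes]
        for c, p in zip(cohorts, config.genotypes):
            logger.info("loaded cohort %s (%d subjects) from %s", c.name, len(c), p)
        study = pool_cohorts(cohorts) if len(cohorts) > 1 else cohorts[0]
        timings[stage] = time.perf_counter() - t0

        stage = "enumerate"
        t0 = time.perf_counter()
        psets = {
            "CALRmut": enumerate_neo_terminus(calr_context()),
            "JAK2V617F": enumerate_point_mutation(jak2_context()),
        }
        timings[stage] = time.perf_counter() - t0

        stage = "ranks"
        t0 = time.perf_counter()
        class_i_alleles = sorted({
            a for s in study for l, gt in s.genotypes.items()
            if l in CLASS_I_LOCI for a in gt.alleles})
        tables = {}
        for mut in psets:
            if mut in config.ranks:
                tables[mut] = read_rank_table(config.ranks[mut], config.rank_dialect)
            else:
                tables[mut] = mock_rank_predictor(
                    class_i_alleles, psets[mut].peptide_strings(), seed=config.seed)
        timings[stage] = time.perf_counter() - t0

        stage = "presentation"
        t0 = time.perf_counter()
        annotations = {}
        br_rows = []
        for mut in sorted(psets):
            brs = allele_best_ranks(tables[mut], psets[mut], class_i_alleles)
            annotations[mut] = {a: br.category for a, br in brs.items()}
            for a in class_i_alleles:
                br_rows.append({"mutation_id": mut, "allele": str(a),
                                "br": brs[a].br, "category": brs[a].category.value})
        _write(pd.DataFrame(br_rows), out_dir / "allele_best_ranks.tsv")
        phbr_table, skipped = cohort_phbr_table(study, tables, psets)
        _write(phbr_table, out_dir / "phbr.tsv")
        if skipped:
            _write(pd.DataFrame(skipped), out_dir / "phbr_skipped.tsv")
        timings[stage] = time.perf_counter() - t0

        stage = "hed"
        t0 = time.perf_counter()
        hed_outputs = []
        if config.sequences:
            db = read_imgt_protein_fasta(config.sequences)
            hed_table = cohort_hed_table(study, db)
            _write(hed_table, out_dir / "hed.tsv")
            comp_frames = []
            for col in ("hed_class_I", "hed_class_II"):
                if hed_table[col].notna().sum() >= 4:
                    try:
                        comp_frames.append(cohort_hed_comparison(hed_table, col))
                    except ValueError:
                        pass
            if comp_frames:
                _write(pd.concat(comp_frames, ignore_index=True),
                       out_dir / "hed_comparison.tsv")
                hed_outputs.append("hed_comparison.tsv")
            hed_outputs.append("hed.tsv")
        else:
            logger.info("no sequence FASTA configured; HED stage skipped")
        timings[stage] = time.perf_counter() - t0

        stage = "association"
        t0 = time.perf_counter()
        assoc_files = []
        for case, control in config.comparisons:
            comparison = (Group(case), Group(control))
            hwe_group = Group(config.hwe_group) if config.hwe_group else None
            if hwe_group not in comparison:
                hwe_group = None
            if len(cohorts) > 1:
                table = pooled_association(
                    study, comparison, min_freq=config.min_freq,
                    hwe_alpha=config.hwe_alpha, hwe_group=hwe_group)
            else:
                table = associate_alleles(
                    study, comparison, min_freq=config.min_freq,
                    hwe_alpha=config.hwe_alpha, hwe_group=hwe_group)
            fname = f"assoc_alleles_{case}_vs_{control}.tsv"
            _write(table, out_dir / fname)
            assoc_files.append(fname)
            cat = associate_categories(study, annotations, comparison)
            fname = f"assoc_categories_{case}_vs_{control}.tsv"
            _write(cat, out_dir / fname)
            assoc_files.append(fname)
        timings[stage] = time.perf_counter() - t0

        stage = "haplotypes"
        t0 = time.perf_counter()
        case, control = config.comparisons[0]
        haplo = haplotype_association_scan(
            study, hla_class=1, arities=config.haplo_arities,
            comparison=(Group(case), Group(control)),
            prune_freq=config.haplo_prune_freq)
        _write(haplo, out_dir / "haplo_classI.tsv")
        timings[stage] = time.perf_counter() - t0

        stage = "correlation"
        t0 = time.perf_counter()
        corr = phbr_correlation(phbr_table, "CALRmut", "JAK2V617F",
                                group_by=("cohort", "group"))
        _write(corr, out_dir / "phbr_correlation.tsv")
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    for name, dt in timings.items():
        logger.info("stage %-12s %.2fs", name, dt)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items()
            if k not in ("genotypes", "sequences", "ranks", "out_dir")
        },
        "inputs": {
            "genotypes": {p: _sha256(p) for p in config.genotypes},
            "sequences": ({config.sequences: _sha256(config.sequences)}
                          if config.sequences else None),
            "ranks": {mut: {p: _sha256(p)} for mut, p in config.ranks.items()},
        },
        "outputs": sorted(p.name for p in out_dir.glob("*.tsv")),
    }
    with (out_dir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def render_tables(report_dir: str | Path) -> list[Path]:
    """Volcano/forest-ready views of the association TSVs in a report dir.

    Adds ``neglog10_p`` and a label column, drops excluded terms.  Returns
    the written paths.
    """
    report_dir = Path(report_dir)
    written = []
    for path in sorted(report_dir.glob("assoc_*.tsv")):
        if path.name.startswith("volcano_"):
            continue
        df = pd.read_csv(path, sep="\t")
        df = df[df["p"].notna()].copy()
        df["neglog10_p"] = -np.log10(df["p"])
        df["label"] = df["term"]
        out = report_dir / f"volcano_{path.name}"
        _write(df, out)
        written.append(out)
    return written
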