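"""Run the complete study pipeline on a generated miniature multi-cohort study.

Generates three cohorts with a planted protective allele (C*06:02, OR 0.4 for
the CALR group) and a planted -0.6 cross-mutation BR correlation, then runs
enumeration -> presentation scoring -> HED -> associations -> haplotype scan
-> PHBR correlations, writing one TSV per analysis plus a reproducibility
manifest.
"""

import tempfile
from pathlib import Path

import pandas as pd

from immunoedit import RunConfig, generate_fixture_suite, run_study

workdir = Path(tempfile.mkdtemp(prefix="immunoedit_demo_"))
suite = workdir / "inputs"
manifest = generate_fixture_suite(suite, seed=5)
print(f"generated {len(manifest['cohorts'])} cohorts, planted protective allele "
      f"{manifest['planted_protective_allele']} (OR {manifest['planted_odds_ratio']})")

config = RunConfig(
    genotypes=[str(suite / f) for f in manifest["files"]["genotypes"]],
    sequences=str(suite / manifest["files"]["sequences"]),
    ranks={f.removeprefix("ranks_").removesuffix(".tsv"): str(suite / f)
           for f in manifest["files"]["ranks"]},
    out_dir=str(workdir / "report"),
    seed=5,
)
report = run_study(config)
print("\nanalysis tables written:")
for name in report["outputs"]:
    print(f"  {name}")

assoc = pd.read_csv(workdir / "report" / "assoc_alleles_CALR_vs_CONTROL.tsv", sep="\t")
hit = assoc[assoc["term"] == "C*06:02"]
print("\nplanted allele in the pooled association output:")
print(hit[["term", "freq_case", "freq_control", "or", "p", "filter_status"]]
      .round(4).to_string(index=False))
# At this miniature scale the direction (case frequency below control
# frequency) is recovered; significance requires the larger cohorts used in
# the test suite's power simulations.
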