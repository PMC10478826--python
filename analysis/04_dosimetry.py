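#!/usr/bin/env python
"""Absorbed red-marrow doses per skeletal site for the synthetic cohort.

Runs the full pipeline (blood fit -> compartment fits -> S-value dosimetry)
on results/cohort/patients.tsv, writes the run directory results/run/, and
reports the central comparison: image-based total dose versus the
skeletal-average blood-based estimate.
"""
import argparse
import warnings
from pathlib import Path

from rmdose import PipelineConfig, run_pipeline

root = Path(__file__).resolve().parents[1]
parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--input", type=Path,
                    default=root / "results" / "cohort" / "patients.tsv")
parser.add_argument("--out", type=Path, default=root / "results" / "run")
parser.add_argument("--seed", type=int, default=None,
                    help="recorded in the run log for provenance")
args = parser.parse_args()

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = run_pipeline(args.input, PipelineConfig(seed=args.seed),
                          out_dir=args.out)
doses = result.doses
n_higher = int((doses["dose_total"] > doses["dose_blood_based"]).sum())
ratio = (doses["dose_total"] / doses["dose_blood_based"]).median()
print(f"run directory: {result.out_dir}")
print(f"{n_higher}/{len(doses)} site doses exceed the blood-based estimate "
      f"(median ratio {ratio:.1f}x)")
print(result.summary.to_string(index=False))
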