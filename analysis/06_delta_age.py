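"""Delta age by exposure arm: does smoke accelerate transcriptomic aging?

Applies the sham-trained clock to every sample and summarizes the
residual (predicted minus chronological age) per exposure group, with
Welch t-tests of each arm against sham and a one-way ANOVA across arms.

Reads results/data (after 04); writes predictions.tsv,
delta_age_groups.tsv and group_inference.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from lungclock.pipeline import PipelineConfig, run_pipeline

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1

cfg = PipelineConfig(out_dir="results/data", seed=SEED)
run_pipeline(cfg, ("predict", "delta"))

out = Path(cfg.out_dir)
groups = pd.read_csv(out / "delta_age_groups.tsv", sep="\t", comment="#")
tests = pd.read_csv(out / "group_inference.tsv", sep="\t", comment="#")
print(groups.to_string(index=False))
print()
print(tests.to_string(index=False))
anova = (out / "group_inference.tsv").read_text().splitlines()[0]
print(anova.lstrip("# "))
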