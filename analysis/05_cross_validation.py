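"""Validate the clock under both cross-validation designs.

Random 75/25 holdout (stratified by study, repeated) and
leave-one-study-out: the pooled validation mean absolute errors, in
months, summarize how well expression predicts chronological age in
held-out control animals.

Reads results/data; writes cv_holdout.tsv and cv_loso.tsv.
"""

import sys
from pathlib import Path

from lungclock.pipeline import PipelineConfig, run_pipeline

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1

cfg = PipelineConfig(out_dir="results/data", seed=SEED, holdout_runs=20)
run_pipeline(cfg, ("validate",))

out = Path(cfg.out_dir)
for name in ("cv_holdout.tsv", "cv_loso.tsv"):
    header = (out / name).read_text().splitlines()[0]
    print(f"{name}: {header.split('pooled_validation_mae=')[1]}")
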