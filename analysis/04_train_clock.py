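"""Fit the transcriptomic age clock on the 111 sham samples.

LASSO (coordinate descent, lambda at minimum 5-fold CV MSE) selects the
predictor genes; an OLS refit on raw log2 expression yields the final
sparse linear model, saved as model.json with the selected-gene table.

Reads results/data; writes model.json and selected_genes.tsv.
"""

import json
import sys
from pathlib import Path

from lungclock.pipeline import PipelineConfig, run_pipeline

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1

cfg = PipelineConfig(out_dir="results/data", seed=SEED)
run_pipeline(cfg, ("train",))

model = json.loads((Path(cfg.out_dir) / "model.json").read_text())
print(f"clock: {len(model['coefficients'])} predictor genes, "
      f"lambda = {model['lambda_selected']:.4g}, "
      f"intercept = {model['intercept']:.2f} months")
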