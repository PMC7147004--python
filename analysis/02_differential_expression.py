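"""Identify age- and smoke-regulated genes.

Age contrasts compare sham groups between time points within each study
(oldest minus youngest, 28 pairs); exposure contrasts compare smoke to
sham at matched time points (14 pairs). A gene is regulated when it
passes |log2 FC| > log2(1.5) and BH-FDR < 0.05 in at least one contrast.

Reads results/data; writes contrast tables and regulated-gene sets under
results/data and a summary to stdout.
"""

import json
import sys
from pathlib import Path

from lungclock.pipeline import PipelineConfig, run_pipeline

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1

cfg = PipelineConfig(out_dir="results/data", seed=SEED)
run_pipeline(cfg, ("deg",))

out = Path(cfg.out_dir)
for kind in ("age", "exposure"):
    doc = json.loads((out / f"regulated_{kind}.json").read_text())
    print(f"{kind}-regulated genes: {len(doc['gene_ids'])}")
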