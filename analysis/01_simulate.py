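"""Generate the multi-study dataset all downstream analyses consume.

Three chronic-inhalation studies of female mice, all 2 months old at
exposure start: fresh-air (sham) and cigarette-smoke arms at matched time
points in every study, plus HTP-aerosol, cessation and switch arms
(animals leave smoke after 2 months). 111 sham samples in total; planted
aging slopes, exposure step effects, per-study batch shifts and a
2-month acceleration of effective age in smoke-exposed animals.

Writes results/data/{expression.tsv, metadata.csv, truth.json}.
"""

import sys

from lungclock.pipeline import PipelineConfig, run_pipeline

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1

cfg = PipelineConfig(out_dir="results/data", seed=SEED)
run_pipeline(cfg, ("simulate",))
print(f"wrote results/data (seed {SEED}): 2000 genes, 3 studies, "
      "111 sham + exposed arms")
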