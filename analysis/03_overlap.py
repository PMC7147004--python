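"""Quantify the overlap between aging and smoke-response transcription.

Computes the Venn partition of the two regulated-gene sets, each gene's
signed maximum fold change across contrasts, and the correlation between
the first-principal-component loadings of the age and exposure
fold-change profiles.

Reads results/data (after 02); writes venn.tsv, mfc.tsv, pc1_loadings.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from lungclock.pipeline import PipelineConfig, run_pipeline

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1

cfg = PipelineConfig(out_dir="results/data", seed=SEED)
run_pipeline(cfg, ("overlap",))

out = Path(cfg.out_dir)
venn = pd.read_csv(out / "venn.tsv", sep="\t", comment="#")
print(venn.to_string(index=False))
header = (out / "pc1_loadings.tsv").read_text().splitlines()[0]
print(header.lstrip("# "))
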