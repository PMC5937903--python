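#!/usr/bin/env python
"""Summarize the screen: per-analyte hit counts at the nested FDR strata
and the top of each association table, in the published column layout."""

from pathlib import Path

import pandas as pd

from carotenome.cli import run_report
from carotenome.config import RunConfig

cfg = RunConfig()
print(run_report(cfg))
print()
for analyte in cfg.analytes:
    path = Path(cfg.screen_dir) / f"hits_{analyte}.tsv"
    if not path.exists():
        continue
    hits = pd.read_csv(path, sep="\t", dtype=str)
    if len(hits):
        print(f"top associations for {analyte}:")
        print(hits.head(5).to_string(index=False))
        print()
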