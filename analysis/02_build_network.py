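#!/usr/bin/env python
"""Build the BDNF co-expression gene network.

First reproduces the published worked example: filtering the packaged
prefrontal-cortex co-expression table at |r| >= 0.5 retains all 46 genes
with their printed signs.  Then runs the full network stage (co-expression
filter -> homolog map -> early-life 1.5-fold enrichment -> +/-500 bp
intervals) on the synthetic reference tables from step 01.
"""
import json
from pathlib import Path

from bdnfnet.network import load_packaged_coexpression, select_coexpressed
from bdnfnet.pipeline import run_pipeline

OUT = Path("results/pipeline")
Path("results").mkdir(exist_ok=True)

packaged = load_packaged_coexpression()
sel = select_coexpressed(packaged, rmin=0.5)
n_pos = int((sel["coexpr_sign"] > 0).sum())
print(f"packaged snapshot: {len(sel)} genes pass |r| >= 0.5 "
      f"({n_pos} positively, {len(sel) - n_pos} negatively co-expressed)")
sel.to_csv("results/packaged_network_genes.tsv", sep="\t", index=False)

run_pipeline({"seed": 1, "stages": ["build-network"]}, out_dir=OUT)
report = json.loads((OUT / "network_report.json").read_text())
print(f"synthetic tables: {report['n_input_genes']} genes -> "
      f"{report['n_coexpressed']} co-expressed -> "
      f"{report['n_network_genes']} after enrichment + annotation")
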