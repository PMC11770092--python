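"""Generate every synthetic input with recorded ground truth.

Emits a lncRNA-like transcriptome with planted small ORFs, a random
reference proteome, a three-cohort tumor/non-tumor abundance matrix with
planted core/unique/differential proteins, interactome replicate lists
with a planted core, and junction-count tables from known PSI values —
all under results/analysis/inputs/ with the truth in truth.json.
"""

from _common import run_stage

counts = run_stage("generate")
print("synthetic inputs written to results/analysis/inputs/")
for k, v in counts.items():
    print(f"  {k}: {v}")
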