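"""Replicate-consistency and Venn analysis of the interactome lists.

Reproduces the study design's set logic on the synthetic lists: proteins
in all four Co-IP replicates (planted core 139), probe-specific pulldown
proteins (65), their cross-experiment overlap (23), and proteins binding
the long but not the short isoform (27).
"""

from _common import run_stage

counts = run_stage("sets")
for k, v in counts.items():
    if k != "elapsed_s":
        print(f"  {k}: {v}")
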