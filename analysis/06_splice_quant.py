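"""PSI quantification and delta-PSI testing of the splice events.

Each event's inclusion/exclusion junction counts are pooled per
condition into a PSI estimate (SE inclusion counts halved for the
two-junction convention), conditions compared by Fisher's exact test,
and the event-type distribution among significant events summarized —
the exon-skipping-dominance readout of the study design.
"""

import json

from _common import WORKDIR, run_stage
from lepscan.splicing import isoform_ratio

counts = run_stage("splice")
print(f"events: {counts['n_events']}; significant: {counts['n_significant']}")
print(f"type distribution among significant: {counts['type_proportions']}")

# long/short isoform ratio implied by the first significant event's PSI shift
for line in (WORKDIR / "psi.tsv").read_text().splitlines()[1:]:
    eid, psis, delta, p, sig, skip = line.split("\t")
    if sig == "true":
        by_cond = dict(kv.split("=") for kv in psis.split(";"))
        ratios = {
            c: isoform_ratio(float(v), 1 - float(v)).ratio for c, v in by_cond.items()
        }
        print(f"{eid}: PSI {by_cond} -> long/short ratios "
              f"{ {c: round(r, 2) for c, r in ratios.items()} }")
        break
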