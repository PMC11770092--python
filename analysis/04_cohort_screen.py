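"""Presence, pan-cancer set and differential screens on the cohorts.

Applies the >30% presence rule per cohort, decomposes the identified
sets into a pan-cancer core and cohort-unique petals, and runs the
tumor/non-tumor differential screen (>50% presence in both groups,
normality-gated t or Mann-Whitney, significant at p < 0.05 and
|FC| >= 1.5) within each cohort.
"""

import json

from _common import WORKDIR, run_stage

counts = run_stage("screen")
pan = json.loads((WORKDIR / "pan_cancer.json").read_text())
print(f"cohorts: {counts['n_cohorts']}; proteins: {counts['n_proteins']}")
print(f"pan-cancer core ({pan['core_count']}): {', '.join(pan['core'])}")
for c, n in pan["unique_counts"].items():
    print(f"  unique to {c}: {n}")
print(f"differential screen: {counts['n_de_tested']} tested, "
      f"{counts['n_de_significant']} significant")
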