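"""Digest candidates and classify tryptic-peptide uniqueness.

Every candidate microprotein is digested in silico (trypsin, up to 2
missed cleavages, 7-50 residues, I/L collapsed) and each peptide is
looked up against the reference proteome. A candidate with at least one
peptide matching nothing in the reference is "peptide-supported" — the
MS-level evidence standard for claiming a novel protein.
"""

from _common import WORKDIR, run_stage

counts = run_stage("digest")
print(f"reference proteins: {counts['n_reference']}; candidates: {counts['n_leps']}")
print(f"peptide calls: {counts['n_peptide_calls']}; "
      f"peptide-supported candidates: {counts['n_peptide_supported']}")
print(f"tables: {WORKDIR / 'uniqueness.tsv'}, {WORKDIR / 'lep_summary.tsv'}")
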