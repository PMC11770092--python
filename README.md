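# lepscan

Discovery and pan-cancer screening of lncRNA-encoded microproteins (LEPs).

Transcripts annotated as long noncoding RNA can harbour small open reading
frames (sORFs) whose translation yields microproteins with real biology —
the exemplar here being a 92-aa product of a tropomyosin pseudogene
transcript that modulates exon skipping in a transcription factor pre-mRNA.
Establishing that such a protein exists and matters takes a chain of desk
analyses over proteomic and transcriptomic data, and `lepscan` implements
that chain as a tested, reusable pipeline:

1. **sORF discovery** (`lepscan.orf`) — scan transcripts for ATG-initiated
   ORFs in three frames, pick one canonical (longest) ORF per transcript,
   and emit a candidate protein database (FASTA).
2. **Peptide uniqueness** (`lepscan.digest`) — digest candidates and the
   reference proteome in silico with the trypsin rule (cleave after K/R,
   not before P; ≤2 missed cleavages; 7–50 residues; I/L collapsed) and
   classify each candidate peptide as `reference`, `shared_lep` or
   `unique_lep`. A candidate with ≥1 unique peptide is peptide-supported.
3. **Cohort screening** (`lepscan.screen`) — on protein × sample intensity
   matrices with missing values: a protein is *identified* in a cohort
   when quantified in >30% of its tumor or of its non-tumor samples;
   identified sets decompose into a pan-cancer *core* (all cohorts) and
   cohort-*unique* petals; proteins quantified in >50% of both groups are
   tested for differential abundance (fold change on linear-scale group
   means; Student's *t* on log2 values when both groups pass Shapiro–Wilk,
   Mann–Whitney U otherwise; significant at p < 0.05 and |FC| ≥ 1.5).
4. **Interactome sets** (`lepscan.sets`) — replicate-consistency and Venn
   algebra over IP-MS / RNA-pulldown identification lists.
5. **Splicing quantification** (`lepscan.splicing`) — percent spliced in
   from junction counts, PSI = I_eff/(I_eff + E) with I_eff = I/2 for
   skipped exons (two inclusion junctions per skipping junction); condition
   differences by two-sided Fisher exact test on the pooled 2×2 table;
   long/short isoform ratios with the identity ratio = PSI/(1 − PSI).
6. **Synthetic data** (`lepscan.simulate`) — generators for every input
   with planted, recorded ground truth: scrubbed transcript backgrounds
   with exact ORF catalogues, log-normal intensities with MNAR + MCAR
   missingness and planted effects, replicate lists with a planted core,
   and Binomial junction counts from true PSI values.

The repository is organised as an analysis project: numbered drivers under
`analysis/` narrate a full run over synthetic data, every computation lives
in the library under `src/lepscan/`, and outputs land under `results/`.

## Worked example

Run the drivers in order (or equivalently `lepscan -o results/analysis run-all`):

```sh
python analysis/01_simulate_inputs.py
python analysis/04_cohort_screen.py
python analysis/05_interactome_sets.py
```

which prints, for the default seed:

```
cohorts: 3; proteins: 150
pan-cancer core (3): LEP00001, LEP00002, LEP00003
  unique to kidney: 6
  unique to liver: 6
  unique to lung: 9
differential screen: 197 tested, 16 significant
  coip_consistent_count: 139
  probe_specific_count: 65
  probe_coip_overlap_count: 23
  isoform_specific_count: 27
```

The three core proteins are exactly the planted universally-expressed
LEPs; 197 of 450 protein × cohort combinations pass the >50% rule in both
groups and 16 carry planted fold changes large enough to clear p < 0.05
and |FC| ≥ 1.5. The interactome counts recover the planted probe-specific
(65), replicate-consistent (139), overlapping (23) and isoform-specific
(27) sets, the Venn logic of an RNA-pulldown + Co-IP interactome study.

The same stages are available as subcommands of the `lepscan` console
script (`generate`, `sorfs`, `digest`, `screen`, `sets`, `splice`,
`run-all`) driven by a YAML config; reruns with the same config and seed
are byte-identical.

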