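# Methods

This note records the statistical procedures, parameter defaults and
design choices behind `lepscan`, and what the synthetic benchmarks do and
do not demonstrate.

## ORF model

An ORF is an ATG-initiated, in-frame-stop-terminated span on the given
transcript strand, under the standard genetic code; alternative start
codons are not considered (start-codon mutagenesis ATG→ATT abolishing
translation is the operational definition of initiation for this class
of microprotein). Transcripts are normalized U→T and uppercased on read;
N is tolerated but any codon containing N is untranslatable and
terminates extension of an open ORF without emitting it. Coordinates are
0-based half-open in memory and 1-based closed in the TSV report.

With `report_nested_starts` off (default) one ORF is reported per stop
codon per frame, from the 5'-most ATG. The canonical ORF of a transcript
is the longest product, ties broken by the 5'-most start — the field's
convention when a single product per transcript must be named; it
reproduces a planted 92-aa product exactly. `min_len_aa` defaults to
20 aa: microproteins of interest concentrate in the 50–200 aa range, and
20 aa is a deliberately permissive candidate-generation bound (exposed in
`OrfConfig`). `require_stop` defaults to on; stop-less run-off ORFs can
be reported for truncated transcripts, with `length_aa` then counting all
codons.

## Peptide uniqueness

Digestion follows the trypsin rule — cleave C-terminal to K or R except
when followed by P — with defaults matching common search-engine
settings: ≤2 missed cleavages, peptide length 7–50. Uniqueness is
evaluated at the tryptic-peptide level: a hash index maps every tryptic
peptide of the combined reference + candidate database to its parent
accessions, and a peptide is `reference` if any reference protein can
produce it, `unique_lep` if exactly one candidate and no reference
protein can, `shared_lep` otherwise. This mirrors how search engines
assign peptides to proteins. A stricter substring mode (match anywhere
in an undigested reference sequence) is available; it can only shrink
the unique set. I and L are collapsed before lookup by default because
mass spectrometry cannot distinguish them; this too can only shrink the
unique set (property-tested). Modified and semi-tryptic peptides are out
of scope — classification is sequence-only, downstream of any search
engine.

## Presence and differential screens

The presence rule is strict: a protein is identified in a cohort when
its non-missing fraction exceeds 0.30 among that cohort's tumor samples
or among its non-tumor samples. (A figure legend elsewhere says
"in 30%"; the methods wording ">30%" wins and the inequality is strict —
3/10 does not qualify, 4/10 does.) Pan-cancer decomposition: core =
identified in every cohort; unique[c] = identified in c and nowhere
else; the remainder is shared-but-not-core. The three planted universal
proteins in the synthetic nine-cohort design are recovered exactly.

The differential screen tests only proteins quantified in >50% of the
tumor AND >50% of the non-tumor samples (skipped proteins are reported
with a reason, never silently dropped). Fold change is the ratio of
linear-scale group means over observed values — no imputation, missing
cells excluded pairwise. The location test runs on log2 intensities:
each group is pre-tested with Shapiro–Wilk at α = 0.05 (the normality
test is unnamed in the source procedure; Shapiro–Wilk is the standard
choice); if both pass, an unpaired two-tailed Student's t with pooled
variance (Welch optional), otherwise a two-sided Mann–Whitney U.
Constant or <3-observation groups are degenerate for Shapiro–Wilk and
are routed to the rank test, which returns p = 1 for identical groups.
Significance is raw p < 0.05 and |FC| ≥ 1.5; no multiple-testing
correction by default (the screen is a candidate filter, not an
inferential endpoint), Benjamini–Hochberg available via `bh_correct`.
The screen is label-symmetric (swapping groups negates log2FC, p
unchanged) and its null false-positive rate at 2000 proteins, 20/20
samples, sits inside [0.03, 0.07].

## Interactome set algebra

Replicate consistency means presence in ≥ `r_min` of N replicates,
default all N — "identified across four biological replicates" is read
as present-in-all, with `r_min` exposed because union-like readings
exist. Probe-specific sets are plain differences against the control
pulldown; cross-experiment candidates are intersections. All operations
are order-invariant and satisfy |A∩B| + |A\B| = |A| (fuzz-tested).
Accessions are uppercased on read; optional flags strip isoform ("-2")
and version (".3") suffixes, off by default. Identifier mixing
(gene symbols vs accessions) must be resolved by the caller; no remote
ID-mapping service is used.

## PSI and splicing tests

For one event, counts are pooled per condition. For skipped exons two
junctions support inclusion versus one for skipping, so inclusion counts
are halved (`length_normalize`, on by default): PSI = (I/2)/(I/2 + E).
Conditions with fewer than `min_coverage` (default 10) total junction
reads skip the event with a reason. The condition test is a two-sided
Fisher exact test on the pooled 2×2 effective-count table (effective
counts rounded to nearest integer; Python's banker's rounding at exact
halves), using the minimum-likelihood two-sided convention — verified
against exact hypergeometric sums computed in integer arithmetic for all
small-margin tables. Pooling replaces a replicate-variance model; this
keeps the procedure deterministic and is adequate for the pooled-depth
regime simulated here, but it understates uncertainty when replicates
disagree. An event is significant at p < alpha (0.05) and
|ΔPSI| ≥ `min_delta` (0.10). Isoform ratios are long/short with a zero
short abundance an explicit error; in the noiseless mapping
long = p·T, short = (1−p)·T the ratio is exactly p/(1−p).

## Synthetic data: what it emulates and what it does not

The generators are first-class, tested code and define the study
conditions for every benchmark:

* **Transcriptome** — random ACGT backgrounds are scrubbed of every ATG
  trinucleotide (G→C rewrite), planted inserts are built codon-by-codon
  to exclude internal ATGs and in-frame stops, and stop-codon/background
  junctions that would recreate an ATG are repaired. The transcript's
  complete ORF catalogue therefore *equals* the planted list by
  construction; recovery tests are exact, not statistical. Planted
  product lengths default to Uniform[50, 200] aa.
* **Abundance** — log2 intensities ~ Normal(μ_p, σ) with σ = 0.5 and
  protein baselines μ_p ~ Normal(25, 2); planted tumor effects of
  ±`effect_log2fc`. Missingness is MNAR — P(missing|x) =
  logistic(slope·(midpoint − x)) with the midpoint at the 20th intensity
  percentile and slope 1 per log2 unit — plus 2% MCAR. These missingness
  defaults are invented but stated; the source procedure says nothing
  about its missingness mechanism. Planted core/cohort-unique proteins
  get a high tight baseline (+2 log2 units) so their identification is a
  matter of construction; remaining proteins are expressed in random
  proper subsets of cohorts, so cohort-unique *calls* may exceed the
  planted unique truth (low-abundance shared proteins can pass the 30%
  rule in only one cohort) — tests assert planted ⊆ called.
* **Interactome** — core accessions appear in every replicate, noise in
  exactly one; the pulldown-study generator plants set sizes of 65
  (probe-specific), 139 (replicate core), 23 (overlap) and 27
  (isoform-specific), the canonical Venn counts of this study design.
* **Junction counts** — inclusion ~ Binomial(depth, 2ψ/(1+ψ)) per sample
  for SE (ψ directly otherwise), exclusion = depth − inclusion, so the
  PSI estimator is consistent by construction.

All randomness flows from one integer seed per generator call through
numpy's `default_rng`; same-seed runs are byte-identical, and the seed is
recorded in every emitted file header and in the truth JSON.

What passing these benchmarks does **not** show: performance on real
spectra (no search-engine FDR, no modifications, no chimeric spectra),
real CPTAC matrices (no batch structure, no TMT ratio compression, no
correlated missingness across proteins), or real splicing calls (no read
alignment, no event discovery, no overdispersion between biological
replicates). Intensities are assumed pre-normalized, as processed
consortium matrices are.

## Problem sizes

The default test and acceptance runs use 12–50 transcripts of 1.2 kb,
reference proteomes of 120–300 proteins, 150–2000-protein abundance
matrices with 12/12 to 20/20 samples per cohort, 200 brute-force ORF
comparisons up to 2 kb, and 200 PSI-shift simulations at depth 500 —
sizes chosen so each property is measured with comfortable statistical
resolution while a full run stays in the seconds-to-minutes range on one
CPU.

## Known limitations

Genomic (multi-exon) coordinates are not modeled — everything is
transcript-space. Kozak context and ribosome-profiling evidence are out
of scope for ORF calling. The paired differential test requires complete
pairs and is lightly exercised. The Fisher-on-pooled-counts ΔPSI test is
anticonservative under between-replicate overdispersion. Survival
analysis, enrichment, network construction and all wet-lab validation
steps of a microprotein study are deliberately outside this package.
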