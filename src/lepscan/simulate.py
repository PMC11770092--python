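"""Synthetic inputs with known ground truth for every pipeline stage.

Real inputs to a microprotein discovery study are large downloads (SRA
translatomes, CPTAC matrices, ProteomeXchange identification lists). The
generators here emit the same file dialects with planted, recorded truth
so that every stage — ORF scan, uniqueness classification, presence and
differential screens, replicate set algebra and PSI quantification — can
be exercised and its recovery measured without any download.

Construction guarantees, not hope, make the truth exact where possible:

* transcript backgrounds are scrubbed of every ATG trinucleotide (G->C
  rewrite), so outside planted ORFs no start codon exists at all;
* planted ORF inserts are built codon-by-codon avoiding in-frame stops
  and any internal ATG substring, so the transcript's complete ORF
  catalogue equals the planted list;
* abundance matrices draw log2 intensities from Normal(mu_p, sigma) with
  planted tumor effects, then censor them with an intensity-dependent
  (MNAR logistic) plus uniform (MCAR) missingness model;
* replicate lists place core accessions in every replicate and noise
  accessions in exactly one;
* junction counts are Binomial draws from the true PSI, honouring the
  two-junction convention for skipped exons.

All randomness flows from one integer seed per call via numpy's
``default_rng``; identical seeds give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .digest import ProteinRecord
from .orf import STOP_CODONS, Transcript, _translate
from .screen import AbundanceMatrix
from .sets import ProteinSet, ReplicateLists
from .splicing import SpliceEvent

__all__ = [
    "TruthBundle",
    "MissingModel",
    "gen_transcriptome",
    "gen_reference_proteome",
    "gen_abundance_cohort",
    "gen_interactome_replicates",
    "gen_pulldown_study",
    "gen_junction_counts",
    "write_transcripts_fasta",
    "write_proteome_fasta",
    "write_abundance_tsv",
    "write_replicate_tsvs",
    "write_event_tsv",
]

_NT = np.array(list("ACGT"))
_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SAFE_CODONS = [c for c in _CODONS if c not in STOP_CODONS]


@dataclass
class TruthBundle:
    """Ground truth planted by the generators, for recovery tests."""

    seed: int
    planted_orfs: list[tuple[str, int, int, str]] = field(default_factory=list)
    planted_de: dict[str, float] = field(default_factory=dict)
    planted_core_leps: set[str] = field(default_factory=set)
    planted_unique_leps: dict[str, set[str]] = field(default_factory=dict)
    replicate_core: set[str] = field(default_factory=set)
    true_psi: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, out: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["planted_core_leps"] = sorted(self.planted_core_leps)
        payload["replicate_core"] = sorted(self.replicate_core)
        payload["planted_unique_leps"] = {
            k: sorted(v) for k, v in sorted(self.planted_unique_leps.items())
        }
        Path(out).write_text(json.dumps(payload, indent=2) + "\n")


# ------------------------------------------------------------ transcriptome

def _scrub_atg(seq: np.ndarray) -> np.ndarray:
    """Remove every ATG trinucleotide by rewriting its G to C."""
    s = "".join(seq)
    while (i := s.find("ATG")) != -1:
        s = s[: i + 2] + "C" + s[i + 3 :]
    return np.array(list(s))


def _orf_insert(rng: np.random.Generator, length_aa: int) -> str:
    """ATG + (length_aa - 1) sense codons + stop, with no internal ATG
    substring (any frame) and no in-frame stop before the final one."""
    out = "ATG"
    for _ in range(length_aa - 1):
        while True:
            codon = _SAFE_CODONS[rng.integers(len(_SAFE_CODONS))]
            if "ATG" not in (out[-2:] + codon):
                out += codon
                break
    while True:
        stop = sorted(STOP_CODONS)[rng.integers(3)]
        if "ATG" not in (out[-2:] + stop):
            out += stop
            break
    assert "ATG" not in out[1:], "internal ATG slipped through"
    return out


def gen_transcriptome(
    seed: int,
    n_transcripts: int = 20,
    orfs_per_transcript: int = 1,
    length_range_aa: tuple[int, int] = (50, 200),
    orf_lengths_aa: Sequence[int] | None = None,
    transcript_length: int = 1200,
) -> tuple[list[Transcript], TruthBundle]:
    """Random lncRNA-like transcripts with planted small ORFs.

    Planted product lengths default to Uniform[50, 200] aa, the range in
    which lncRNA-encoded microproteins concentrate; pass explicit
    ``orf_lengths_aa`` (cycled across transcripts) to pin them.
    """
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    rng = np.random.default_rng(seed)
    truth = TruthBundle(seed=seed)
    transcripts: list[Transcript] = []
    for t in range(n_transcripts):
        tid = f"SYNT{t + 1:04d}.1"
        bg = _scrub_atg(_NT[rng.integers(4, size=transcript_length)])
        seq = "".join(bg)
        planted: list[tuple[int, int, str]] = []
        cursor = 0
        for k in range(orfs_per_transcript):
            if orf_lengths_aa is not None:
                length_aa = int(orf_lengths_aa[(t * orfs_per_transcript + k) % len(orf_lengths_aa)])
            else:
                length_aa = int(rng.integers(length_range_aa[0], length_range_aa[1] + 1))
            nt_len = 3 * (length_aa + 1)
            room = len(seq) - cursor - nt_len
            if room < 0:
                raise ValueError(
                    f"ORF of {length_aa} aa does not fit in transcript of "
                    f"{transcript_length} nt (cursor {cursor})"
                )
            start = cursor + int(rng.integers(room + 1))
            insert = _orf_insert(rng, length_aa)
            seq = seq[:start] + insert + seq[start + nt_len :]
            planted.append((start, start + nt_len, insert))
            cursor = start + nt_len
        # a stop codon ending in A followed by background "TG" forms a
        # junction ATG; the offending G is always background, rewrite it
        planted_starts = {s for s, _e, _i in planted}
        pos = seq.find("ATG")
        while pos != -1:
            if pos not in planted_starts:
                assert not any(s < pos + 2 < e for s, e, _i in planted)
                seq = seq[: pos + 2] + "C" + seq[pos + 3 :]
            pos = seq.find("ATG", pos + 1)
        tx = Transcript(tid, seq)
        transcripts.append(tx)
        for start, end, insert in planted:
            truth.planted_orfs.append((tid, start, end, _translate(insert[:-3])))
    return transcripts, truth


def gen_reference_proteome(
    seed: int,
    n_proteins: int = 300,
    length_range: tuple[int, int] = (100, 600),
    prefix: str = "REF",
) -> list[ProteinRecord]:
    """Random reference proteins with UniProt-style synthetic accessions."""
    rng = np.random.default_rng(seed)
    aas = np.array(list(_AA20))
    out = []
    for i in range(n_proteins):
        n = int(rng.integers(length_range[0], length_range[1] + 1))
        out.append(ProteinRecord(f"{prefix}{i + 1:05d}", "".join(aas[rng.integers(20, size=n)]), "reference"))
    return out


# ------------------------------------------------------------- abundance

@dataclass(frozen=True)
class MissingModel:
    """Intensity-dependent (MNAR) plus uniform (MCAR) censoring.

    P(missing | x) = logistic(slope * (midpoint - x)) with the midpoint at
    the ``mnar_quantile`` of all expressed log2 intensities, then an
    additional ``mcar_rate`` of cells dropped uniformly.
    """

    mnar_quantile: float = 0.20
    mnar_slope: float = 1.0  # per log2 unit
    mcar_rate: float = 0.02

    def missing_prob(self, x: np.ndarray, midpoint: float) -> np.ndarray:
        if self.mnar_slope == 0 and self.mcar_rate == 0:
            return np.zeros_like(x)
        mnar = 1.0 / (1.0 + np.exp(self.mnar_slope * (x - midpoint))) if self.mnar_slope else 0.0
        return 1.0 - (1.0 - mnar) * (1.0 - self.mcar_rate)


def gen_abundance_cohort(
    seed: int,
    design: Mapping[str, tuple[int, int]],
    n_proteins: int = 200,
    de_fraction: float = 0.10,
    effect_log2fc: float = 1.0,
    sigma: float = 0.5,
    missing: MissingModel = MissingModel(),
    n_core: int = 3,
    n_unique_per_cohort: int = 5,
    baseline_mean: float = 25.0,
    baseline_sd: float = 2.0,
) -> tuple[AbundanceMatrix, TruthBundle]:
    """CPTAC-style multi-cohort abundance matrix with planted structure.

    ``design`` maps cohort label -> (n_tumor, n_nontumor). The first
    ``n_core`` proteins are expressed in every cohort (high baseline, so
    the 30% presence rule always finds them); the next blocks of
    ``n_unique_per_cohort`` are expressed in exactly one cohort; the rest
    are expressed in a random proper subset of >= 2 cohorts (or all, when
    only one or two cohorts exist). A ``de_fraction`` of proteins carries
    a +/- ``effect_log2fc`` tumor shift wherever expressed.
    """
    if not 0 <= de_fraction <= 1:
        raise ValueError("de_fraction must lie in [0, 1]")
    cohorts = sorted(design)
    if any(min(sz) < 3 for sz in design.values()):
        raise ValueError("group sizes must be >= 3")
    rng = np.random.default_rng(seed)
    proteins = [f"LEP{i + 1:05d}" for i in range(n_proteins)]
    truth = TruthBundle(seed=seed)

    n_unique_total = n_unique_per_cohort * len(cohorts)
    if n_core + n_unique_total > n_proteins:
        raise ValueError("n_proteins too small for requested core/unique structure")
    expressed_in: dict[str, set[str]] = {p: set() for p in proteins}
    truth.planted_core_leps = set(proteins[:n_core])
    for p in truth.planted_core_leps:
        expressed_in[p] = set(cohorts)
    idx = n_core
    truth.planted_unique_leps = {}
    for c in cohorts:
        block = set(proteins[idx : idx + n_unique_per_cohort])
        truth.planted_unique_leps[c] = block
        for p in block:
            expressed_in[p] = {c}
        idx += n_unique_per_cohort
    for p in proteins[idx:]:
        if len(cohorts) <= 2:
            expressed_in[p] = set(cohorts)
        else:
            k = int(rng.integers(2, len(cohorts)))  # proper subset, never all
            expressed_in[p] = set(rng.choice(cohorts, size=k, replace=False))

    planted = expressed_in  # alias for readability below
    n_de = int(round(de_fraction * n_proteins))
    de_idx = rng.choice(n_proteins, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    truth.planted_de = {proteins[i]: float(s * effect_log2fc) for i, s in zip(de_idx, signs)}

    # baselines: planted core/unique proteins get a high, tight baseline so
    # their presence is a matter of construction, not luck
    mu = rng.normal(baseline_mean, baseline_sd, size=n_proteins)
    special = set(proteins[: n_core + n_unique_total])
    for i, p in enumerate(proteins):
        if p in special:
            mu[i] = baseline_mean + 2.0 + rng.normal(0, 0.25)

    columns: list[str] = []
    meta_rows: list[tuple[str, str, str, str]] = []
    for c in cohorts:
        nt, nn = design[c]
        for j in range(nt):
            sid = f"{c}_T{j + 1:02d}"
            columns.append(sid)
            meta_rows.append((sid, c, "tumor", f"{c}_P{j + 1:02d}" if j < nn else ""))
        for j in range(nn):
            sid = f"{c}_N{j + 1:02d}"
            columns.append(sid)
            meta_rows.append((sid, c, "nontumor", f"{c}_P{j + 1:02d}" if j < nt else ""))

    de_effect = np.zeros(n_proteins)
    for i, s in zip(de_idx, signs):
        de_effect[i] = s * effect_log2fc
    expressed_by_cohort = {
        c: np.array([c in planted[p] for p in proteins]) for c in cohorts
    }
    log2 = np.full((n_proteins, len(columns)), np.nan)
    for si, (sid, cohort, group, _pair) in enumerate(meta_rows):
        x = rng.normal(mu, sigma)
        if group == "tumor":
            x = x + de_effect
        col = np.where(expressed_by_cohort[cohort], x, np.nan)
        log2[:, si] = col

    expressed_vals = log2[~np.isnan(log2)]
    midpoint = float(np.quantile(expressed_vals, missing.mnar_quantile)) if expressed_vals.size else 0.0
    pmiss = missing.missing_prob(np.nan_to_num(log2, nan=-np.inf), midpoint)
    drop = rng.random(log2.shape) < pmiss
    log2[drop] = np.nan

    values = pd.DataFrame(np.exp2(log2), index=proteins, columns=columns)
    meta = pd.DataFrame(
        [(c, g, pid or np.nan) for (_s, c, g, pid) in meta_rows],
        index=[s for (s, _c, _g, _p) in meta_rows],
        columns=["cohort", "group", "pair_id"],
    )
    meta.index.name = "sample_id"
    return AbundanceMatrix(values, meta), truth


# ------------------------------------------------------------ interactome

def gen_interactome_replicates(
    seed: int,
    n_core: int = 139,
    n_noise_per_replicate: int = 40,
    n_replicates: int = 4,
    experiment: str = "coip",
    core_accessions: Sequence[str] | None = None,
) -> tuple[ReplicateLists, TruthBundle]:
    """Replicate identification lists: a planted core present in every
    replicate plus noise accessions each private to one replicate."""
    if n_core < 0 or n_noise_per_replicate < 0:
        raise ValueError("counts must be >= 0")
    if core_accessions is None:
        core = [f"{experiment.upper()}C{i + 1:04d}" for i in range(n_core)]
    else:
        if len(core_accessions) != n_core:
            raise ValueError("core_accessions length must equal n_core")
        core = list(core_accessions)
    reps = []
    for r in range(n_replicates):
        noise = {f"{experiment.upper()}R{r + 1}N{i + 1:04d}" for i in range(n_noise_per_replicate)}
        reps.append(frozenset(core) | noise)
    truth = TruthBundle(seed=seed, replicate_core=set(core))
    return ReplicateLists(experiment, tuple(reps)), truth


def gen_pulldown_study(
    seed: int,
    n_probe_specific: int = 65,
    n_shared_with_control: int = 80,
    n_coip_core: int = 139,
    n_overlap: int = 23,
    n_isoform_specific: int = 27,
    n_coip_noise: int = 40,
    n_coip_replicates: int = 4,
) -> dict[str, object]:
    """Planted interactome study mirroring an RNA-pulldown + IP-MS design.

    Emits: a probe (pre-mRNA bait) list and a bead-control list whose
    difference has exactly ``n_probe_specific`` members; Co-IP replicate
    lists whose all-replicate core has ``n_coip_core`` members, of which
    exactly ``n_overlap`` also sit in the probe-specific set; and two
    isoform IP lists (long vs short) differing by ``n_isoform_specific``
    proteins. Returns a dict of the objects plus a TruthBundle.
    """
    if n_overlap > min(n_probe_specific, n_coip_core):
        raise ValueError("n_overlap cannot exceed either parent set size")
    rng = np.random.default_rng(seed)

    def accs(tag: str, n: int) -> list[str]:
        return [f"{tag}{i + 1:04d}" for i in range(n)]

    overlap = accs("OVL", n_overlap)
    probe_only = overlap + accs("PRB", n_probe_specific - n_overlap)
    shared = accs("SHR", n_shared_with_control)
    control_only = accs("CTL", 30 + int(rng.integers(20)))
    probe = ProteinSet("probe", frozenset(probe_only) | frozenset(shared))
    control = ProteinSet("control", frozenset(shared) | frozenset(control_only))

    coip_core = overlap + accs("CIP", n_coip_core - n_overlap)
    coip, _ = gen_interactome_replicates(
        int(rng.integers(2**31)),
        n_core=n_coip_core,
        n_noise_per_replicate=n_coip_noise,
        n_replicates=n_coip_replicates,
        experiment="coip",
        core_accessions=coip_core,
    )

    iso_shared = accs("ISH", 60)
    long_only = accs("LNG", n_isoform_specific)
    short_only = accs("SRT", 10 + int(rng.integers(10)))
    long_ip = ProteinSet("tcf7l2_l_ip", frozenset(iso_shared) | frozenset(long_only))
    short_ip = ProteinSet("tcf7l2_s_ip", frozenset(iso_shared) | frozenset(short_only))

    truth = TruthBundle(seed=seed, replicate_core=set(coip_core))
    return {
        "probe": probe,
        "control": control,
        "coip": coip,
        "long_ip": long_ip,
        "short_ip": short_ip,
        "planted": {
            "probe_specific": sorted(probe_only),
            "coip_core": sorted(coip_core),
            "overlap": sorted(overlap),
            "isoform_specific": sorted(long_only),
        },
        "truth": truth,
    }


# ----------------------------------------------------------------- splice

def gen_junction_counts(
    seed: int,
    events_spec: Sequence[tuple[str, str, str, Mapping[str, float]]],
    n_samples_per_condition: int = 3,
    depth: int = 100,
) -> tuple[list[SpliceEvent], TruthBundle]:
    """Binomial junction counts from true PSI values.

    ``events_spec``: (event_id, gene, event_type, {condition: true_psi}).
    For SE events the per-read inclusion probability is 2*psi/(1+psi),
    honouring the two-inclusion-junctions-per-skip convention; other
    types use psi directly. Per sample, inclusion ~ Binomial(depth, p)
    and exclusion = depth - inclusion.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    truth = TruthBundle(seed=seed)
    events = []
    for event_id, gene, event_type, psi_by_cond in events_spec:
        samples, inc, exc, conds = [], [], [], []
        for cond in sorted(psi_by_cond):
            psi = float(psi_by_cond[cond])
            if not 0 <= psi <= 1:
                raise ValueError(f"PSI {psi} outside [0, 1] for {event_id}/{cond}")
            p = 2 * psi / (1 + psi) if event_type == "SE" else psi
            for j in range(n_samples_per_condition):
                i = int(rng.binomial(depth, p))
                samples.append(f"{cond}_{j + 1}")
                inc.append(i)
                exc.append(depth - i)
                conds.append(cond)
        events.append(
            SpliceEvent(event_id, gene, event_type, tuple(samples), tuple(inc), tuple(exc), tuple(conds))
        )
        truth.true_psi[event_id] = dict(psi_by_cond)
    return events, truth


# ---------------------------------------------------------------- writers

def write_transcripts_fasta(transcripts: Sequence[Transcript], out: str | Path, seed: int) -> None:
    lines = []
    for t in transcripts:
        lines.append(f">{t.id} seed={seed}")
        for i in range(0, len(t.sequence), 70):
            lines.append(t.sequence[i : i + 70])
    Path(out).write_text("\n".join(lines) + "\n")


def write_proteome_fasta(proteins: Sequence[ProteinRecord], out: str | Path, seed: int | None = None) -> None:
    lines = []
    tag = f" seed={seed}" if seed is not None else ""
    for p in proteins:
        lines.append(f">{p.accession}{tag}")
        for i in range(0, len(p.sequence), 70):
            lines.append(p.sequence[i : i + 70])
    Path(out).write_text("\n".join(lines) + "\n")


def write_abundance_tsv(
    matrix: AbundanceMatrix, values_out: str | Path, meta_out: str | Path, seed: int
) -> None:
    with open(values_out, "w") as fh:
        fh.write(f"# seed={seed}\n")
        matrix.values.to_csv(fh, sep="\t", na_rep="NA", index_label="protein")
    with open(meta_out, "w") as fh:
        fh.write(f"# seed={seed}\n")
        matrix.sample_meta.to_csv(fh, sep="\t", na_rep="")


def write_replicate_tsvs(lists: ReplicateLists, outdir: str | Path, seed: int) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for r, rep in enumerate(lists.replicates):
        path = outdir / f"{lists.experiment}_rep{r + 1}.tsv"
        path.write_text(f"# seed={seed}\naccession\n" + "\n".join(sorted(rep)) + "\n")
        paths.append(path)
    return paths


def write_event_tsv(events: Sequence[SpliceEvent], out: str | Path, seed: int) -> None:
    lines = [
        f"# seed={seed}",
        "event_id\tgene\tevent_type\tsample_id\tcondition\tinclusion_count\texclusion_count",
    ]
    for e in events:
        for s, i, x, c in zip(e.samples, e.inclusion_counts, e.exclusion_counts, e.conditions):
            lines.append(f"{e.event_id}\t{e.gene}\t{e.event_type}\t{s}\t{c}\t{i}\t{x}")
    Path(out).write_text("\n".join(lines) + "\n")
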