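"""End-to-end orchestration of the microprotein screening pipeline.

Stages run in dependency order: (optional) synthetic-data generation,
sORF discovery, peptide-uniqueness classification, cohort screening,
interactome set analysis and splicing quantification. Every stage writes
its tables under the configured output directory and contributes counts
to a machine-readable run report. Reruns with the same config and seed
reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import digest as dg
from . import orf as orf_mod
from . import screen as sc
from . import sets as st
from . import simulate as sim
from . import splicing as sp

log = logging.getLogger("lepscan")

ALL_STAGES = ("generate", "sorfs", "digest", "screen", "sets", "splice")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    outdir: str = "results/pipeline"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # inputs; filled automatically by the generate stage when enabled
    transcripts_fasta: str | None = None
    reference_fasta: str | None = None
    abundance_tsv: str | None = None
    sample_meta_tsv: str | None = None
    replicate_dir: str | None = None
    event_tsv: str | None = None
    # stage parameters
    orf: orf_mod.OrfConfig = field(default_factory=orf_mod.OrfConfig)
    digest: dg.DigestConfig = field(default_factory=dg.DigestConfig)
    screen: sc.ScreenConfig = field(default_factory=sc.ScreenConfig)
    splice_test_condition: str = "overexpression"
    splice_control_condition: str = "control"
    splice_alpha: float = 0.05
    splice_min_delta: float = 0.1
    splice_min_coverage: int = 10
    # generator sizes (used only when the generate stage is enabled)
    gen_n_transcripts: int = 12
    gen_n_reference: int = 120
    gen_design: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"kidney": (12, 12), "liver": (12, 12), "lung": (12, 12)}
    )
    gen_n_proteins: int = 150
    gen_n_events: int = 8

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict[str, Any] = {}
        for key, val in raw.items():
            if key == "orf":
                kwargs[key] = orf_mod.OrfConfig(**val)
            elif key == "digest":
                kwargs[key] = dg.DigestConfig(**val)
            elif key == "screen":
                kwargs[key] = sc.ScreenConfig(**val)
            elif key == "stages":
                kwargs[key] = tuple(val)
            elif key == "gen_design":
                kwargs[key] = {c: tuple(v) for c, v in val.items()}
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["stages"] = list(self.stages)
        raw["gen_design"] = {c: list(v) for c, v in self.gen_design.items()}
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


@dataclass
class RunReport:
    seed: int
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)
    elapsed_s: float = 0.0
    failed_stage: str | None = None
    error: str | None = None

    def to_json(self, out: str | Path) -> None:
        Path(out).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n")


def run_pipeline(config: RunConfig) -> RunReport:
    t0 = time.monotonic()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    try:
        for stage in config.stages:
            if stage not in ALL_STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            t1 = time.monotonic()
            try:
                counts = _STAGE_FNS[stage](config, outdir)
            except Exception as exc:  # noqa: BLE001 - converted to report
                raise StageError(stage, exc) from exc
            counts["elapsed_s"] = round(time.monotonic() - t1, 3)
            report.stages[stage] = counts
            log.info("stage=%s %s", stage, counts)
    except StageError as err:
        report.failed_stage = err.stage
        report.error = str(err.cause)
        report.elapsed_s = round(time.monotonic() - t0, 3)
        report.to_json(outdir / "run_report.json")
        raise
    report.elapsed_s = round(time.monotonic() - t0, 3)
    report.to_json(outdir / "run_report.json")
    return report


# ------------------------------------------------------------------ stages

def _stage_generate(config: RunConfig, outdir: Path) -> dict[str, Any]:
    gdir = outdir / "inputs"
    gdir.mkdir(exist_ok=True)
    seed = config.seed
    transcripts, tx_truth = sim.gen_transcriptome(seed, n_transcripts=config.gen_n_transcripts)
    sim.write_transcripts_fasta(transcripts, gdir / "transcripts.fasta", seed)
    reference = sim.gen_reference_proteome(seed + 1, n_proteins=config.gen_n_reference)
    sim.write_proteome_fasta(reference, gdir / "reference.fasta", seed + 1)
    matrix, ab_truth = sim.gen_abundance_cohort(
        seed + 2, design=config.gen_design, n_proteins=config.gen_n_proteins
    )
    sim.write_abundance_tsv(matrix, gdir / "abundance.tsv", gdir / "samples.tsv", seed + 2)
    study = sim.gen_pulldown_study(seed + 3)
    sim.write_replicate_tsvs(study["coip"], gdir / "replicates", seed + 3)
    for key in ("probe", "control", "long_ip", "short_ip"):
        st.write_membership(study[key], gdir / "replicates" / f"{key}.tsv")
    conds = {config.splice_control_condition: 0.4, config.splice_test_condition: 0.7}
    spec = [
        (f"EV{i + 1:03d}", f"GENE{i + 1}", "SE" if i % 2 == 0 else "RI", conds)
        for i in range(config.gen_n_events)
    ]
    events, psi_truth = sim.gen_junction_counts(seed + 4, spec, depth=300)
    sim.write_event_tsv(events, gdir / "events.tsv", seed + 4)
    truth = sim.TruthBundle(
        seed=seed,
        planted_orfs=tx_truth.planted_orfs,
        planted_de=ab_truth.planted_de,
        planted_core_leps=ab_truth.planted_core_leps,
        planted_unique_leps=ab_truth.planted_unique_leps,
        replicate_core=set(study["planted"]["coip_core"]),
        true_psi=psi_truth.true_psi,
    )
    truth.to_json(gdir / "truth.json")
    config.transcripts_fasta = str(gdir / "transcripts.fasta")
    config.reference_fasta = str(gdir / "reference.fasta")
    config.abundance_tsv = str(gdir / "abundance.tsv")
    config.sample_meta_tsv = str(gdir / "samples.tsv")
    config.replicate_dir = str(gdir / "replicates")
    config.event_tsv = str(gdir / "events.tsv")
    return {
        "n_transcripts": len(transcripts),
        "n_reference_proteins": len(reference),
        "n_abundance_proteins": matrix.values.shape[0],
        "n_events": len(events),
    }


def _stage_sorfs(config: RunConfig, outdir: Path) -> dict[str, Any]:
    if config.transcripts_fasta is None:
        raise ValueError("transcripts_fasta not configured")
    all_orfs: list[orf_mod.SmallORF] = []
    canonical: list[orf_mod.SmallORF] = []
    n_tx = 0
    for tx in orf_mod.read_transcripts(config.transcripts_fasta):
        n_tx += 1
        orfs = orf_mod.find_sorfs(tx, config.orf)
        all_orfs.extend(orfs)
        if orfs:
            canonical.append(orf_mod.select_canonical_orf(orfs))
    orf_mod.write_orf_table(all_orfs, outdir / "orfs.tsv")
    n_written = orf_mod.write_candidate_db(canonical, outdir / "candidates.fasta")
    return {"n_transcripts": n_tx, "n_orfs": len(all_orfs), "n_candidates": n_written}


def _stage_digest(config: RunConfig, outdir: Path) -> dict[str, Any]:
    if config.reference_fasta is None:
        raise ValueError("reference_fasta not configured")
    reference = dg.read_proteome(config.reference_fasta, "reference")
    leps = dg.read_proteome(outdir / "candidates.fasta", "lep")
    calls: list[dg.UniquenessCall] = []
    calls_by_lep: dict[str, list[dg.UniquenessCall]] = {}
    if leps:
        index = dg.build_reference_index(reference + leps, config.digest)
        for lep in leps:
            lep_calls = [
                dg.classify_peptide(p.sequence, index)
                for p in dg.digest_protein(lep, config.digest)
            ]
            calls_by_lep[lep.accession] = lep_calls
            calls.extend(lep_calls)
    dg.write_uniqueness_table(calls, outdir / "uniqueness.tsv")
    dg.write_lep_summary(leps, calls_by_lep, outdir / "lep_summary.tsv")
    n_supported = sum(
        1 for lep in leps if dg.lep_unique_peptide_count(lep, calls_by_lep[lep.accession]) >= 1
    )
    return {"n_reference": len(reference), "n_leps": len(leps),
            "n_peptide_calls": len(calls), "n_peptide_supported": n_supported}


def _stage_screen(config: RunConfig, outdir: Path) -> dict[str, Any]:
    if config.abundance_tsv is None or config.sample_meta_tsv is None:
        raise ValueError("abundance inputs not configured")
    matrix = sc.read_abundance(config.abundance_tsv, config.sample_meta_tsv)
    presence = sc.call_presence(matrix, config.screen)
    sc.write_presence_table(presence, outdir / "presence.tsv")
    ident = sc.identified_sets(presence)
    core, unique, counts = sc.pan_cancer_sets(ident)
    sc.write_set_summary(core, unique, counts, outdir / "pan_cancer.json")
    de_all: list[sc.DEResult] = []
    lines = ["protein\tcohort\tlog2fc\tp_value\ttest_used\tsignificant\tskip_reason"]
    for cohort in matrix.cohorts:
        for r in sc.differential_expression(matrix, config.screen, cohort=cohort):
            de_all.append(r)
            lines.append(
                f"{r.protein}\t{cohort}\t{r.log2fc:.6g}\t{r.p_value:.6g}\t"
                f"{r.test_used}\t{str(r.significant).lower()}\t{r.skip_reason}"
            )
    (outdir / "de.tsv").write_text("\n".join(lines) + "\n")
    return {
        "n_proteins": matrix.values.shape[0],
        "n_cohorts": len(matrix.cohorts),
        "core_count": len(core),
        "unique_counts": {c: len(s) for c, s in sorted(unique.items())},
        "n_de_tested": sum(1 for r in de_all if not r.skip_reason),
        "n_de_significant": sum(1 for r in de_all if r.significant),
    }


def _stage_sets(config: RunConfig, outdir: Path) -> dict[str, Any]:
    if config.replicate_dir is None:
        raise ValueError("replicate_dir not configured")
    rdir = Path(config.replicate_dir)
    rep_paths = sorted(rdir.glob("*_rep*.tsv"))
    counts: dict[str, Any] = {}
    consistent = None
    if rep_paths:
        by_exp: dict[str, list[Path]] = {}
        for p in rep_paths:
            exp = p.stem.rsplit("_rep", 1)[0]
            by_exp.setdefault(exp, []).append(p)
        for exp, paths in sorted(by_exp.items()):
            reps = [st.read_accession_list(p).members for p in sorted(paths)]
            lists = st.ReplicateLists(exp, tuple(reps))
            consistent = st.replicate_consistent_set(lists)
            st.write_membership(consistent, outdir / f"{exp}_consistent.tsv")
            counts[f"{exp}_consistent_count"] = len(consistent)
    named = {}
    for key in ("probe", "control", "long_ip", "short_ip"):
        path = rdir / f"{key}.tsv"
        if path.exists():
            named[key] = st.read_accession_list(path, key)
    if {"probe", "control"} <= named.keys():
        specific = st.set_difference(named["probe"], named["control"])
        st.write_membership(specific, outdir / "probe_specific.tsv")
        counts["probe_specific_count"] = len(specific)
        if consistent is not None:
            overlap = st.set_intersection([specific, consistent])
            st.write_membership(overlap, outdir / "probe_coip_overlap.tsv")
            counts["probe_coip_overlap_count"] = len(overlap)
    if {"long_ip", "short_ip"} <= named.keys():
        iso = st.set_difference(named["long_ip"], named["short_ip"])
        st.write_membership(iso, outdir / "isoform_specific.tsv")
        counts["isoform_specific_count"] = len(iso)
    st.venn_summary(
        [s for s in (consistent, *named.values()) if s is not None],
        outdir / "venn.json",
    ) if (consistent or named) else None
    return counts


def _stage_splice(config: RunConfig, outdir: Path) -> dict[str, Any]:
    if config.event_tsv is None:
        raise ValueError("event_tsv not configured")
    events = sp.read_event_table(config.event_tsv)
    results = []
    for ev in events:
        results.append(
            sp.delta_psi_test(
                ev,
                config.splice_test_condition,
                config.splice_control_condition,
                alpha=config.splice_alpha,
                min_delta=config.splice_min_delta,
                min_coverage=config.splice_min_coverage,
            )
        )
    sp.write_psi_table(results, outdir / "psi.tsv")
    props, type_counts = sp.event_type_distribution(results, {e.event_id: e for e in events})
    (outdir / "event_types.json").write_text(
        json.dumps({"proportions": props, "counts": type_counts}, indent=2) + "\n"
    )
    return {
        "n_events": len(events),
        "n_significant": sum(1 for r in results if r.significant),
        "type_proportions": props,
    }


_STAGE_FNS = {
    "generate": _stage_generate,
    "sorfs": _stage_sorfs,
    "digest": _stage_digest,
    "screen": _stage_screen,
    "sets": _stage_sets,
    "splice": _stage_splice,
}
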