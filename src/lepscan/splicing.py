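"""Percent-spliced-in (PSI) quantification of alternative-splicing events.

Works from an rMATS-like junction-count table: per event, per sample,
the number of reads supporting inclusion of the alternative segment and
the number supporting its exclusion. For a skipped-exon (SE) event two
junctions support inclusion but only one supports skipping, so inclusion
counts are halved before the PSI ratio (``length_normalize``):

    PSI = I_eff / (I_eff + E),   I_eff = I/2 for SE.

Condition differences are tested on the pooled 2x2 effective-count table
with a two-sided Fisher exact test (minimum-likelihood convention, as in
common implementations); an event is significant when p < alpha and
|delta PSI| >= min_delta. Long/short isoform ratios follow the same
inclusion/exclusion algebra: ratio = PSI/(1-PSI) in the noiseless limit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpliceEvent",
    "PsiResult",
    "IsoformRatio",
    "EVENT_TYPES",
    "compute_psi",
    "delta_psi_test",
    "event_type_distribution",
    "isoform_ratio",
    "read_event_table",
    "write_psi_table",
]

EVENT_TYPES = ("SE", "RI", "A5SS", "A3SS", "MXE")


@dataclass(frozen=True)
class SpliceEvent:
    event_id: str
    gene: str
    event_type: str
    samples: tuple[str, ...]
    inclusion_counts: tuple[int, ...]
    exclusion_counts: tuple[int, ...]
    conditions: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type {self.event_type!r}")
        n = len(self.samples)
        if not (len(self.inclusion_counts) == len(self.exclusion_counts) == len(self.conditions) == n):
            raise ValueError("per-sample vectors must align")
        if any(c < 0 for c in self.inclusion_counts + self.exclusion_counts):
            raise ValueError("counts must be non-negative")

    def pooled(self, condition: str) -> tuple[int, int]:
        inc = sum(i for i, c in zip(self.inclusion_counts, self.conditions) if c == condition)
        exc = sum(e for e, c in zip(self.exclusion_counts, self.conditions) if c == condition)
        return inc, exc


@dataclass(frozen=True)
class PsiResult:
    event_id: str
    psi_by_condition: dict[str, float]
    delta_psi: float = float("nan")
    p_value: float = float("nan")
    significant: bool = False
    skip_reason: str = ""


@dataclass(frozen=True)
class IsoformRatio:
    long_abundance: float
    short_abundance: float
    ratio: float


class LowCoverageError(ValueError):
    pass


def _effective(inc: int, exc: int, event_type: str, length_normalize: bool) -> tuple[float, float]:
    i_eff = inc / 2 if (length_normalize and event_type == "SE") else float(inc)
    return i_eff, float(exc)


def compute_psi(
    event: SpliceEvent,
    length_normalize: bool = True,
    min_coverage: int = 10,
) -> PsiResult:
    """Pooled per-condition PSI; conditions below ``min_coverage`` total
    junction reads cause the event to be skipped with a reason."""
    psi: dict[str, float] = {}
    for cond in dict.fromkeys(event.conditions):
        inc, exc = event.pooled(cond)
        if inc + exc < min_coverage:
            return PsiResult(event.event_id, {}, skip_reason=f"coverage<{min_coverage} in {cond}")
        i_eff, e_eff = _effective(inc, exc, event.event_type, length_normalize)
        psi[cond] = i_eff / (i_eff + e_eff)
    return PsiResult(event.event_id, psi)


def delta_psi_test(
    event: SpliceEvent,
    test_condition: str,
    control_condition: str,
    alpha: float = 0.05,
    min_delta: float = 0.1,
    length_normalize: bool = True,
    min_coverage: int = 10,
) -> PsiResult:
    """Two-sided Fisher exact test on the pooled effective-count 2x2 table."""
    for cond in (test_condition, control_condition):
        if cond not in event.conditions:
            raise ValueError(f"condition {cond!r} absent from event {event.event_id}")
    base = compute_psi(event, length_normalize, min_coverage)
    if base.skip_reason:
        return base
    table = []
    for cond in (test_condition, control_condition):
        inc, exc = event.pooled(cond)
        i_eff, e_eff = _effective(inc, exc, event.event_type, length_normalize)
        table.append([round(i_eff), round(e_eff)])
    p = float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])
    delta = base.psi_by_condition[test_condition] - base.psi_by_condition[control_condition]
    return PsiResult(
        event.event_id,
        base.psi_by_condition,
        delta_psi=delta,
        p_value=p,
        significant=bool(p < alpha and abs(delta) >= min_delta),
    )


def event_type_distribution(
    results: Iterable[PsiResult],
    events_by_id: Mapping[str, SpliceEvent],
) -> tuple[dict[str, float], dict[str, int]]:
    """Proportions (and counts) of event types among significant events.

    Returns empty dicts with a warning-free empty result when nothing is
    significant; callers decide how to report that.
    """
    counts: dict[str, int] = {}
    for r in results:
        if r.significant:
            et = events_by_id[r.event_id].event_type
            counts[et] = counts.get(et, 0) + 1
    total = sum(counts.values())
    props = {et: c / total for et, c in counts.items()} if total else {}
    return props, counts


def isoform_ratio(long_abundance: float, short_abundance: float) -> IsoformRatio:
    """Long/short splice-variant ratio (e.g. exon-13-retaining TCF7L2-L
    over TCF7L2-S); a zero short-isoform abundance is an error, never inf."""
    if long_abundance < 0 or short_abundance < 0:
        raise ValueError("abundances must be non-negative")
    if short_abundance == 0:
        raise ValueError("short_abundance is zero: ratio undefined")
    return IsoformRatio(long_abundance, short_abundance, long_abundance / short_abundance)


# ---------------------------------------------------------------- file IO

_COLS = ["event_id", "gene", "event_type", "sample_id", "condition",
         "inclusion_count", "exclusion_count"]


def read_event_table(path: str | Path) -> list[SpliceEvent]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _COLS if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    events = []
    for eid, grp in df.groupby("event_id", sort=True):
        events.append(
            SpliceEvent(
                event_id=str(eid),
                gene=str(grp["gene"].iloc[0]),
                event_type=str(grp["event_type"].iloc[0]),
                samples=tuple(grp["sample_id"].astype(str)),
                inclusion_counts=tuple(int(x) for x in grp["inclusion_count"]),
                exclusion_counts=tuple(int(x) for x in grp["exclusion_count"]),
                conditions=tuple(grp["condition"].astype(str)),
            )
        )
    return events


def write_psi_table(results: Iterable[PsiResult], out: str | Path) -> int:
    rows = []
    for r in results:
        psi_str = ";".join(f"{c}={v:.6g}" for c, v in sorted(r.psi_by_condition.items()))
        rows.append(
            f"{r.event_id}\t{psi_str}\t{r.delta_psi:.6g}\t{r.p_value:.6g}\t"
            f"{str(r.significant).lower()}\t{r.skip_reason}"
        )
    header = "event_id\tpsi_by_condition\tdelta_psi\tp_value\tsignificant\tskip_reason"
    Path(out).write_text("\n".join([header, *rows]) + "\n")
    return len(rows)
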