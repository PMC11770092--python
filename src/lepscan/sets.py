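"""Set algebra over replicate protein-identification lists.

Interactome experiments (IP-MS, RNA pulldown) yield one protein list per
biological replicate. The analysis questions are Venn-style: which
proteins are identified consistently across replicates, which are
specific to a probe versus its control, and which candidates overlap
between two independent experiments. These operations are deliberately
simple set algebra, kept explicit so provenance (set names) survives
into the reports.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ProteinSet",
    "ReplicateLists",
    "normalize_accession",
    "replicate_consistent_set",
    "set_difference",
    "set_intersection",
    "read_accession_list",
    "write_membership",
    "venn_summary",
]

_ISOFORM = re.compile(r"-\d+$")
_VERSION = re.compile(r"\.\d+$")


def normalize_accession(
    acc: str, *, strip_isoform: bool = False, strip_version: bool = False
) -> str:
    """Uppercase an accession; optionally drop isoform ("-2") and version
    (".3") suffixes, which supplementary MS tables mix freely."""
    acc = acc.strip().upper()
    if strip_isoform:
        acc = _ISOFORM.sub("", acc)
    if strip_version:
        acc = _VERSION.sub("", acc)
    return acc


@dataclass(frozen=True)
class ProteinSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("set name must be non-empty")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ReplicateLists:
    experiment: str
    replicates: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("need at least one replicate")
        object.__setattr__(
            self, "replicates", tuple(frozenset(r) for r in self.replicates)
        )


def replicate_consistent_set(lists: ReplicateLists, r_min: int | None = None) -> ProteinSet:
    """Proteins seen in at least ``r_min`` replicates (default: all).

    "Identified across N biological replicates" is read as present in all
    N; relax ``r_min`` for union-like semantics.
    """
    n = len(lists.replicates)
    if r_min is None:
        r_min = n
    if not 1 <= r_min <= n:
        raise ValueError(f"r_min={r_min} out of range [1, {n}]")
    counts = Counter(acc for rep in lists.replicates for acc in rep)
    members = frozenset(acc for acc, c in counts.items() if c >= r_min)
    return ProteinSet(f"{lists.experiment}_r{r_min}of{n}", members)


def set_difference(a: ProteinSet, b: ProteinSet) -> ProteinSet:
    return ProteinSet(f"{a.name}_minus_{b.name}", a.members - b.members)


def set_intersection(sets: Sequence[ProteinSet]) -> ProteinSet:
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    members = frozenset.intersection(*(s.members for s in sets))
    return ProteinSet("_and_".join(s.name for s in sets), members)


def read_accession_list(
    path: str | Path,
    name: str | None = None,
    *,
    strip_isoform: bool = False,
    strip_version: bool = False,
) -> ProteinSet:
    """One- or multi-column TSV; the first column is the accession, a
    header line named 'accession' (or starting '#') is skipped."""
    members: set[str] = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        acc = line.split("\t")[0].strip()
        if acc.lower() in {"accession", "protein", "protein_id"}:
            continue
        members.add(
            normalize_accession(acc, strip_isoform=strip_isoform, strip_version=strip_version)
        )
    return ProteinSet(name or Path(path).stem, members)


def write_membership(pset: ProteinSet, out: str | Path) -> int:
    Path(out).write_text("accession\n" + "\n".join(sorted(pset.members)) + "\n")
    return len(pset)


def venn_summary(sets: Sequence[ProteinSet], out: str | Path | None = None) -> dict[str, int]:
    """Region -> count for every non-empty intersection/exclusion region."""
    regions: dict[str, int] = {s.name: len(s) for s in sets}
    if len(sets) >= 2:
        universe = frozenset().union(*(s.members for s in sets))
        pattern_counts: Counter[tuple[str, ...]] = Counter()
        for acc in universe:
            key = tuple(s.name for s in sets if acc in s.members)
            pattern_counts[key] += 1
        for key, count in sorted(pattern_counts.items()):
            regions["only:" + "&".join(key)] = count
    if out is not None:
        Path(out).write_text(json.dumps(regions, indent=2) + "\n")
    return regions
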