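"""In-silico tryptic digestion and peptide-uniqueness classification.

A candidate microprotein is only credible as a mass-spectrometry discovery
if at least one of its tryptic peptides cannot be produced by any protein
in the reviewed reference proteome. This module digests proteins with the
trypsin rule (cleave C-terminal to K or R, except before P), indexes the
reference digest for constant-time membership queries, and classifies each
candidate peptide as matching the reference, shared among candidates, or
unique to a single candidate.

Because MS cannot distinguish isoleucine from leucine, lookups collapse
I and L by default. Uniqueness is evaluated at the tryptic-peptide level
(the way search engines assign peptides to proteins); a stricter
substring-of-protein mode is available via ``IndexMode.SUBSTRING``.
"""

from __future__ import annotations

import enum
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "DigestConfig",
    "PeptideRecord",
    "UniquenessCall",
    "digest_protein",
    "cleavage_fragments",
    "build_reference_index",
    "PeptideIndex",
    "classify_peptide",
    "lep_unique_peptide_count",
    "read_proteome",
    "write_uniqueness_table",
    "write_lep_summary",
]

_AA = re.compile(r"[ACDEFGHIKLMNPQRSTVWYXU]+\Z")  # X unknown, U selenocysteine


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str
    origin: Literal["reference", "lep"] = "reference"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not _AA.match(seq):
            bad = next(c for c in seq if not _AA.match(c))
            raise ValueError(f"{self.accession}: invalid residue {bad!r}")


@dataclass(frozen=True)
class DigestConfig:
    """Trypsin digest parameters, mirroring common search-engine defaults."""

    max_missed_cleavages: int = 2
    min_len: int = 7
    max_len: int = 50
    il_equivalent: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.max_missed_cleavages <= 5:
            raise ValueError("max_missed_cleavages must be in [0, 5]")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")


@dataclass(frozen=True)
class PeptideRecord:
    sequence: str
    parent_accession: str
    missed_cleavages: int


@dataclass(frozen=True)
class UniquenessCall:
    peptide: str
    status: Literal["reference", "shared_lep", "unique_lep"]
    matched_accessions: tuple[str, ...]


def cleavage_fragments(sequence: str) -> list[str]:
    """Fully cleaved tryptic fragments (0 missed cleavages, no length filter).

    Concatenating the result reconstructs the input exactly.
    """
    sites = [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]
    bounds = [0, *sites, len(sequence)]
    return [sequence[a:b] for a, b in zip(bounds, bounds[1:])]


def digest_protein(protein: ProteinRecord, config: DigestConfig = DigestConfig()) -> list[PeptideRecord]:
    """Tryptic peptides with up to ``max_missed_cleavages`` internal sites,
    filtered to [min_len, max_len], ordered by start then length."""
    frags = cleavage_fragments(protein.sequence)
    out: list[PeptideRecord] = []
    for i in range(len(frags)):
        pep = ""
        for mc in range(config.max_missed_cleavages + 1):
            if i + mc >= len(frags):
                break
            pep += frags[i + mc]
            if config.min_len <= len(pep) <= config.max_len:
                out.append(PeptideRecord(pep, protein.accession, mc))
    return out


def _key(peptide: str, il_equivalent: bool) -> str:
    return peptide.replace("I", "L") if il_equivalent else peptide


class IndexMode(str, enum.Enum):
    TRYPTIC = "tryptic"
    SUBSTRING = "substring"


class PeptideIndex:
    """Answers "which accessions contain this peptide" for a digested database.

    TRYPTIC mode hashes every tryptic peptide of every protein (sub-linear
    lookups). SUBSTRING mode additionally accepts any exact substring match
    against the undigested protein sequences (stricter uniqueness; linear
    scan per query, adequate at the database sizes used here).
    """

    def __init__(
        self,
        proteins: Sequence[ProteinRecord],
        config: DigestConfig = DigestConfig(),
        mode: IndexMode | str = IndexMode.TRYPTIC,
    ) -> None:
        if not proteins:
            raise ValueError("empty protein database")
        accs = [p.accession for p in proteins]
        if len(set(accs)) != len(accs):
            dupes = sorted({a for a in accs if accs.count(a) > 1})
            raise ValueError(f"duplicate accessions: {', '.join(dupes)}")
        self.config = config
        self.mode = IndexMode(mode)
        self._origin = {p.accession: p.origin for p in proteins}
        self._proteins = list(proteins)
        self._table: dict[str, set[str]] = defaultdict(set)
        for prot in proteins:
            for pep in digest_protein(prot, config):
                self._table[_key(pep.sequence, config.il_equivalent)].add(prot.accession)

    def lookup(self, peptide: str) -> set[str]:
        if not _AA.match(peptide.upper()):
            raise ValueError(f"invalid peptide sequence: {peptide!r}")
        key = _key(peptide.upper(), self.config.il_equivalent)
        hits = set(self._table.get(key, ()))
        if self.mode is IndexMode.SUBSTRING:
            for prot in self._proteins:
                if key in _key(prot.sequence, self.config.il_equivalent):
                    hits.add(prot.accession)
        return hits

    def origin(self, accession: str) -> str:
        return self._origin[accession]


def build_reference_index(
    proteins: Sequence[ProteinRecord],
    config: DigestConfig = DigestConfig(),
    mode: IndexMode | str = IndexMode.TRYPTIC,
) -> PeptideIndex:
    """Index a protein database (reference, candidates, or their union)."""
    return PeptideIndex(proteins, config, mode)


def classify_peptide(
    peptide: str,
    index: PeptideIndex,
    lep_db: Sequence[ProteinRecord] | None = None,
) -> UniquenessCall:
    """Classify one peptide against an index built over reference + LEPs.

    Any reference hit dominates: such a peptide cannot serve as evidence
    for a novel protein. ``lep_db`` may restrict which accessions count as
    candidates; by default the index's own origin labels are used.
    """
    hits = index.lookup(peptide)
    lep_accs = {p.accession for p in lep_db} if lep_db is not None else None
    ref_hits = sorted(a for a in hits if index.origin(a) == "reference")
    lep_hits = sorted(
        a
        for a in hits
        if index.origin(a) == "lep" and (lep_accs is None or a in lep_accs)
    )
    if ref_hits:
        status = "reference"
    elif len(lep_hits) == 1:
        status = "unique_lep"
    elif len(lep_hits) > 1:
        status = "shared_lep"
    else:
        raise ValueError(f"peptide {peptide!r} matches no protein in the index")
    return UniquenessCall(peptide.upper(), status, tuple(ref_hits + lep_hits))


def lep_unique_peptide_count(lep: ProteinRecord, calls: Iterable[UniquenessCall]) -> int:
    """Number of peptides unique to this LEP; >= 1 means peptide-supported."""
    return sum(
        1
        for c in calls
        if c.status == "unique_lep" and c.matched_accessions == (lep.accession,)
    )


_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|([^|]+)\|")


def read_proteome(path: str | Path, origin: Literal["reference", "lep"] = "reference") -> list[ProteinRecord]:
    """Read a proteome FASTA; UniProt-style ``sp|ACC|NAME`` headers are
    reduced to the accession, plain headers are used verbatim."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _UNIPROT_HEADER.match(rec.id)
        acc = m.group(1) if m else rec.id
        records.append(ProteinRecord(acc, str(rec.seq), origin))
    return records


def write_uniqueness_table(calls: Iterable[UniquenessCall], out: str | Path) -> int:
    lines = ["peptide\tstatus\tmatched_accessions"]
    n = 0
    for c in calls:
        lines.append(f"{c.peptide}\t{c.status}\t{';'.join(c.matched_accessions)}")
        n += 1
    Path(out).write_text("\n".join(lines) + "\n")
    return n


def write_lep_summary(
    leps: Sequence[ProteinRecord],
    calls_by_lep: dict[str, list[UniquenessCall]],
    out: str | Path,
) -> int:
    lines = ["accession\tlength_aa\tn_peptides\tn_unique_peptides\tpeptide_supported"]
    for lep in leps:
        calls = calls_by_lep.get(lep.accession, [])
        n_unique = lep_unique_peptide_count(lep, calls)
        lines.append(
            f"{lep.accession}\t{len(lep.sequence)}\t{len(calls)}\t{n_unique}\t"
            f"{str(n_unique >= 1).lower()}"
        )
    Path(out).write_text("\n".join(lines) + "\n")
    return len(leps)
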