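"""Small-ORF discovery on lncRNA transcripts.

Scans transcripts for ATG-initiated open reading frames in the three
forward frames, translates them with the standard genetic code, selects a
canonical (longest) ORF per transcript and emits a candidate microprotein
database in FASTA form for downstream peptide-level validation.

Coordinates are 0-based half-open in memory and 1-based closed in the TSV
report. Scanning is performed on the given strand only: a transcript is
already an oriented RNA molecule, so the reverse complement is never
searched.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Transcript",
    "SmallORF",
    "OrfConfig",
    "find_sorfs",
    "select_canonical_orf",
    "write_candidate_db",
    "write_orf_table",
    "read_transcripts",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_VALID_NT = re.compile(r"[ACGTN]*")


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert U to T; no validation here."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class Transcript:
    """A single (lnc)RNA transcript in transcript-space coordinates."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        norm = normalize_sequence(self.sequence)
        object.__setattr__(self, "sequence", norm)
        if not norm:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        m = _VALID_NT.match(norm)
        if m.end() != len(norm):
            pos = m.end()
            raise ValueError(
                f"transcript {self.id!r}: non-nucleotide character "
                f"{norm[pos]!r} at position {pos}"
            )


@dataclass(frozen=True, order=True)
class SmallORF:
    """An ATG-initiated ORF located on one transcript.

    ``start``/``end`` are 0-based half-open transcript offsets; ``end``
    points just past the stop codon (or past the last complete codon for
    stop-less ORFs when ``require_stop`` is disabled). ``protein_seq``
    excludes the stop symbol.
    """

    transcript_id: str = field(compare=False)
    start: int
    end: int
    frame: int = field(compare=False)
    protein_seq: str = field(compare=False)
    length_aa: int = field(compare=False)
    has_stop: bool = field(compare=False, default=True)

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF span must be a multiple of 3")
        expected = (self.end - self.start) // 3 - (1 if self.has_stop else 0)
        if self.length_aa != expected:
            raise ValueError(
                f"length_aa={self.length_aa} inconsistent with span "
                f"{self.start}-{self.end}"
            )
        if not self.protein_seq.startswith("M"):
            raise ValueError("protein_seq must start with M")


@dataclass(frozen=True)
class OrfConfig:
    """ORF scan parameters.

    min_len_aa: smallest reported product, in residues (stop excluded).
        Microproteins reported from lncRNAs concentrate in the 50-200 aa
        range; 20 aa is a permissive lower bound for candidate generation.
    require_stop: drop ORFs whose frame runs off the transcript 3' end.
    report_nested_starts: also report in-frame internal ATGs sharing a stop
        codon; off by default (one ORF per stop per frame, 5'-most ATG).
    """

    min_len_aa: int = 20
    require_stop: bool = True
    report_nested_starts: bool = False

    def __post_init__(self) -> None:
        if self.min_len_aa < 1:
            raise ValueError("min_len_aa must be >= 1")


def _translate(cds: str) -> str:
    return str(Seq(cds).translate(table="Standard"))


def find_sorfs(transcript: Transcript, config: OrfConfig = OrfConfig()) -> list[SmallORF]:
    """Enumerate ATG-initiated ORFs in the three forward frames.

    A codon containing N is untranslatable and terminates extension of any
    open ORF in that frame without emitting it. Returned list is sorted by
    (start, end).
    """
    seq = transcript.sequence
    n = len(seq)
    found: list[SmallORF] = []
    for frame in range(3):
        open_starts: list[int] = []
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if "N" in codon:
                open_starts.clear()
            elif codon in STOP_CODONS:
                if open_starts:
                    starts = open_starts if config.report_nested_starts else open_starts[:1]
                    for s in starts:
                        _emit(found, seq, transcript.id, s, i + 3, frame, True, config)
                    open_starts.clear()
            elif codon == "ATG":
                open_starts.append(i)
            i += 3
        if open_starts and not config.require_stop:
            end = i  # last complete codon boundary in this frame
            starts = open_starts if config.report_nested_starts else open_starts[:1]
            for s in starts:
                _emit(found, seq, transcript.id, s, end, frame, False, config)
    found.sort(key=lambda o: (o.start, o.end))
    return found


def _emit(
    out: list[SmallORF],
    seq: str,
    tid: str,
    start: int,
    end: int,
    frame: int,
    has_stop: bool,
    config: OrfConfig,
) -> None:
    n_codons = (end - start) // 3
    length_aa = n_codons - 1 if has_stop else n_codons
    if length_aa < config.min_len_aa:
        return
    cds_end = end - 3 if has_stop else end
    out.append(
        SmallORF(
            transcript_id=tid,
            start=start,
            end=end,
            frame=frame,
            protein_seq=_translate(seq[start:cds_end]),
            length_aa=length_aa,
            has_stop=has_stop,
        )
    )


def select_canonical_orf(orfs: Iterable[SmallORF]) -> SmallORF:
    """Longest ORF; ties broken by 5'-most start. Mirrors the convention
    of reporting one product per lncRNA."""
    orfs = list(orfs)
    if not orfs:
        raise ValueError("no ORF")
    return min(orfs, key=lambda o: (-o.length_aa, o.start))


def candidate_header(orf: SmallORF) -> str:
    return f"LEP|{orf.transcript_id}|{orf.start}-{orf.end}"


def write_candidate_db(orfs: Iterable[SmallORF], out: str | Path) -> int:
    """Write the candidate microprotein FASTA; returns the record count."""
    records = []
    seen: dict[str, int] = {}
    for orf in orfs:
        header = candidate_header(orf)
        seen[header] = seen.get(header, 0) + 1
        records.append(SeqRecord(Seq(orf.protein_seq), id=header, description=""))
    dupes = sorted(h for h, c in seen.items() if c > 1)
    if dupes:
        raise ValueError(f"duplicate candidate headers: {', '.join(dupes)}")
    count = SeqIO.write(records, str(out), "fasta")
    return count


def write_orf_table(orfs: Iterable[SmallORF], out: str | Path) -> int:
    """TSV report with 1-based closed coordinates."""
    rows = [
        "\t".join(
            (
                o.transcript_id,
                str(o.start + 1),
                str(o.end),
                str(o.frame),
                str(o.length_aa),
                o.protein_seq,
            )
        )
        for o in orfs
    ]
    header = "transcript_id\tstart_1based\tend_1based\tframe\tlength_aa\tprotein_seq"
    Path(out).write_text("\n".join([header, *rows]) + "\n")
    return len(rows)


def read_transcripts(path: str | Path) -> Iterator[Transcript]:
    """Read a (possibly wrapped) multi-FASTA of transcripts."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield Transcript(id=rec.id, sequence=str(rec.seq))
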