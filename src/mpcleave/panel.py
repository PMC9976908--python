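"""Reference panel of pri-miRNA hairpin substrates.

A panel record holds one in-vitro-transcribed pri-miRNA: the pre-miRNA
sequence embedded in its genomic flanks, with the ``GGG`` prefix that T7
transcription appends to the 5' end.  The annotated pre-miRNA boundaries
anchor the strand-local coordinate systems used everywhere downstream:

* 5p strand: offset 0 is the pre-miRNA 5' nucleotide (the canonical
  cleavage site CL0); positive offsets run toward the loop, negative
  offsets into the basal 5' flank.
* 3p strand: offset 0 is the pre-miRNA 3' nucleotide; positive offsets
  run toward the loop (upstream in transcript coordinates), negative
  offsets into the basal 3' flank (downstream in transcript coordinates).

``pre_end`` is 0-based and inclusive.  Sequences are stored as RNA
(uppercase, T transcribed to U on input).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GGG_PREFIX = "GGG"
#: flank lengths used when panels are built from genomic context
DEFAULT_FLANK5 = 30
DEFAULT_FLANK3 = 25

_RNA_OK = re.compile(r"^[ACGUN]*$")


class PanelError(ValueError):
    """Raised on invalid panel construction (duplicate ids, bad records)."""


def clean_rna(seq: str) -> str:
    """Uppercase and transcribe T->U; reject characters outside A/C/G/U/N."""
    s = seq.strip().upper().replace("T", "U")
    if not _RNA_OK.match(s):
        bad = sorted(set(s) - set("ACGUN"))
        raise PanelError(f"non-nucleotide characters in sequence: {bad}")
    return s


@dataclass(frozen=True)
class PriMiRNARecord:
    """One reference hairpin with annotated pre-miRNA boundaries."""

    id: str
    sequence: str
    pre_start: int
    pre_end: int  # inclusive
    is_spikein: bool = False
    species: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.pre_start < self.pre_end < len(self.sequence)):
            raise PanelError(
                f"{self.id}: pre-miRNA boundaries [{self.pre_start}, "
                f"{self.pre_end}] out of range for length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def pre_sequence(self) -> str:
        return self.sequence[self.pre_start : self.pre_end + 1]


@dataclass(frozen=True)
class StrandPosition:
    """A strand-local coordinate (see module docstring for conventions)."""

    strand: Literal["5p", "3p"]
    offset: int


def to_transcript(record: PriMiRNARecord, pos: StrandPosition) -> int:
    """Convert a strand-local position to a 0-based transcript coordinate.

    ``(5p, k) -> pre_start + k`` and ``(3p, k) -> pre_end - k``, so a
    negative 3p offset lands downstream of the pre-miRNA 3' end.
    """
    if pos.strand == "5p":
        coord = record.pre_start + pos.offset
    elif pos.strand == "3p":
        coord = record.pre_end - pos.offset
    else:
        raise ValueError(f"unknown strand {pos.strand!r}")
    if not 0 <= coord < len(record.sequence):
        raise IndexError(
            f"{record.id}: ({pos.strand}, {pos.offset:+d}) maps to transcript "
            f"coordinate {coord}, outside [0, {len(record.sequence)})"
        )
    return coord


def from_transcript(
    record: PriMiRNARecord, coord: int, strand: Literal["5p", "3p"]
) -> StrandPosition:
    """Inverse of :func:`to_transcript` for a given strand."""
    if not 0 <= coord < len(record.sequence):
        raise IndexError(f"{record.id}: transcript coordinate {coord} out of range")
    if strand == "5p":
        return StrandPosition("5p", coord - record.pre_start)
    return StrandPosition("3p", record.pre_end - coord)


def build_panel(
    entries: Iterable[tuple],
) -> list[PriMiRNARecord]:
    """Assemble panel records from (id, pre, flank5, flank3[, spikein[, species]]).

    Each record's sequence is ``GGG + flank5 + pre + flank3`` with the
    pre-miRNA boundaries set accordingly.  At most one entry may be the
    spike-in control species.
    """
    records: list[PriMiRNARecord] = []
    seen: set[str] = set()
    n_spike = 0
    for entry in entries:
        rid, pre, flank5, flank3 = entry[0], entry[1], entry[2], entry[3]
        spike = bool(entry[4]) if len(entry) > 4 else False
        species = entry[5] if len(entry) > 5 else None
        if rid in seen:
            raise PanelError(f"duplicate panel id {rid!r}")
        seen.add(rid)
        pre = clean_rna(pre)
        if not pre:
            raise PanelError(f"{rid}: empty pre-miRNA sequence")
        flank5 = clean_rna(flank5)
        flank3 = clean_rna(flank3)
        seq = GGG_PREFIX + flank5 + pre + flank3
        pre_start = len(GGG_PREFIX) + len(flank5)
        pre_end = pre_start + len(pre) - 1
        if spike:
            n_spike += 1
            if n_spike > 1:
                raise PanelError("panel may contain at most one spike-in record")
        records.append(
            PriMiRNARecord(rid, seq, pre_start, pre_end, spike, species)
        )
    return records


def spikein_record(panel: Sequence[PriMiRNARecord]) -> PriMiRNARecord | None:
    """Return the panel's spike-in record, or None."""
    hits = [r for r in panel if r.is_spikein]
    if len(hits) > 1:
        raise PanelError("panel contains more than one spike-in record")
    return hits[0] if hits else None


# ---------------------------------------------------------------------------
# FASTA + TSV sidecar round trip

def write_panel(panel: Sequence[PriMiRNARecord], fasta: str | Path, tsv: str | Path) -> None:
    fasta, tsv = Path(fasta), Path(tsv)
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in panel),
        str(fasta),
        "fasta",
    )
    with open(tsv, "w") as fh:
        fh.write("id\tpre_start\tpre_end\tis_spikein\tspecies\n")
        for r in panel:
            fh.write(
                f"{r.id}\t{r.pre_start}\t{r.pre_end}\t"
                f"{int(r.is_spikein)}\t{r.species or ''}\n"
            )


def read_panel(fasta: str | Path, tsv: str | Path) -> list[PriMiRNARecord]:
    meta: dict[str, tuple[int, int, bool, str | None]] = {}
    with open(tsv) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rid = parts[idx["id"]]
            meta[rid] = (
                int(parts[idx["pre_start"]]),
                int(parts[idx["pre_end"]]),
                bool(int(parts[idx["is_spikein"]])),
                parts[idx["species"]] or None if "species" in idx else None,
            )
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta), "fasta"):
        if rec.id in seen:
            raise PanelError(f"duplicate panel id {rec.id!r}")
        seen.add(rec.id)
        if rec.id not in meta:
            raise PanelError(f"{rec.id}: present in FASTA but missing from sidecar TSV")
        pre_start, pre_end, spike, species = meta[rec.id]
        records.append(
            PriMiRNARecord(rec.id, clean_rna(str(rec.seq)), pre_start, pre_end, spike, species)
        )
    if sum(r.is_spikein for r in records) > 1:
        raise PanelError("panel contains more than one spike-in record")
    return records
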