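"""Paired-end read processing for high-throughput cleavage libraries.

Raw paired-end FASTQ is converted into unique, barcode-stripped fragments
assigned to panel references through a fixed stage order:

    trim_adapters -> join_pair -> quality_filter -> collapse_duplicates
                  -> trim_barcodes -> map_fragment

Duplicate collapse runs *before* barcode trimming, so the randomized 4-nt
terminal barcodes distinguish independent ligation events that captured
identical fragments.

Mapping is plain local (Smith-Waterman style) alignment against every
panel reference on the plus strand, with a bowtie2-local-shaped default
scoring scheme; a read is kept only when its best score is strictly higher
than its best score on every other reference.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

from Bio import Align
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .panel import PriMiRNARecord

#: 3' adapter ligated to the product RNA (read-through target of mate 1)
ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
#: reverse complement of the 5' adapter (read-through target of mate 2)
ADAPTER5_RC = "GATCGTCGGACTGTAGAACTCTGAAC"

_COMP = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class ConfigError(ValueError):
    pass


@dataclass
class ReadPair:
    id: str
    seq1: str
    qual1: list[int]
    seq2: str
    qual2: list[int]


@dataclass
class ProcessedRead:
    id: str
    seq: str
    qual: list[int]
    barcode5: str = ""
    barcode3: str = ""


@dataclass(frozen=True)
class FragmentAlignment:
    read_id: str
    ref_id: str
    start: int  # 0-based, half-open [start, end) on the reference
    end: int
    score: float
    unique: bool
    n_mismatches: int


# ---------------------------------------------------------------------------
# adapter trimming


def _find_adapter(seq: str, adapter: str, min_overlap: int, max_error_rate: float) -> int | None:
    """Return the trim position of the best adapter occurrence, or None.

    The adapter may occur in full anywhere in the read (everything from the
    adapter on is removed), or as a prefix of length >= ``min_overlap`` at
    the read 3' end.  Substitutions only; best occurrence maximizes
    (matches - mismatches), ties broken toward the longest removal.
    """
    n, m = len(seq), len(adapter)
    best: tuple[int, int] | None = None  # (score, -p)
    best_p = None
    for p in range(n):
        overlap = min(m, n - p)
        if overlap < min_overlap:
            break
        mism = sum(1 for a, b in zip(seq[p : p + overlap], adapter) if a != b)
        if mism > max_error_rate * overlap:
            continue
        score = (overlap - mism) - mism
        key = (score, -p)
        if best is None or key > best:
            best, best_p = key, p
    return best_p


def trim_adapters(
    pair: ReadPair,
    adapter3: str = ADAPTER3,
    adapter5rc: str = ADAPTER5_RC,
    min_overlap: int = 3,
    max_error_rate: float = 0.1,
) -> ReadPair:
    """Remove read-through adapter sequence from the 3' end of each mate.

    Mate 1 runs into the 3' adapter, mate 2 into the reverse complement of
    the 5' adapter.  Reads without an acceptable occurrence are unchanged.
    """
    if not adapter3 or not adapter5rc:
        raise ConfigError("adapter sequences must be non-empty")
    out = []
    for seq, qual, adapter in (
        (pair.seq1, pair.qual1, adapter3.upper().replace("U", "T")),
        (pair.seq2, pair.qual2, adapter5rc.upper().replace("U", "T")),
    ):
        p = _find_adapter(seq.upper(), adapter, min_overlap, max_error_rate)
        if p is None:
            out.append((seq, qual))
        else:
            out.append((seq[:p], qual[:p]))
    return ReadPair(pair.id, out[0][0], out[0][1], out[1][0], out[1][1])


# ---------------------------------------------------------------------------
# pair joining


def join_pair(
    pair: ReadPair, max_mismatch_frac: float = 0.05, min_overlap: int = 6
) -> ProcessedRead | None:
    """Merge the two mates over their best 3'-end overlap.

    Mate 2 is reverse-complemented, then every overlap length from the
    longest possible down to ``min_overlap`` is scored; the merge with the
    lowest mismatch fraction (ties: longest overlap) is returned, provided
    that fraction is <= ``max_mismatch_frac``.  Disagreeing overlap bases
    take the base with the higher Phred score (mate 1 wins ties).
    Returns None when no acceptable overlap exists.
    """
    s1, q1 = pair.seq1.upper(), pair.qual1
    s2 = revcomp(pair.seq2).upper()
    q2 = pair.qual2[::-1]
    n1, n2 = len(s1), len(s2)
    best: tuple[float, int] | None = None  # (mismatch_frac, -overlap)
    best_o = None
    for o in range(min(n1, n2), min_overlap - 1, -1):
        mism = sum(1 for a, b in zip(s1[n1 - o :], s2[:o]) if a != b)
        frac = mism / o
        if frac > max_mismatch_frac:
            continue
        key = (frac, -o)
        if best is None or key < best:
            best, best_o = key, o
    if best_o is None:
        return None
    o = best_o
    merged_seq = list(s1[: n1 - o])
    merged_qual = list(q1[: n1 - o])
    for k in range(o):
        a, qa = s1[n1 - o + k], q1[n1 - o + k]
        b, qb = s2[k], q2[k]
        if a == b or qa >= qb:
            merged_seq.append(a)
        else:
            merged_seq.append(b)
        merged_qual.append(max(qa, qb))
    merged_seq.extend(s2[o:])
    merged_qual.extend(q2[o:])
    return ProcessedRead(pair.id, "".join(merged_seq), merged_qual)


# ---------------------------------------------------------------------------
# quality filter / duplicate collapse / barcode trimming


def quality_filter(read: ProcessedRead, q: int = 20, p: float = 90.0) -> bool:
    """True iff at least ``p`` percent of bases have Phred >= ``q``."""
    if not read.seq:
        return False
    n_ok = sum(1 for x in read.qual if x >= q)
    return n_ok * 100.0 >= p * len(read.qual)


def collapse_duplicates(reads: Iterable[ProcessedRead]) -> list[ProcessedRead]:
    """Keep the first occurrence of each distinct sequence string."""
    seen: set[str] = set()
    out = []
    for r in reads:
        if r.seq not in seen:
            seen.add(r.seq)
            out.append(r)
    return out


def trim_barcodes(read: ProcessedRead, n5: int, n3: int) -> ProcessedRead | None:
    """Strip the randomized terminal barcodes; None if the read is too short."""
    if len(read.seq) <= n5 + n3:
        return None
    end = len(read.seq) - n3 if n3 else len(read.seq)
    return ProcessedRead(
        read.id,
        read.seq[n5:end],
        read.qual[n5:end],
        barcode5=read.seq[:n5],
        barcode3=read.seq[end:],
    )


# ---------------------------------------------------------------------------
# mapping


@dataclass(frozen=True)
class AlignScoring:
    """Local-alignment scoring; a length-k gap costs ``gap_open + k*gap_extend``."""

    match: float = 2.0
    mismatch: float = -6.0
    gap_open: float = -5.0
    gap_extend: float = -3.0

    def min_score(self, read_len: int) -> float:
        # bowtie2 --local default shape
        return 20.0 + 8.0 * math.log(max(read_len, 1))


class PanelMapper:
    """Maps processed reads against a small reference panel.

    Exact substring matches short-circuit the aligner (an exact full-length
    hit attains the maximum possible local score, so uniqueness reduces to
    substring membership); everything else runs through a local pairwise
    aligner against every reference.
    """

    def __init__(self, panel: Sequence[PriMiRNARecord], scoring: AlignScoring | None = None):
        self.panel = list(panel)
        self.scoring = scoring or AlignScoring()
        self._aligner = Align.PairwiseAligner()
        self._aligner.mode = "local"
        self._aligner.match_score = self.scoring.match
        self._aligner.mismatch_score = self.scoring.mismatch
        # Biopython charges open_gap_score for the first gap position
        self._aligner.open_gap_score = self.scoring.gap_open + self.scoring.gap_extend
        self._aligner.extend_gap_score = self.scoring.gap_extend

    def map(self, read: ProcessedRead) -> tuple[str, FragmentAlignment | None]:
        """Return (status, alignment); status in {mapped, unmapped, multimapped}."""
        seq = read.seq.upper().replace("T", "U")
        L = len(seq)
        if L == 0:
            return "unmapped", None
        hits = [r for r in self.panel if seq in r.sequence]
        if len(hits) == 1:
            ref = hits[0]
            start = ref.sequence.index(seq)
            return "mapped", FragmentAlignment(
                read.id, ref.id, start, start + L, self.scoring.match * L, True, 0
            )
        if len(hits) > 1:
            return "multimapped", None

        scores = [self._aligner.score(r.sequence, seq) for r in self.panel]
        order = sorted(range(len(scores)), key=lambda i: -scores[i])
        best = order[0]
        if scores[best] < self.scoring.min_score(L):
            return "unmapped", None
        if len(order) > 1 and scores[order[1]] == scores[best]:
            return "multimapped", None
        ref = self.panel[best]
        aln = self._aligner.align(ref.sequence, seq)[0]
        blocks_ref, blocks_read = aln.aligned
        n_mm = 0
        for (rs, re_), (qs, qe) in zip(blocks_ref, blocks_read):
            n_mm += sum(
                1 for a, b in zip(ref.sequence[rs:re_], seq[qs:qe]) if a != b
            )
        return "mapped", FragmentAlignment(
            read.id,
            ref.id,
            int(blocks_ref[0][0]),
            int(blocks_ref[-1][1]),
            float(scores[best]),
            True,
            n_mm,
        )


def map_fragment(
    read: ProcessedRead,
    panel: Sequence[PriMiRNARecord],
    scoring: AlignScoring | None = None,
) -> tuple[str, FragmentAlignment | None]:
    """One-shot wrapper around :class:`PanelMapper` for a single read."""
    return PanelMapper(panel, scoring).map(read)


# ---------------------------------------------------------------------------
# FASTQ I/O and the full pipeline


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq_pairs(r1: str | Path, r2: str | Path) -> Iterator[ReadPair]:
    with _open_text(r1) as f1, _open_text(r2) as f2:
        for (id1, s1, q1), (id2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2), strict=True
        ):
            yield ReadPair(
                id1.split()[0],
                s1,
                [ord(c) - 33 for c in q1],
                s2,
                [ord(c) - 33 for c in q2],
            )


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, str]]) -> None:
    """Write (id, seq, qual-string) triples as Phred+33 FASTQ."""
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


#: barcode lengths per sample type: product reads carry 4 nt at both ends,
#: control reads carry 4 nt at the 5' end and 6 nt at the 3' end
BARCODE_SCHEME = {"product": (4, 4), "control": (4, 6)}


@dataclass
class PipelineConfig:
    adapter3: str = ADAPTER3
    adapter5rc: str = ADAPTER5_RC
    adapter_min_overlap: int = 3
    adapter_max_error_rate: float = 0.1
    join_max_mismatch_frac: float = 0.05
    join_min_overlap: int = 6
    quality_q: int = 20
    quality_p: float = 90.0
    scoring: AlignScoring = field(default_factory=AlignScoring)


def process_read_pairs(
    pairs: Iterable[ReadPair],
    panel: Sequence[PriMiRNARecord],
    sample_type: Literal["product", "control"],
    config: PipelineConfig | None = None,
) -> tuple[list[FragmentAlignment], dict[str, int]]:
    """Run the full stage chain, returning unique alignments and attrition counts."""
    cfg = config or PipelineConfig()
    if sample_type not in BARCODE_SCHEME:
        raise ConfigError(f"sample_type must be product or control, got {sample_type!r}")
    n5, n3 = BARCODE_SCHEME[sample_type]

    stats = {
        "total_pairs": 0,
        "joined": 0,
        "quality_passed": 0,
        "unique_sequences": 0,
        "barcode_trimmed": 0,
        "mapped_unique": 0,
        "multimapped": 0,
        "unmapped": 0,
    }
    joined: list[ProcessedRead] = []
    for pair in pairs:
        stats["total_pairs"] += 1
        pair = trim_adapters(
            pair,
            cfg.adapter3,
            cfg.adapter5rc,
            cfg.adapter_min_overlap,
            cfg.adapter_max_error_rate,
        )
        merged = join_pair(pair, cfg.join_max_mismatch_frac, cfg.join_min_overlap)
        if merged is None:
            continue
        stats["joined"] += 1
        if not quality_filter(merged, cfg.quality_q, cfg.quality_p):
            continue
        stats["quality_passed"] += 1
        joined.append(merged)

    collapsed = collapse_duplicates(joined)
    stats["unique_sequences"] = len(collapsed)

    trimmed: list[ProcessedRead] = []
    for r in collapsed:
        t = trim_barcodes(r, n5, n3)
        if t is not None:
            trimmed.append(t)
    stats["barcode_trimmed"] = len(trimmed)

    mapper = PanelMapper(panel, cfg.scoring)
    alignments: list[FragmentAlignment] = []
    for r in trimmed:
        status, aln = mapper.map(r)
        if status == "mapped":
            stats["mapped_unique"] += 1
            alignments.append(aln)
        elif status == "multimapped":
            stats["multimapped"] += 1
        else:
            stats["unmapped"] += 1
    return alignments, stats


def write_alignments_tsv(path: str | Path, alignments: Iterable[FragmentAlignment]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tref_id\tstart\tend\tscore\tmismatches\n")
        for a in alignments:
            fh.write(f"{a.read_id}\t{a.ref_id}\t{a.start}\t{a.end}\t{a.score:g}\t{a.n_mismatches}\n")


def read_alignments_tsv(path: str | Path) -> list[FragmentAlignment]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            rid, ref, start, end, score, mm = line.rstrip("\n").split("\t")
            out.append(FragmentAlignment(rid, ref, int(start), int(end), float(score), True, int(mm)))
    return out
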