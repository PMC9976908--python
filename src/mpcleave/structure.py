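"""Hairpin structure annotation: junctions, stem lengths, motif classes.

Structures are consumed as Vienna dot-bracket strings (e.g. RNAfold
output) or as designed pair tables; this module never folds RNA itself.

Junctions are called on the 5p strand in CL coordinates (offset 0 = the
pre-miRNA 5' end):

* basal junction (bJC): scanning outward from CL0, the first unpaired
  offset that opens a run of >= 3 consecutive unpaired positions, accepted
  only within [-25, -10];
* apical junction (aJC): scanning loopward, the first unpaired offset
  opening a >= 3 run, accepted only within [+21, +30].

Stem lengths are the number of *paired* 5p positions between the cleavage
site and the junction, so bulged positions do not count as base pairs:
a perfect N-bp lower stem has bJC = -(N+1) and lower_stem_bp = N.

Motif windows (5p offsets unless stated): UG at [-14, -12]; UGU/GUG
starting in [+21, +24] (trinucleotide inside [+21, +26]); CNNC with its
first C at 3p offsets [-21, -16]; midBMW = unpaired or G:U wobble at any
of +10..+12; mGHG scored on the 3p [-5, -3] triplet against an externally
supplied matrix, flagged when the score exceeds 38.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .panel import PriMiRNARecord

BJC_WINDOW = (-25, -10)
AJC_WINDOW = (21, 30)
MIN_SS_RUN = 3
MGHG_THRESHOLD = 38.0


class StructureError(ValueError):
    pass


@dataclass
class PairTable:
    """Nested base-pairing of one transcript; ``partners[i]`` is the paired
    coordinate or None."""

    partners: list[int | None]
    source: str = "supplied"  # designed | external-folded | supplied

    def __post_init__(self) -> None:
        for i, j in enumerate(self.partners):
            if j is not None and (not 0 <= j < len(self.partners) or self.partners[j] != i):
                raise StructureError(f"pair table not symmetric at position {i}")

    def __len__(self) -> int:
        return len(self.partners)

    def partner(self, i: int) -> int | None:
        return self.partners[i]

    def is_paired(self, i: int) -> bool:
        return self.partners[i] is not None


def parse_dotbracket(structure: str, sequence: str | None = None) -> PairTable:
    """Parse a Vienna dot-bracket string into a pair table."""
    if sequence is not None and len(sequence) != len(structure):
        raise StructureError(
            f"structure length {len(structure)} != sequence length {len(sequence)}"
        )
    partners: list[int | None] = [None] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            partners[i], partners[j] = j, i
        elif c != ".":
            raise StructureError(f"illegal character {c!r} at position {i}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return PairTable(partners)


def to_dotbracket(pt: PairTable) -> str:
    return "".join(
        "." if j is None else ("(" if j > i else ")") for i, j in enumerate(pt.partners)
    )


def is_multiloop(pt: PairTable) -> bool:
    """True iff the structure closes more than one hairpin loop."""
    n_loops = 0
    for i, j in enumerate(pt.partners):
        if j is not None and j > i:
            if all(pt.partners[k] is None for k in range(i + 1, j)):
                n_loops += 1
    return n_loops > 1


@dataclass
class MotifFlags:
    ug: bool | None = None
    ugu_gug: bool | None = None
    cnnc: bool | None = None
    midbmw: bool | None = None
    mghg_score: float | None = None
    mghg: bool | None = None


@dataclass
class StructureAnnotation:
    ref_id: str
    multiloop: bool
    bJC: int | None
    aJC: int | None
    lower_stem_bp: int | None
    upper_stem_bp: int | None
    motifs: MotifFlags = field(default_factory=MotifFlags)


def _unpaired5(pt: PairTable, record: PriMiRNARecord, offset: int) -> bool:
    """Unpaired test at a 5p offset; coordinates beyond the transcript count
    as single-stranded."""
    coord = record.pre_start + offset
    if not 0 <= coord < len(pt):
        return True
    return not pt.is_paired(coord)


def call_junctions(pt: PairTable, record: PriMiRNARecord) -> tuple[int | None, int | None]:
    """Locate (bJC, aJC); either may be None if no qualifying run starts in
    its acceptance window.  The >= 3 single-stranded run must start inside
    the window but may extend beyond it."""
    bjc = None
    for off in range(-1, BJC_WINDOW[0] - 1, -1):
        if all(_unpaired5(pt, record, off - k) for k in range(MIN_SS_RUN)):
            if BJC_WINDOW[0] <= off <= BJC_WINDOW[1]:
                bjc = off
            break
    ajc = None
    for off in range(1, AJC_WINDOW[1] + 1):
        if all(_unpaired5(pt, record, off + k) for k in range(MIN_SS_RUN)):
            if AJC_WINDOW[0] <= off <= AJC_WINDOW[1]:
                ajc = off
            break
    return bjc, ajc


def stem_lengths(
    pt: PairTable, junctions: tuple[int | None, int | None], record: PriMiRNARecord
) -> tuple[int | None, int | None]:
    """Base-paired lengths of the lower and upper stems (bulges skipped)."""
    bjc, ajc = junctions
    lower = None
    if bjc is not None:
        lower = sum(
            1 for off in range(bjc + 1, 0) if not _unpaired5(pt, record, off)
        )
    upper = None
    if ajc is not None:
        upper = sum(
            1 for off in range(0, ajc) if not _unpaired5(pt, record, off)
        )
    return lower, upper


def mismatch_profile(
    entries: Iterable[tuple[PriMiRNARecord, PairTable]],
    offsets: Sequence[int] = tuple(range(-25, 31)),
) -> dict[int, float]:
    """Per 5p offset, the fraction of records whose position is unpaired.

    Only offsets that fall inside a record's transcript contribute to its
    denominator; an empty input gives an empty mapping.
    """
    num = {o: 0 for o in offsets}
    den = {o: 0 for o in offsets}
    for record, pt in entries:
        for o in offsets:
            coord = record.pre_start + o
            if 0 <= coord < len(pt):
                den[o] += 1
                if not pt.is_paired(coord):
                    num[o] += 1
    return {o: num[o] / den[o] for o in offsets if den[o] > 0}


# ---------------------------------------------------------------------------
# motif scanning

_WOBBLE = {("G", "U"), ("U", "G")}


def _coord5(record: PriMiRNARecord, offset: int) -> int:
    return record.pre_start + offset


def _coord3(record: PriMiRNARecord, offset: int) -> int:
    return record.pre_end - offset


def read_mghg_matrix(path: str | Path) -> dict[str, float]:
    """Read a triplet -> score TSV (header optional)."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.strip().split("\t")
            if len(parts) != 2 or not parts[0]:
                continue
            try:
                out[parts[0].upper().replace("T", "U")] = float(parts[1])
            except ValueError:
                continue  # header line
    if not out:
        raise StructureError(f"no triplet scores found in {path}")
    return out


def _mghg_window_bulged(pt: PairTable, record: PriMiRNARecord) -> bool:
    """Bulge test for the 3p [-5, -3] window.

    A bulge shifts the pairing register, so the window is bulged when two
    paired window positions have partners that are not anti-diagonal, or
    when an unpaired window position faces (by register interpolation) a
    5p position that is itself paired elsewhere.  Symmetric mismatches
    (both strands unpaired) are not bulges and stay scoreable; a window
    with no paired position at all carries no register evidence and is
    treated as mismatched, not bulged.
    """
    w3 = [c for c in (_coord3(record, o) for o in (-5, -4, -3)) if 0 <= c < len(pt)]
    paired = [(c, pt.partner(c)) for c in w3 if pt.partner(c) is not None]
    for (c1, j1), (c2, j2) in zip(paired, paired[1:]):
        if (c2 - c1) != (j1 - j2):
            return True
    if paired:
        c0, j0 = paired[0]
        for c in w3:
            if pt.partner(c) is not None:
                continue
            opp = j0 - (c - c0)
            if 0 <= opp < len(pt) and pt.partner(opp) is not None:
                return True
    return False


def scan_motifs(
    record: PriMiRNARecord,
    pt: PairTable,
    mghg_matrix: Mapping[str, float] | None = None,
    mghg_threshold: float = MGHG_THRESHOLD,
) -> MotifFlags:
    """Flag the five motif classes; a motif whose window leaves the
    transcript is reported as None (undefined) rather than absent."""
    seq = record.sequence
    flags = MotifFlags()

    def window_ok(coords: list[int]) -> bool:
        return all(0 <= c < len(seq) for c in coords)

    # UG dinucleotide, 5p offsets -14..-12
    coords = [_coord5(record, o) for o in range(-14, -11)]
    if window_ok(coords + [coords[-1] + 1]):
        flags.ug = any(seq[c : c + 2] == "UG" for c in coords)

    # UGU/GUG trinucleotide inside 5p +21..+26
    coords = [_coord5(record, o) for o in range(21, 25)]
    if window_ok(coords + [coords[-1] + 2]):
        flags.ugu_gug = any(seq[c : c + 3] in ("UGU", "GUG") for c in coords)

    # CNNC with first (5'-most) C at 3p offsets -21..-16
    coords = [_coord3(record, o) for o in range(-21, -15)]
    if window_ok(coords + [max(coords) + 3]):
        flags.cnnc = any(seq[c] == "C" and seq[c + 3] == "C" for c in coords)

    # midBMW: unpaired or wobble at any 5p offset +10..+12
    coords = [_coord5(record, o) for o in (10, 11, 12)]
    if window_ok(coords):
        hit = False
        for c in coords:
            j = pt.partner(c)
            if j is None:
                hit = True
            elif (seq[c], seq[j]) in _WOBBLE:
                hit = True
        flags.midbmw = hit

    # mGHG: 3p -5..-3 triplet scored against the supplied matrix
    coords = [_coord3(record, o) for o in (-5, -4, -3)]
    if mghg_matrix is not None and window_ok(coords):
        if not _mghg_window_bulged(pt, record):
            triplet = "".join(seq[c] for c in sorted(coords))
            score = mghg_matrix.get(triplet)
            if score is not None:
                flags.mghg_score = score
                flags.mghg = score > mghg_threshold
    return flags


def annotate_record(
    record: PriMiRNARecord,
    pt: PairTable,
    mghg_matrix: Mapping[str, float] | None = None,
) -> StructureAnnotation:
    """Full annotation of one hairpin: loop count, junctions, stems, motifs."""
    multi = is_multiloop(pt)
    junctions = call_junctions(pt, record)
    lower, upper = stem_lengths(pt, junctions, record)
    motifs = scan_motifs(record, pt, mghg_matrix)
    return StructureAnnotation(record.id, multi, junctions[0], junctions[1], lower, upper, motifs)


def species_summary(
    annotated: Iterable[tuple[PriMiRNARecord, StructureAnnotation]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species motif percentages and stem-length distributions.

    Multi-loop records are excluded; each motif percentage is taken over
    the records where that motif is defined.  Returns (motif table,
    stem-length long table with one row per species x stem x length).
    """
    by_species: dict[str, list[StructureAnnotation]] = {}
    for record, ann in annotated:
        if ann.multiloop:
            continue
        by_species.setdefault(record.species or "unknown", []).append(ann)

    motif_rows = []
    stem_rows = []
    for species in sorted(by_species):
        anns = by_species[species]
        row: dict = {"species": species, "n": len(anns)}
        for name in ("ug", "ugu_gug", "cnnc", "mghg", "midbmw"):
            vals = [getattr(a.motifs, name) for a in anns]
            defined = [v for v in vals if v is not None]
            row[f"pct_{name}"] = (
                100.0 * sum(defined) / len(defined) if defined else float("nan")
            )
        motif_rows.append(row)
        for stem_attr, stem_name in (("lower_stem_bp", "lower"), ("upper_stem_bp", "upper")):
            counts: dict[int, int] = {}
            for a in anns:
                v = getattr(a, stem_attr)
                if v is not None:
                    counts[v] = counts.get(v, 0) + 1
            total = sum(counts.values())
            for length in sorted(counts):
                stem_rows.append(
                    {
                        "species": species,
                        "stem": stem_name,
                        "length_bp": length,
                        "count": counts[length],
                        "percent": 100.0 * counts[length] / total,
                    }
                )
    return pd.DataFrame(motif_rows), pd.DataFrame(stem_rows)


# ---------------------------------------------------------------------------
# Vienna-format I/O (">id\nsequence\nstructure" records)


def read_vienna(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, dot-bracket) from a Vienna-format file."""
    with open(path) as fh:
        rid = None
        seq = None
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                rid, seq = line[1:].split()[0], None
            elif seq is None:
                seq = line
            else:
                # RNAfold appends the MFE in parentheses after the structure
                struct = line.split(" ")[0]
                if rid is None:
                    raise StructureError("structure line before any header")
                yield rid, seq, struct
                rid, seq = None, None


def write_vienna(path: str | Path, records: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq, struct in records:
            fh.write(f">{rid}\n{seq}\n{struct}\n")


def annotation_table(annotations: Sequence[StructureAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        rows.append(
            {
                "ref_id": a.ref_id,
                "multiloop": a.multiloop,
                "bJC": a.bJC,
                "aJC": a.aJC,
                "lower_stem_bp": a.lower_stem_bp,
                "upper_stem_bp": a.upper_stem_bp,
                "UG": a.motifs.ug,
                "UGU_GUG": a.motifs.ugu_gug,
                "CNNC": a.motifs.cnnc,
                "midBMW": a.motifs.midbmw,
                "mGHG_score": a.motifs.mghg_score,
                "mGHG": a.motifs.mghg,
            }
        )
    return pd.DataFrame(rows)
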