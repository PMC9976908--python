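"""Ground-truth hairpin panels and simulated cleavage libraries.

The generator emulates the in-vitro cleavage experiment end to end:
designed pri-miRNA hairpins (known pairing, no folding involved), a
two-ruler cleavage model (an enzyme that measures a fixed number of base
pairs from the basal junction, one that measures from the apical
junction, or a mixture of the two), RNase-III-style 3' overhangs, a
fixed-count spike-in species, randomized terminal barcodes, ligated
adapters, and uniform per-base substitution errors.  Every ground truth
is recorded so that the analysis modules can be tested for parameter
recovery without any external data.

Designed geometry (5' to 3'): GGG prefix, single-stranded 5' flank,
lower-stem 5p arm, upper-stem 5p arm (CL0 = its first nucleotide), loop,
upper-stem 3p arm, lower-stem 3p arm, single-stranded 3' flank.  The
annotated pre-miRNA 3' end carries the configured overhang (2 nt by
default) past the partner of CL0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

from .panel import PriMiRNARecord, build_panel
from .reads import ADAPTER3, ADAPTER5_RC, revcomp
from .structure import PairTable, call_junctions

_RNA = "ACGU"
_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}

#: fixed 61-nt internal-control (spike-in) product; an arbitrary sequence
#: standing in for the cloning-control RNA, not any natural pre-miRNA
SPIKE_SEQ = (
    "GAUCCUAGGUCACGUAAGGCUUCAGCUAAUCGGAUACGUCCAAGGUCGAAUGCCAUGGAUC"
)
SPIKE_ID = "spikein-control"

#: default cleavage accuracy kernel: dominant site plus minor alternative
#: cleavages 1-2 nt away, mimicking multi-site cleavage around the mode
DEFAULT_KERNEL = {-2: 0.05, -1: 0.15, 0: 0.60, 1: 0.15, 2: 0.05}

_FILLER = "AUCUCGUAUGCCGUCUUCUGCUUGA".replace("U", "T") * 12


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class HairpinDesign:
    """Parameters of one designed hairpin substrate.

    Flank lengths are the single-stranded segments outside the stem; with
    the default 16-bp lower stem they reproduce the 30-nt upstream / 25-nt
    downstream genomic extensions of the reference construct design.
    """

    id: str
    lower_stem_bp: int = 16
    upper_stem_bp: int = 25
    loop_nt: int = 10
    flank5_nt: int = 14
    flank3_nt: int = 11
    planted_mismatch_offsets: tuple[int, ...] = ()
    planted_wobble_offsets: tuple[int, ...] = ()
    seed: int = 0


@dataclass(frozen=True)
class CleavageModel:
    """Two-ruler cleavage model with a positional accuracy kernel."""

    mode: Literal["basal_ruler", "apical_ruler", "mixture"] = "basal_ruler"
    basal_distance_bp: int = 16
    apical_distance_bp: int = 25
    accuracy_kernel: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_KERNEL)
    )
    overhang_nt: int = 2
    mixture_weight: float = 0.5  # probability of the apical-ruler centre

    def __post_init__(self) -> None:
        total = sum(self.accuracy_kernel.values())
        if abs(total - 1.0) > 1e-9:
            raise DesignError(f"accuracy kernel sums to {total}, not 1")
        if not 0.0 <= self.mixture_weight <= 1.0:
            raise DesignError("mixture_weight must be a fraction")


@dataclass(frozen=True)
class LibraryConfig:
    depth_per_ref: int = 2000
    spikein_reads: int = 50
    error_rate: float = 0.0
    barcode5_len: int = 4
    barcode3_len: int = 4
    adapter3: str = ADAPTER3
    adapter5rc: str = ADAPTER5_RC
    read_len: int = 150
    seed: int = 0


@dataclass(frozen=True)
class SimFragment:
    """One cleaved product: half-open transcript interval plus its truth."""

    ref_id: str
    start: int
    end: int
    cl5: int  # 5' cut offset relative to CL0


@dataclass
class RefTruth:
    planted_accuracy: dict[int, float]
    planted_mcl: int
    planted_overhang: int
    centers: list[int]
    emitted_counts: dict[int, int]


@dataclass
class SimTruth:
    refs: dict[str, RefTruth]
    spikein_reads: int
    seed: int


# ---------------------------------------------------------------------------
# hairpin design


def design_hairpin(
    design: HairpinDesign, overhang_nt: int = 2
) -> tuple[PriMiRNARecord, PairTable]:
    """Build a designed hairpin record and its ground-truth pair table.

    The 3p arm is the reverse complement of the 5p arm except at planted
    mismatch offsets (forced non-complementary, non-wobble base, unpaired
    in the truth table) and wobble offsets (G:U pair, still paired).
    Deterministic in ``design.seed``.
    """
    lo, up = design.lower_stem_bp, design.upper_stem_bp
    stem = lo + up
    if design.loop_nt < 4:
        raise DesignError("terminal loop must be at least 4 nt")
    if design.flank5_nt < 3 or design.flank3_nt < 3:
        raise DesignError("single-stranded flanks must be at least 3 nt")
    if lo < 1 or up < 1:
        raise DesignError("stem segments must be at least 1 bp")
    if lo < overhang_nt + 1:
        raise DesignError("lower stem too short to carry the 3' overhang")
    offsets_ok = range(-lo, up)
    for o in tuple(design.planted_mismatch_offsets) + tuple(design.planted_wobble_offsets):
        if o not in offsets_ok:
            raise DesignError(f"planted offset {o:+d} outside the designed stem")
    if set(design.planted_mismatch_offsets) & set(design.planted_wobble_offsets):
        raise DesignError("an offset cannot be both mismatch and wobble")

    rng = np.random.default_rng(design.seed)

    def rand(n: int) -> list[str]:
        return [_RNA[i] for i in rng.integers(0, 4, n)]

    arm5 = rand(stem)
    # wobble positions need a G or U on the 5p strand
    for o in design.planted_wobble_offsets:
        a = o + lo
        arm5[a] = "G" if rng.integers(0, 2) else "U"
    arm3 = [""] * stem
    for a in range(stem):
        o = a - lo
        comp = _COMPLEMENT[arm5[a]]
        j = stem - 1 - a  # mirrored index within the 3p arm
        if o in design.planted_mismatch_offsets:
            banned = {comp}
            if arm5[a] == "G":
                banned.add("U")
            elif arm5[a] == "U":
                banned.add("G")
            choices = [b for b in _RNA if b not in banned]
            arm3[j] = choices[rng.integers(0, len(choices))]
        elif o in design.planted_wobble_offsets:
            arm3[j] = "U" if arm5[a] == "G" else "G"
        else:
            arm3[j] = comp

    flank5 = "".join(rand(design.flank5_nt))
    flank3 = "".join(rand(design.flank3_nt))
    loop = "".join(rand(design.loop_nt))
    seq = "GGG" + flank5 + "".join(arm5) + loop + "".join(arm3) + flank3

    s = 3 + design.flank5_nt  # first 5p stem coordinate
    loop_end = s + stem + design.loop_nt  # first 3p stem coordinate
    partners: list[int | None] = [None] * len(seq)
    for a in range(stem):
        o = a - lo
        if o in design.planted_mismatch_offsets:
            continue
        i, j = s + a, loop_end + stem - 1 - a
        partners[i], partners[j] = j, i

    pre_start = s + lo
    pre_end = (loop_end + up - 1) + overhang_nt  # partner of CL0 + overhang
    record = PriMiRNARecord(design.id, seq, pre_start, pre_end)
    return record, PairTable(partners, source="designed")


# ---------------------------------------------------------------------------
# cleavage simulation


def _paired_offsets(pt: PairTable, record: PriMiRNARecord, lo: int, hi: int) -> list[int]:
    out = []
    for off in range(lo, hi):
        c = record.pre_start + off
        if 0 <= c < len(pt) and pt.is_paired(c):
            out.append(off)
    return out


def ruler_centers(
    record: PriMiRNARecord, pt: PairTable, model: CleavageModel
) -> list[int]:
    """Centre CL offsets implied by the model's ruler(s).

    The basal centre sits ``basal_distance_bp`` paired positions above the
    basal junction; the apical centre sits ``apical_distance_bp`` paired
    positions below the apical junction.  Bulged positions are skipped by
    both rulers.
    """
    bjc, ajc = call_junctions(pt, record)
    centers: list[int] = []

    def basal() -> int:
        if bjc is None:
            raise DesignError(f"{record.id}: no basal junction; basal ruler undefined")
        cnt = 0
        for off in range(bjc + 1, bjc + 1 + 80):
            if cnt == model.basal_distance_bp:
                return off
            c = record.pre_start + off
            if 0 <= c < len(pt) and pt.is_paired(c):
                cnt += 1
        raise DesignError(f"{record.id}: stem shorter than the basal ruler")

    def apical() -> int:
        if ajc is None:
            raise DesignError(f"{record.id}: no apical junction; apical ruler undefined")
        cnt = 0
        for off in range(ajc - 1, ajc - 1 - 80, -1):
            c = record.pre_start + off
            if 0 <= c < len(pt) and pt.is_paired(c):
                cnt += 1
            if cnt == model.apical_distance_bp:
                return off
        raise DesignError(f"{record.id}: stem shorter than the apical ruler")

    if model.mode == "basal_ruler":
        centers.append(basal())
    elif model.mode == "apical_ruler":
        centers.append(apical())
    elif model.mode == "mixture":
        centers.extend([basal(), apical()])
    else:
        raise DesignError(f"unknown model mode {model.mode!r}")
    return centers


def _project_3p_end(pt: PairTable, coord5: int, overhang: int) -> int:
    """Blunt-projected partner of the 5' cut, plus the overhang (inclusive)."""
    for d in range(6):
        c = coord5 + d
        if c < len(pt) and pt.partner(c) is not None and pt.partner(c) > c:
            return pt.partner(c) + d + overhang
    raise DesignError(f"no paired anchor within 5 nt of coordinate {coord5}")


def planted_accuracy(
    record: PriMiRNARecord, pt: PairTable, model: CleavageModel
) -> dict[int, float]:
    """Theoretical cleavage distribution over CL-5..CL5 implied by the model,
    renormalized over the window."""
    centers = ruler_centers(record, pt, model)
    if model.mode == "mixture":
        weights = [1.0 - model.mixture_weight, model.mixture_weight]
    else:
        weights = [1.0]
    dist = {p: 0.0 for p in range(-5, 6)}
    for center, w in zip(centers, weights):
        for k, prob in model.accuracy_kernel.items():
            p = center + k
            if -5 <= p <= 5:
                dist[p] += w * prob
    total = sum(dist.values())
    if total <= 0:
        raise DesignError(f"{record.id}: planted distribution has no mass in CL-5..CL5")
    return {p: v / total for p, v in dist.items()}


def simulate_products(
    record: PriMiRNARecord,
    pt: PairTable,
    model: CleavageModel,
    n: int,
    seed: int,
) -> tuple[list[SimFragment], RefTruth]:
    """Draw ``n`` cleaved fragments from the model.

    Each fragment's 5' cut is a kernel draw around the ruler-determined
    centre (mixture mode first picks a centre); its 3' cut is the
    projected partner of the 5' cut plus the overhang.
    """
    rng = np.random.default_rng(seed)
    centers = ruler_centers(record, pt, model)
    kernel_offsets = sorted(model.accuracy_kernel)
    kernel_probs = np.array([model.accuracy_kernel[k] for k in kernel_offsets])
    kernel_probs = kernel_probs / kernel_probs.sum()

    fragments: list[SimFragment] = []
    emitted: dict[int, int] = {}
    for _ in range(n):
        if model.mode == "mixture":
            center = centers[1] if rng.random() < model.mixture_weight else centers[0]
        else:
            center = centers[0]
        k = kernel_offsets[rng.choice(len(kernel_offsets), p=kernel_probs)]
        cl5 = center + k
        coord5 = record.pre_start + cl5
        coord3 = _project_3p_end(pt, coord5, model.overhang_nt)
        fragments.append(SimFragment(record.id, coord5, coord3 + 1, cl5))
        emitted[cl5] = emitted.get(cl5, 0) + 1

    acc = planted_accuracy(record, pt, model)
    mcl = min((p for p, v in acc.items() if v == max(acc.values())), key=lambda p: (abs(p), p))
    truth = RefTruth(acc, mcl, model.overhang_nt, centers, dict(sorted(emitted.items())))
    return fragments, truth


# ---------------------------------------------------------------------------
# library emission


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def emit_library(
    fragments: Sequence[SimFragment],
    config: LibraryConfig,
    panel: Sequence[PriMiRNARecord],
    barcode_lens: tuple[int, int] | None = None,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]]]:
    """Turn fragments into paired reads (id, sequence, quality) for R1/R2.

    Layout per molecule: 5' barcode + fragment + 3' barcode, with the 3'
    adapter downstream of mate 1 and the reverse-complemented 5' adapter
    downstream of mate 2.  Substitution errors are applied independently
    per mate.  Deterministic in ``config.seed``.
    """
    # separate streams so the error process does not perturb barcode draws
    rng = np.random.default_rng([config.seed, 0])
    rng_err = np.random.default_rng([config.seed, 1])
    by_id = {r.id: r for r in panel}
    n5, n3 = barcode_lens if barcode_lens is not None else (
        config.barcode5_len,
        config.barcode3_len,
    )
    qual_char = chr(33 + 37)
    r1_reads: list[tuple[str, str, str]] = []
    r2_reads: list[tuple[str, str, str]] = []
    for idx, frag in enumerate(fragments):
        record = by_id[frag.ref_id]
        if not 0 <= frag.start < frag.end <= len(record.sequence):
            raise DesignError(f"fragment interval out of range for {frag.ref_id}")
        frag_dna = record.sequence[frag.start : frag.end].replace("U", "T")
        b5 = "".join("ACGT"[i] for i in rng.integers(0, 4, n5))
        b3 = "".join("ACGT"[i] for i in rng.integers(0, 4, n3))
        insert = b5 + frag_dna + b3
        if len(insert) < 6:
            raise DesignError("insert shorter than the minimum join overlap")
        r1 = (insert + config.adapter3 + _FILLER)[: config.read_len]
        r2 = (revcomp(insert) + config.adapter5rc + _FILLER)[: config.read_len]
        r1 = _apply_errors(r1, config.error_rate, rng_err)
        r2 = _apply_errors(r2, config.error_rate, rng_err)
        rid = f"{frag.ref_id}:{idx}"
        r1_reads.append((rid, r1, qual_char * len(r1)))
        r2_reads.append((rid, r2, qual_char * len(r2)))
    return r1_reads, r2_reads


def spike_record() -> PriMiRNARecord:
    """Panel record for the built-in internal-control species."""
    [rec] = build_panel(
        [(SPIKE_ID, SPIKE_SEQ, "AUCGA", "UCGAU", True, None)]
    )
    return rec


def simulate_experiment(
    designs: Sequence[HairpinDesign],
    model: CleavageModel,
    config: LibraryConfig,
    control_depth_per_ref: int = 100,
) -> dict:
    """Simulate a full experiment: panel, product library, control library.

    Returns a dict with the panel (designed records + spike-in), pair
    tables, product/control read lists and the :class:`SimTruth`.  All
    randomness derives from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    records: list[PriMiRNARecord] = []
    tables: dict[str, PairTable] = {}
    fragments: list[SimFragment] = []
    truths: dict[str, RefTruth] = {}
    for design in designs:
        record, pt = design_hairpin(design, overhang_nt=model.overhang_nt)
        records.append(record)
        tables[record.id] = pt
        frags, truth = simulate_products(
            record, pt, model, config.depth_per_ref, int(rng.integers(0, 2**31))
        )
        fragments.extend(frags)
        truths[record.id] = truth

    spike = spike_record()
    panel = records + [spike]
    spike_frag = SimFragment(
        spike.id, spike.pre_start, spike.pre_end + 1, 0
    )
    fragments.extend([spike_frag] * config.spikein_reads)

    product_cfg = LibraryConfig(
        **{**config.__dict__, "seed": int(rng.integers(0, 2**31))}
    )
    r1, r2 = emit_library(fragments, product_cfg, panel)

    control_frags = [
        SimFragment(r.id, 0, len(r.sequence), 0)
        for r in records
        for _ in range(control_depth_per_ref)
    ]
    control_cfg = LibraryConfig(
        **{**config.__dict__, "seed": int(rng.integers(0, 2**31))}
    )
    c1, c2 = emit_library(control_frags, control_cfg, panel, barcode_lens=(4, 6))

    return {
        "panel": panel,
        "pair_tables": tables,
        "product_r1": r1,
        "product_r2": r2,
        "control_r1": c1,
        "control_r2": c2,
        "truth": SimTruth(truths, config.spikein_reads, config.seed),
    }


def random_designs(
    n: int,
    seed: int,
    lower_range: tuple[int, int] = (14, 18),
    upper_range: tuple[int, int] = (22, 29),
    loop_range: tuple[int, int] = (8, 14),
) -> list[HairpinDesign]:
    """Seeded batch of hairpin designs with varied stem geometry."""
    rng = np.random.default_rng(seed)
    designs = []
    for i in range(n):
        designs.append(
            HairpinDesign(
                id=f"sim-{i:03d}",
                lower_stem_bp=int(rng.integers(lower_range[0], lower_range[1] + 1)),
                upper_stem_bp=int(rng.integers(upper_range[0], upper_range[1] + 1)),
                loop_nt=int(rng.integers(loop_range[0], loop_range[1] + 1)),
                seed=int(rng.integers(0, 2**31)),
            )
        )
    return designs
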