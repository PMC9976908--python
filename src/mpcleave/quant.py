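"""Cleavage-site quantification: normalized counts, scores, overhangs, KL shifts.

The cleavage atlas is built per pri-miRNA in strand-local CL coordinates:
CL0 is the annotated pre-miRNA 5' end, CL-5..CL5 the 11-position window
around it.  Product counts are normalized to a fixed-amount spike-in
species (times a scale factor of 1000), control abundance to counts per
million.  With pseudocount c = 0.1:

    global efficiency  = log2(sum_P N_P + c) - log2(N_S + c)
    efficiency(P)      = log2(N_P + c)       - log2(N_S + c)
    accuracy(P)        = N_P / sum_P N_P

The major cleavage site (mCL) is the accuracy argmax.  Profile shifts
between enzymes (e.g. mutant vs wild type) are measured as the
Kullback-Leibler divergence of the accuracy distributions in bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import PriMiRNARecord
from .reads import FragmentAlignment
from .structure import PairTable

#: the CL window on the 5p strand
CL_OFFSETS: tuple[int, ...] = tuple(range(-5, 6))

PSEUDOCOUNT = 0.1
SPIKE_SCALE = 1000.0
MIN_CONTROL_RAW = 20  # strict: retained iff raw control count > 20


@dataclass
class CleavageProfile:
    ref_id: str
    sample_id: str = ""
    raw_counts: dict[int, int] = field(default_factory=lambda: {p: 0 for p in CL_OFFSETS})
    N_P: dict[int, float] = field(default_factory=lambda: {p: 0.0 for p in CL_OFFSETS})
    N_S: float = 0.0
    control_raw: int = 0
    n_selected_reads: int = 0

    def __post_init__(self) -> None:
        for d in (self.raw_counts, self.N_P):
            if set(d) != set(CL_OFFSETS):
                raise ValueError("profile must cover exactly CL-5..CL5")
        if any(v < 0 for v in self.raw_counts.values()) or any(
            v < 0 for v in self.N_P.values()
        ) or self.N_S < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class ScoreSet:
    ref_id: str
    global_efficiency: float
    efficiency: dict[int, float]
    accuracy: dict[int, float] | None  # None when no product signal
    mCL: int | None


@dataclass(frozen=True)
class OverhangCall:
    read_id: str
    overhang_nt: int
    paired_anchor_used: bool


def assign_CL(
    aln: FragmentAlignment, record: PriMiRNARecord, window: int = 5
) -> tuple[int | None, int | None]:
    """CL offsets of the fragment's two ends; None when outside the window.

    The 5' end offset is positive downstream of CL0 (toward the loop); the
    3' end offset is sign-matched so that positive also points loopward.
    """
    end5 = aln.start - record.pre_start
    end3 = record.pre_end - (aln.end - 1)
    return (
        end5 if abs(end5) <= window else None,
        end3 if abs(end3) <= window else None,
    )


def count_profile(
    alignments: Iterable[FragmentAlignment],
    record: PriMiRNARecord,
    sample_type: Literal["product", "control"],
    spikein_count: int | None = None,
    scale: float = SPIKE_SCALE,
    total_control_reads: int | None = None,
    sample_id: str = "",
) -> CleavageProfile:
    """Accumulate mapped fragments into a cleavage profile.

    Product samples: a fragment is selected when either end lies in
    CL-5..CL5; position attribution uses the 5' end only.  Normalized
    counts are raw / spike-in count x scale.  Control samples: every
    mapped read counts toward the reference's abundance, normalized as
    counts per million when the library total is given.
    """
    prof = CleavageProfile(record.id, sample_id)
    alignments = [a for a in alignments if a.ref_id == record.id]
    if sample_type == "product":
        if not spikein_count:
            raise ValueError(
                f"{record.id}: product sample requires a positive spike-in count"
            )
        for a in alignments:
            end5, end3 = assign_CL(a, record)
            if end5 is None and end3 is None:
                continue
            prof.n_selected_reads += 1
            if end5 is not None:
                prof.raw_counts[end5] += 1
        prof.N_P = {p: c / spikein_count * scale for p, c in prof.raw_counts.items()}
    elif sample_type == "control":
        prof.control_raw = len(alignments)
        if total_control_reads:
            prof.N_S = prof.control_raw / total_control_reads * 1e6
    else:
        raise ValueError(f"unknown sample type {sample_type!r}")
    return prof


def merge_control(product: CleavageProfile, control: CleavageProfile) -> CleavageProfile:
    """Attach a control profile's abundance to a product profile."""
    if product.ref_id != control.ref_id:
        raise ValueError("profiles refer to different references")
    return CleavageProfile(
        product.ref_id,
        product.sample_id,
        dict(product.raw_counts),
        dict(product.N_P),
        control.N_S,
        control.control_raw,
        product.n_selected_reads,
    )


def efficiency_scores(
    profile: CleavageProfile, pseudocount: float = PSEUDOCOUNT
) -> tuple[float, dict[int, float]]:
    """Global and per-position log2 efficiency scores."""
    denom = math.log2(profile.N_S + pseudocount)
    total = sum(profile.N_P.values())
    global_score = math.log2(total + pseudocount) - denom
    per_pos = {
        p: math.log2(n + pseudocount) - denom for p, n in profile.N_P.items()
    }
    return global_score, per_pos


def accuracy_scores(profile: CleavageProfile) -> dict[int, float] | None:
    """Per-position fraction of normalized product counts; None if no signal."""
    total = sum(profile.N_P.values())
    if total <= 0:
        return None
    return {p: n / total for p, n in profile.N_P.items()}


def major_cleavage_site(accuracy: Mapping[int, float] | None) -> int | None:
    """The accuracy argmax; ties go to the offset closest to CL0, then the
    smaller signed offset."""
    if accuracy is None:
        return None
    peak = max(accuracy.values())
    candidates = [p for p, v in accuracy.items() if v == peak]
    return min(candidates, key=lambda p: (abs(p), p))


def score_profile(profile: CleavageProfile, pseudocount: float = PSEUDOCOUNT) -> ScoreSet:
    g, per = efficiency_scores(profile, pseudocount)
    acc = accuracy_scores(profile)
    return ScoreSet(profile.ref_id, g, per, acc, major_cleavage_site(acc))


def overhang_length(
    aln: FragmentAlignment,
    pt: PairTable,
    record: PriMiRNARecord,
    max_anchor_dist: int = 5,
) -> OverhangCall | None:
    """3' overhang of a fragment relative to the predicted duplex.

    The fragment's 5' end is projected across the stem: the nearest paired
    position at distance d >= 0 loopward of the 5' end anchors the
    projection, and the expected blunt 3' end is partner(anchor) + d.  The
    overhang is how far the observed 3' end extends past that point
    (negative = recessed).  None when no paired anchor lies within
    ``max_anchor_dist`` nt.
    """
    i = aln.start
    for d in range(max_anchor_dist + 1):
        if i + d < len(pt) and pt.partner(i + d) is not None and pt.partner(i + d) > i + d:
            j = pt.partner(i + d) + d
            return OverhangCall(aln.read_id, (aln.end - 1) - j, d > 0)
    return None


def overhang_fractions(calls: Iterable[OverhangCall | None]) -> dict[int, float]:
    """Fraction of defined overhang calls per overhang length."""
    counts: dict[int, int] = {}
    for c in calls:
        if c is None:
            continue
        counts[c.overhang_nt] = counts.get(c.overhang_nt, 0) + 1
    total = sum(counts.values())
    return {k: v / total for k, v in sorted(counts.items())} if total else {}


def kl_divergence(
    acc_test: Mapping[int, float] | None,
    acc_ref: Mapping[int, float] | None,
    smoothing: float = 1e-3,
) -> float:
    """D(test || ref) in bits over CL-5..CL5, after additive smoothing.

    Both distributions get ``smoothing`` added to every bin and are
    renormalized, so the divergence is finite for empirical profiles with
    empty bins.  Asymmetric by construction: the test (e.g. mutant)
    distribution is the reference measure.
    """
    if acc_test is None or acc_ref is None:
        raise ValueError("KL divergence requires defined accuracy distributions")
    p = np.array([acc_test[o] for o in CL_OFFSETS], dtype=float) + smoothing
    q = np.array([acc_ref[o] for o in CL_OFFSETS], dtype=float) + smoothing
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("accuracy values must be non-negative")
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log2(p / q)))


def filter_panel_by_control(
    profiles: Iterable[CleavageProfile], min_control_raw: int = MIN_CONTROL_RAW
) -> list[str]:
    """Reference ids whose raw control count strictly exceeds the threshold."""
    return [p.ref_id for p in profiles if p.control_raw > min_control_raw]


def scores_table(scores: Sequence[ScoreSet]) -> pd.DataFrame:
    """One row per reference: global efficiency, per-position scores, mCL."""
    rows = []
    for s in scores:
        row: dict = {"ref_id": s.ref_id, "global_efficiency": s.global_efficiency}
        for p in CL_OFFSETS:
            row[f"efficiency_CL{p}"] = s.efficiency[p]
        for p in CL_OFFSETS:
            row[f"accuracy_CL{p}"] = s.accuracy[p] if s.accuracy else float("nan")
        row["mCL"] = s.mCL if s.mCL is not None else pd.NA
        rows.append(row)
    return pd.DataFrame(rows)
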