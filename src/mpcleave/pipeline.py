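"""End-to-end orchestration: raw reads -> alignments -> cleavage atlas.

Thin glue over the stage modules, shared by the command-line interface,
the test suite and reproduction scripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .panel import PriMiRNARecord, spikein_record
from .quant import (
    CleavageProfile,
    OverhangCall,
    ScoreSet,
    count_profile,
    filter_panel_by_control,
    merge_control,
    overhang_length,
    score_profile,
)
from .reads import (
    FragmentAlignment,
    PipelineConfig,
    ReadPair,
    process_read_pairs,
)
from .structure import PairTable


def pairs_from_lists(
    r1: Sequence[tuple[str, str, str]], r2: Sequence[tuple[str, str, str]]
) -> list[ReadPair]:
    """Zip in-memory (id, seq, qual-string) mate lists into ReadPairs."""
    out = []
    for (id1, s1, q1), (id2, s2, q2) in zip(r1, r2, strict=True):
        out.append(
            ReadPair(id1, s1, [ord(c) - 33 for c in q1], s2, [ord(c) - 33 for c in q2])
        )
    return out


@dataclass
class AtlasResult:
    profiles: dict[str, CleavageProfile]
    scores: dict[str, ScoreSet]
    retained: list[str]
    spikein_count: int
    overhangs: dict[str, list[OverhangCall]] = field(default_factory=dict)


def build_atlas(
    panel: Sequence[PriMiRNARecord],
    product_alignments: Sequence[FragmentAlignment],
    control_alignments: Sequence[FragmentAlignment],
    pair_tables: Mapping[str, PairTable] | None = None,
    min_control_raw: int = 20,
    scale: float = 1000.0,
    pseudocount: float = 0.1,
) -> AtlasResult:
    """Quantify mapped fragments into per-reference profiles and scores.

    The spike-in count is taken from the product alignments mapped to the
    panel's spike-in record; control abundance is CPM over all mapped
    control reads.  When pair tables are supplied, per-read 3' overhangs
    are computed for every product fragment.
    """
    spike = spikein_record(panel)
    if spike is None:
        raise ValueError("panel has no spike-in record; product counts cannot be normalized")
    spike_count = sum(1 for a in product_alignments if a.ref_id == spike.id)
    if spike_count == 0:
        raise ValueError("no product reads mapped to the spike-in; normalization impossible")
    total_control = len(control_alignments)

    profiles: dict[str, CleavageProfile] = {}
    scores: dict[str, ScoreSet] = {}
    overhangs: dict[str, list[OverhangCall]] = {}
    for record in panel:
        if record.is_spikein:
            continue
        prod = count_profile(
            product_alignments, record, "product", spikein_count=spike_count, scale=scale
        )
        ctrl = count_profile(
            control_alignments, record, "control", total_control_reads=total_control
        )
        prof = merge_control(prod, ctrl)
        profiles[record.id] = prof
        scores[record.id] = score_profile(prof, pseudocount)
        if pair_tables and record.id in pair_tables:
            pt = pair_tables[record.id]
            calls = []
            for a in product_alignments:
                if a.ref_id == record.id:
                    call = overhang_length(a, pt, record)
                    if call is not None:
                        calls.append(call)
            overhangs[record.id] = calls

    retained = filter_panel_by_control(profiles.values(), min_control_raw)
    return AtlasResult(profiles, scores, retained, spike_count, overhangs)


def run_experiment(
    sim: dict,
    pipeline_config: PipelineConfig | None = None,
    min_control_raw: int = 20,
) -> tuple[AtlasResult, dict[str, dict[str, int]]]:
    """Process a simulated experiment through the full read pipeline.

    ``sim`` is the output of :func:`mpcleave.simulate.simulate_experiment`.
    Returns the atlas plus per-sample attrition statistics.
    """
    panel = sim["panel"]
    prod_pairs = pairs_from_lists(sim["product_r1"], sim["product_r2"])
    ctrl_pairs = pairs_from_lists(sim["control_r1"], sim["control_r2"])
    prod_alns, prod_stats = process_read_pairs(prod_pairs, panel, "product", pipeline_config)
    ctrl_alns, ctrl_stats = process_read_pairs(ctrl_pairs, panel, "control", pipeline_config)
    atlas = build_atlas(
        panel,
        prod_alns,
        ctrl_alns,
        pair_tables=sim.get("pair_tables"),
        min_control_raw=min_control_raw,
    )
    return atlas, {"product": prod_stats, "control": ctrl_stats}
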