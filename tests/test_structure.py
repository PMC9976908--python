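import numpy as np
import pytest

from mpcleave.panel import PriMiRNARecord, build_panel
from mpcleave.simulate import HairpinDesign, design_hairpin
from mpcleave.structure import (
    PairTable,
    StructureError,
    annotate_record,
    annotation_table,
    call_junctions,
    is_multiloop,
    mismatch_profile,
    parse_dotbracket,
    read_mghg_matrix,
    read_vienna,
    scan_motifs,
    species_summary,
    stem_lengths,
    to_dotbracket,
    write_vienna,
)


class TestParseDotbracket:
    def test_nested_pairing(self):
        pt = parse_dotbracket("((((....))))")
        assert pt.partner(0) == 11
        assert pt.partner(3) == 8
        assert all(not pt.is_paired(i) for i in range(4, 8))

    def test_all_unpaired(self):
        pt = parse_dotbracket("....")
        assert all(not pt.is_paired(i) for i in range(4))

    @pytest.mark.parametrize("bad", ["((.)", "(.))", "..x.."])
    def test_malformed_raises_with_position(self, bad):
        with pytest.raises(StructureError):
            parse_dotbracket(bad)

    def test_length_mismatch_with_sequence(self):
        with pytest.raises(StructureError, match="length"):
            parse_dotbracket("(((...)))", "ACGU")

    def test_round_trip_through_dotbracket(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            lo = int(rng.integers(1, 12))
            loop = int(rng.integers(3, 9))
            db = "." * int(rng.integers(0, 4)) + "(" * lo + "." * loop + ")" * lo
            pt = parse_dotbracket(db)
            assert to_dotbracket(pt) == db
            # symmetry invariant
            for i, j in enumerate(pt.partners):
                if j is not None:
                    assert pt.partner(j) == i


class TestMultiloop:
    def test_single_hairpin(self):
        assert not is_multiloop(parse_dotbracket("(((....)))"))

    def test_cloverleaf(self):
        assert is_multiloop(parse_dotbracket("((..))((..))"))
        assert is_multiloop(parse_dotbracket("((((..))((..))))"))

    def test_fully_unpaired_has_no_loop(self):
        assert not is_multiloop(parse_dotbracket("........"))

    def test_internal_loops_do_not_count(self):
        assert not is_multiloop(parse_dotbracket("((..((...))..))"))


class TestJunctions:
    def test_perfect_default_geometry(self, designed_hairpin):
        record, pt = designed_hairpin
        bjc, ajc = call_junctions(pt, record)
        assert (bjc, ajc) == (-17, 25)
        assert stem_lengths(pt, (bjc, ajc), record) == (16, 25)

    def test_basal_run_starting_inside_minus_10_window_required(self):
        # 9-bp lower stem: the single-stranded run starts at -10 (in window)
        rec9, pt9 = design_hairpin(HairpinDesign("a", lower_stem_bp=9, seed=1))
        assert call_junctions(pt9, rec9)[0] == -10
        # 8-bp lower stem: run starts at -9, outside [-25, -10] -> undefined
        rec8, pt8 = design_hairpin(HairpinDesign("b", lower_stem_bp=8, seed=1))
        assert call_junctions(pt8, rec8)[0] is None

    def test_apical_window(self):
        rec, pt = design_hairpin(HairpinDesign("c", upper_stem_bp=20, seed=2))
        assert call_junctions(pt, rec)[1] is None  # aJC +20 < +21
        rec, pt = design_hairpin(HairpinDesign("d", upper_stem_bp=31, seed=2))
        assert call_junctions(pt, rec)[1] is None  # run starts at +31, past +30
        rec, pt = design_hairpin(HairpinDesign("e", upper_stem_bp=30, seed=2))
        assert call_junctions(pt, rec)[1] == 30  # window edge is inclusive

    def test_interior_mismatch_does_not_move_junction_but_shortens_stem(self):
        design = HairpinDesign(
            "m", planted_mismatch_offsets=(-8, 12), seed=3
        )
        record, pt = design_hairpin(design)
        bjc, ajc = call_junctions(pt, record)
        assert (bjc, ajc) == (-17, 25)
        assert stem_lengths(pt, (bjc, ajc), record) == (15, 24)

    def test_three_mismatch_run_in_stem_truncates_junction_call(self):
        # a >=3 single-stranded run inside the lower stem opens early
        design = HairpinDesign(
            "n", lower_stem_bp=20, planted_mismatch_offsets=(-10, -11, -12), seed=4
        )
        record, pt = design_hairpin(design)
        bjc, _ = call_junctions(pt, record)
        assert bjc == -10

    def test_recovery_across_design_grid(self):
        rng = np.random.default_rng(2024)
        for i in range(60):
            lo = int(rng.integers(11, 25))
            up = int(rng.integers(22, 30))
            design = HairpinDesign(
                f"g{i}", lower_stem_bp=lo, upper_stem_bp=up,
                loop_nt=int(rng.integers(4, 15)), seed=int(rng.integers(0, 2**31)),
            )
            record, pt = design_hairpin(design)
            bjc, ajc = call_junctions(pt, record)
            assert (bjc, ajc) == (-(lo + 1), up)
            assert stem_lengths(pt, (bjc, ajc), record) == (lo, up)


def test_mismatch_profile_fractions():
    r1, p1 = design_hairpin(HairpinDesign("a", seed=5))
    r2, p2 = design_hairpin(HairpinDesign("b", planted_mismatch_offsets=(11,), seed=6))
    prof = mismatch_profile([(r1, p1), (r2, p2)], offsets=range(-16, 25))
    assert prof[11] == 0.5
    assert prof[5] == 0.0
    assert prof[-3] == 0.0
    assert mismatch_profile([]) == {}


def _motif_record(seq5p_mods=None, seq3p_mods=None, **design_kw):
    """Designed hairpin with specific bases written into chosen offsets."""
    design = HairpinDesign("mot", seed=42, **design_kw)
    record, pt = design_hairpin(design)
    seq = list(record.sequence)
    for off, base in (seq5p_mods or {}).items():
        seq[record.pre_start + off] = base
    for off, base in (seq3p_mods or {}).items():
        seq[record.pre_end - off] = base
    rec = PriMiRNARecord(record.id, "".join(seq), record.pre_start, record.pre_end)
    return rec, pt


class TestMotifs:
    def test_ug_in_window(self):
        rec, pt = _motif_record({-13: "U", -12: "G", -14: "A"})
        assert scan_motifs(rec, pt).ug is True

    def test_ug_outside_window(self):
        mods = {o: "A" for o in range(-15, -10)}
        mods.update({-17: "U", -16: "G"})
        rec, pt = _motif_record(mods)
        assert scan_motifs(rec, pt).ug is False

    def test_ugu_gug_window(self):
        mods = {o: "C" for o in range(20, 28)}
        mods.update({24: "G", 25: "U", 26: "G"})
        rec, pt = _motif_record(mods)
        assert scan_motifs(rec, pt).ugu_gug is True
        # trinucleotide starting at +25 would end at +27, outside the window
        mods = {o: "C" for o in range(20, 28)}
        mods.update({25: "U", 26: "G", 27: "U"})
        rec, pt = _motif_record(mods)
        assert scan_motifs(rec, pt).ugu_gug is False

    def test_cnnc_on_3p_flank(self):
        rec, pt = _motif_record(
            seq3p_mods={-18: "C", -19: "A", -20: "A", -21: "C", -16: "G", -17: "G"},
            flank3_nt=25,
        )
        assert scan_motifs(rec, pt).cnnc is True

    def test_cnnc_window_truncated_is_undefined(self):
        rec, pt = _motif_record(flank3_nt=3)  # 3p window leaves the transcript
        assert scan_motifs(rec, pt).cnnc is None

    def test_midbmw_absent_on_watson_crick(self):
        rec, pt = design_hairpin(HairpinDesign("wc", seed=7))
        seq = list(rec.sequence)
        for off in (10, 11, 12):  # force A:U pairs, no wobble
            c = rec.pre_start + off
            seq[c] = "A"
            seq[pt.partner(c)] = "U"
        rec = PriMiRNARecord(rec.id, "".join(seq), rec.pre_start, rec.pre_end)
        assert scan_motifs(rec, pt).midbmw is False

    def test_midbmw_wobble_and_mismatch(self):
        rec, pt = design_hairpin(
            HairpinDesign("wob", planted_wobble_offsets=(11,), seed=8)
        )
        assert scan_motifs(rec, pt).midbmw is True
        rec, pt = design_hairpin(
            HairpinDesign("mm", planted_mismatch_offsets=(10,), seed=8)
        )
        assert scan_motifs(rec, pt).midbmw is True

    def test_mghg_scored_from_matrix(self, tmp_path):
        rec, pt = design_hairpin(HairpinDesign("gh", seed=9))
        triplet = rec.sequence[rec.pre_end + 3 : rec.pre_end + 6]
        matrix_path = tmp_path / "mghg.tsv"
        lines = ["triplet\tscore"] + [f"{triplet}\t55.0"]
        matrix_path.write_text("\n".join(lines) + "\n")
        matrix = read_mghg_matrix(matrix_path)
        flags = scan_motifs(rec, pt, matrix)
        assert flags.mghg_score == 55.0
        assert flags.mghg is True
        low = {triplet: 10.0}
        assert scan_motifs(rec, pt, low).mghg is False

    def test_mghg_undefined_without_matrix(self):
        rec, pt = design_hairpin(HairpinDesign("nm", seed=10))
        flags = scan_motifs(rec, pt)
        assert flags.mghg_score is None and flags.mghg is None

    def test_mghg_bulge_exclusion(self):
        # a bulge in the 3p -5..-3 window shifts the pairing register
        rec, pt = design_hairpin(HairpinDesign("bg", seed=12))
        partners = list(pt.partners)
        c = rec.pre_end + 4  # 3p offset -4
        five = partners[c]
        # delete the pair and re-pair the 5p side one step off-register
        partners[c] = None
        partners[five] = None
        other3 = rec.pre_end + 6  # outside the window
        old5 = partners[other3]
        if old5 is not None:
            partners[old5] = None
        partners[five], partners[other3] = other3, five
        bulged = PairTable(partners)
        flags = scan_motifs(rec, bulged, {"AAA": 50.0})
        assert flags.mghg_score is None


class TestSpeciesSummary:
    def _annotated(self):
        out = []
        for i, species in enumerate(["cel", "cel", "cel", "cel", "hsa"]):
            rec, pt = design_hairpin(HairpinDesign(f"s{i}", seed=100 + i))
            rec = PriMiRNARecord(rec.id, rec.sequence, rec.pre_start, rec.pre_end,
                                 species=species)
            out.append((rec, annotate_record(rec, pt)))
        return out

    def test_percentages_and_grouping(self):
        annotated = self._annotated()
        # plant CNNC=True on exactly one of the four cel records
        annotated[0][1].motifs.cnnc = True
        for _, ann in annotated[1:4]:
            ann.motifs.cnnc = False
        motifs, stems = species_summary(annotated)
        assert set(motifs["species"]) == {"cel", "hsa"}
        cel = motifs.set_index("species").loc["cel"]
        assert cel["n"] == 4
        assert cel["pct_cnnc"] == 25.0
        assert not stems.empty
        cel_lower = stems[(stems.species == "cel") & (stems.stem == "lower")]
        assert cel_lower["percent"].sum() == pytest.approx(100.0)

    def test_multiloop_records_excluded(self):
        annotated = self._annotated()
        for _, ann in annotated:
            if ann.ref_id != "s4":
                ann.multiloop = True
        motifs, _ = species_summary(annotated)
        assert list(motifs["species"]) == ["hsa"]


def test_vienna_round_trip(tmp_path, designed_hairpin):
    record, pt = designed_hairpin
    path = tmp_path / "x.db"
    write_vienna(path, [(record.id, record.sequence, to_dotbracket(pt))])
    [(rid, seq, db)] = list(read_vienna(path))
    assert (rid, seq) == (record.id, record.sequence)
    assert parse_dotbracket(db, seq).partners == pt.partners


def test_annotation_table_shape(designed_hairpin):
    record, pt = designed_hairpin
    df = annotation_table([annotate_record(record, pt)])
    assert df.loc[0, "bJC"] == -17
    assert df.loc[0, "lower_stem_bp"] == 16
    assert "mGHG_score" in df.columns
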