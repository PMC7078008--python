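"""Codec behaviour: pitch map, styles, encode/decode, structure inference."""
import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aminoscore import sonics
from aminoscore.types import (
    AA_ALPHABET,
    Chain,
    ConfigError,
    MidiScore,
    NoteEvent,
    SequenceRecord,
    ValidationError,
)

from conftest import random_record


def one_residue(aa: str, cls: str) -> SequenceRecord:
    return SequenceRecord("x", [Chain(aa, cls)])


record_strategy = st.builds(
    lambda chains: SequenceRecord("h", [Chain(s, x) for s, x in chains]),
    st.lists(
        st.tuples(
            st.text(alphabet=AA_ALPHABET, min_size=1, max_size=20),
            st.text(alphabet="HEC", min_size=1, max_size=20),
        ).map(lambda t: (t[0], (t[1] * 20)[: len(t[0])])),
        min_size=1,
        max_size=3,
    ),
)


class TestPitchMap:
    def test_vocabulary_is_22_distinct_pitches(self):
        pm = sonics.PitchMap()
        assert len(pm.all_pitches()) == 22

    def test_default_assignment_runs_up_the_white_keys(self):
        pm = sonics.PitchMap()
        # alphabetical amino acids onto consecutive white keys from C-2,
        # skipping reserved B-2; spot-check ends and the octave crossing
        assert pm.aa_to_pitch["A"] == sonics.pitch_from_name("C-2")
        assert pm.aa_to_pitch["G"] == sonics.pitch_from_name("A-2")  # 6th white key
        assert pm.aa_to_pitch["H"] == sonics.pitch_from_name("C-1")  # skips B-2
        assert pm.aa_to_pitch["Y"] == sonics.pitch_from_name("B0")
        pitches = sorted(pm.aa_to_pitch.values())
        assert pitches == sorted(set(pitches))
        assert all(p % 12 in {0, 2, 4, 5, 7, 9, 11} for p in pitches)  # white keys
        assert all(0 <= p <= 45 for p in pitches)  # C-2 .. A1 register

    def test_separator_pitches(self):
        pm = sonics.PitchMap()
        assert pm.chain_sep_pitch == sonics.pitch_from_name("B-2") == 11
        assert pm.protein_sep_pitch == sonics.pitch_from_name("A#-2") == 10

    def test_bijection_inverts(self):
        pm = sonics.PitchMap()
        for aa in AA_ALPHABET:
            assert pm.invert(pm.aa_to_pitch[aa]) == aa

    def test_user_table_collision_is_config_error(self):
        table = {aa: name for aa, name in zip(AA_ALPHABET, [
            "C-2", "D-2", "E-2", "F-2", "G-2", "A-2", "C-1", "D-1", "E-1",
            "F-1", "G-1", "A-1", "B-1", "C0", "D0", "E0", "F0", "G0", "A0",
            "C-2",  # Y duplicates A's note
        ])}
        with pytest.raises(ConfigError, match="bijection"):
            sonics.build_pitch_map(table)

    def test_user_table_on_separator_pitch_is_config_error(self):
        pm_cfg = {aa: p for aa, p in zip(AA_ALPHABET, range(12, 32))}
        pm_cfg["A"] = 11  # B-2 is reserved for the chain delimiter
        with pytest.raises(ConfigError, match="reserved"):
            sonics.build_pitch_map(pm_cfg)

    @pytest.mark.parametrize(
        "pitch, name", [(0, "C-2"), (10, "A#-2"), (11, "B-2"), (45, "A1")]
    )
    def test_note_naming_convention(self, pitch, name):
        assert sonics.note_name(pitch) == name
        assert sonics.pitch_from_name(name) == pitch


class TestEncode:
    @pytest.mark.parametrize(
        "cls, duration, velocity",
        [("H", 0.5, 50), ("E", 1.0, 100), ("C", 2.0, 25)],
    )
    def test_class_styles(self, cls, duration, velocity):
        score = sonics.encode([one_residue("A", cls)])
        (note,) = score.main_track
        assert note.duration == duration
        assert note.velocity == velocity

    def test_chain_separator_between_chains(self):
        rec = SequenceRecord("x", [Chain("A", "H"), Chain("C", "E")])
        score = sonics.encode([rec])
        assert len(score.main_track) == 3
        sep = score.main_track[1]
        assert sep.pitch == 11 and sep.duration == 4.0 and sep.velocity == 100

    def test_protein_separator_between_records(self):
        score = sonics.encode([one_residue("A", "H"), one_residue("C", "E")])
        assert len(score.main_track) == 3
        sep = score.main_track[1]
        assert sep.pitch == 10 and sep.duration == 8.0 and sep.velocity == 100

    def test_empty_record_list(self):
        assert sonics.encode([]).tracks == []

    def test_missing_ss_errors(self):
        rec = SequenceRecord("x", [Chain("AC")])
        with pytest.raises(ValidationError, match="secondary structure"):
            sonics.encode([rec])

    def test_onsets_are_cumulative_durations(self, rng):
        rec = random_record(rng)
        notes = sonics.encode([rec]).main_track
        cursor = 0.0
        for note in notes:
            assert note.onset == pytest.approx(cursor)
            cursor += note.duration

    @given(record_strategy)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_total_duration_identity(self, rec):
        # total = sum of residue durations + 4 per chain break (+8 per
        # protein break, none here for a single record)
        style = sonics.SSStyle()
        notes = sonics.encode([rec]).main_track
        expected = sum(
            style.duration(cls) for c in rec.chains for cls in c.ss
        ) + 4.0 * (len(rec.chains) - 1)
        assert notes[-1].end == pytest.approx(expected)

    def test_helix_notes_shorter_and_softer_than_sheet(self):
        style = sonics.SSStyle()
        assert style.duration("H") < style.duration("E")
        assert style.velocity("H") < style.velocity("E")
        assert style.duration("C") > style.duration("E")
        assert style.velocity("C") < style.velocity("E")


class TestDecode:
    @given(record_strategy)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_round_trip_tokens(self, rec):
        tokens = sonics.decode(sonics.encode([rec]))
        expected = "!".join(c.sequence for c in rec.chains)
        assert str(tokens) == expected

    def test_chain_separator_token(self):
        score = MidiScore(tracks=[[NoteEvent(11, 0.0, 4.0, 100)]])
        assert str(sonics.decode(score)) == "!"

    def test_oov_pitch_lenient_skips_with_warning(self, caplog):
        score = MidiScore(
            tracks=[[NoteEvent(0, 0.0, 0.5, 50), NoteEvent(46, 0.5, 0.5, 50)]]
        )
        with caplog.at_level(logging.WARNING, logger="aminoscore.sonics"):
            tokens = sonics.decode(score)
        assert str(tokens) == "A"
        assert sum("out-of-vocabulary" in r.message for r in caplog.records) == 1

    def test_oov_pitch_strict_raises_with_onset_and_pitch(self):
        score = MidiScore(tracks=[[NoteEvent(46, 2.5, 0.5, 50)]])
        with pytest.raises(ValidationError, match=r"pitch 46.*onset 2\.5"):
            sonics.decode(score, strict=True)


class TestInferSS:
    @given(record_strategy)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_recovers_input_ss(self, rec):
        assert sonics.infer_ss(sonics.encode([rec])) == "".join(
            c.ss for c in rec.chains
        )

    @pytest.mark.parametrize(
        "duration, velocity, cls",
        [(0.5, 50, "H"), (1.0, 100, "E"), (2.0, 25, "C")],
    )
    def test_exact_styles_classify(self, duration, velocity, cls):
        score = MidiScore(tracks=[[NoteEvent(0, 0.0, duration, velocity)]])
        assert sonics.infer_ss(score) == cls

    def test_nearest_style_in_lenient_mode(self):
        score = MidiScore(tracks=[[NoteEvent(0, 0.0, 0.55, 48)]])
        assert sonics.infer_ss(score) == "H"

    def test_strict_mode_requires_exact_match(self):
        score = MidiScore(tracks=[[NoteEvent(0, 0.0, 0.55, 48)]])
        with pytest.raises(ValidationError, match="exactly"):
            sonics.infer_ss(score, strict=True)

    def test_separators_excluded(self):
        rec1 = SequenceRecord("a", [Chain("AC", "HH"), Chain("D", "E")])
        rec2 = SequenceRecord("b", [Chain("K", "C")])
        assert sonics.infer_ss(sonics.encode([rec1, rec2])) == "HHEC"

    def test_ambiguous_tie_lists_candidates(self):
        style = sonics.SSStyle(
            class_style={"E": (1.0, 1.0), "H": (1.0, 1.0), "C": (2.0, 0.25)}
        )
        score = MidiScore(tracks=[[NoteEvent(0, 0.0, 1.0, 100)]])
        with pytest.raises(ValidationError, match=r"\['E', 'H'\]"):
            sonics.infer_ss(score, style)


class TestBarCount:
    @pytest.mark.parametrize("n_notes, bars", [(8, 1), (9, 2), (16, 2), (17, 3)])
    def test_sheet_notes_fill_bars(self, n_notes, bars):
        rec = SequenceRecord("x", [Chain("A" * n_notes, "E" * n_notes)])
        assert sonics.bar_count(sonics.encode([rec])) == bars

    def test_empty_score_is_zero_bars(self):
        assert sonics.bar_count(MidiScore()) == 0

    @given(record_strategy)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_ceiling_oracle(self, rec):
        import math

        score = sonics.encode([rec])
        total = sum(n.duration for n in score.main_track)
        assert sonics.bar_count(score) == math.ceil(total / 8 - 1e-9)
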