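"""Grammar parsing, local alignment, helix segmentation, ANM normal modes."""
from functools import lru_cache
from itertools import product

import numpy as np
import pytest

from aminoscore import analysis
from aminoscore.types import CaCoordinates, ValidationError


# ---------------------------------------------------------------------------
# delimiter grammar
# ---------------------------------------------------------------------------

class TestParseGenerated:
    def test_seed_then_chains(self):
        parsed = analysis.parse_generated(list("ACD#EFG!HIK!LMN"))
        assert parsed.seed_part == "ACD"
        assert parsed.proteins == [["EFG", "HIK", "LMN"]]
        assert parsed.trailing_incomplete

    def test_unclosed_final_chain_flagged(self):
        parsed = analysis.parse_generated(list("A#AA!AA"))
        assert parsed.proteins == [["AA", "AA"]]
        assert parsed.trailing_incomplete

    def test_closed_final_chain_not_flagged(self):
        parsed = analysis.parse_generated(list("A#AA!AA!"))
        assert parsed.proteins == [["AA", "AA"]]
        assert not parsed.trailing_incomplete

    def test_hash_after_bang_opens_protein_without_empty_chain(self):
        parsed = analysis.parse_generated(list("A#CC!#DD"))
        assert parsed.proteins == [["CC"], ["DD"]]

    def test_no_hash_everything_is_seed(self):
        parsed = analysis.parse_generated(list("AA!AA"))
        assert parsed.seed_part == "AAAA"
        assert parsed.proteins == []

    def test_left_inverse_of_delimiter_joining(self, rng):
        # joining proteins with '#'/'!' then parsing recovers the structure
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(50):
            proteins = [
                [
                    "".join(rng.choice(letters, size=int(rng.integers(1, 8))))
                    for _ in range(int(rng.integers(1, 4)))
                ]
                for _ in range(int(rng.integers(1, 4)))
            ]
            text = "".join("#" + "!".join(chains) + "!" for chains in proteins)
            parsed = analysis.parse_generated(list("AC" + text))
            assert parsed.seed_part == "AC"
            assert parsed.proteins == proteins
            assert not parsed.trailing_incomplete


# ---------------------------------------------------------------------------
# local alignment
# ---------------------------------------------------------------------------

def _global_score(a: str, b: str, match=1, mismatch=-1, gap=-2) -> int:
    """Independent oracle: exhaustive recursive global alignment score."""

    @lru_cache(maxsize=None)
    def f(i: int, j: int) -> int:
        if i == 0 and j == 0:
            return 0
        best = -(10**9)
        if i > 0 and j > 0:
            best = max(best, f(i - 1, j - 1) + (match if a[i - 1] == b[j - 1] else mismatch))
        if i > 0:
            best = max(best, f(i - 1, j) + gap)
        if j > 0:
            best = max(best, f(i, j - 1) + gap)
        return best

    return f(len(a), len(b))


def _brute_local_score(q: str, t: str) -> int:
    """Best local score = max global score over all substring pairs."""
    best = 0
    for qa in range(len(q)):
        for qb in range(qa + 1, len(q) + 1):
            for ta in range(len(t)):
                for tb in range(ta + 1, len(t) + 1):
                    best = max(best, _global_score(q[qa:qb], t[ta:tb]))
    return best


class TestLocalAlign:
    def test_identical_sequences(self):
        hit = analysis.local_align("A" * 30, "A" * 30)
        assert hit.percent_identity == 100.0
        assert hit.query_cover == 100.0
        assert hit.alignment_score == 30

    def test_single_middle_substitution(self):
        hit = analysis.local_align("ACDEF", "ACXEF".replace("X", "W"))
        assert hit.percent_identity == pytest.approx(80.0)
        assert hit.query_cover == 100.0
        assert hit.alignment_score == 3  # 4 matches - 1 mismatch

    def test_disjoint_alphabets(self):
        hit = analysis.local_align("AAAA", "CCCC")
        assert hit.alignment_score == 0
        assert hit.query_cover == 0.0

    def test_gapped_alignment(self):
        hit = analysis.local_align("ACDEFG", "ACDFG")
        # 5 matches with one query residue gapped: 5 - 2 = 3
        assert hit.alignment_score == 3

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            analysis.local_align("", "ACD")

    def test_matches_brute_force_on_short_strings(self, rng):
        # oracle: enumeration of all substring pairs, recursive global score
        letters = list("ACD")
        for _ in range(150):
            q = "".join(rng.choice(letters, size=int(rng.integers(1, 7))))
            t = "".join(rng.choice(letters, size=int(rng.integers(1, 7))))
            assert analysis.local_align(q, t).alignment_score == _brute_local_score(q, t), (q, t)

    def test_exhaustive_length_three(self):
        # every pair of length-3 strings over a 2-letter alphabet
        for q_t in product(product("AC", repeat=3), repeat=2):
            q, t = "".join(q_t[0]), "".join(q_t[1])
            assert analysis.local_align(q, t).alignment_score == _brute_local_score(q, t)

    def test_tie_break_earliest_start(self):
        # 'ACA' occurs at target positions 1 and 5 with equal score
        hit = analysis.local_align("ACA", "ACADACA")
        assert hit.target_span[0] == 1


class TestNoveltyScan:
    def test_training_member_flagged(self):
        corpus = {"a": "MKQLEDKVEELLSK", "b": "GIFSKLAGKKIKNL"}
        hits = analysis.novelty_scan("MKQLEDKVEELLSK", corpus)
        assert hits[0].target_id == "a"
        assert hits[0].in_training

    def test_novel_chain_not_flagged(self):
        hits = analysis.novelty_scan("WWWWYYYY", {"a": "MKQLEDKVEELLSK"})
        assert not hits[0].in_training

    def test_shared_kmer_ranks_first(self):
        query = "AAAACDEFGHIKLMAAAA"
        corpus = {"near": "WWCDEFGHIKLMWW", "far": "YYYYYYYYYYYYYY"}
        hits = analysis.novelty_scan(query, corpus)
        assert hits[0].target_id == "near"
        assert hits[0].alignment_score > hits[1].alignment_score

    def test_empty_corpus(self):
        assert analysis.novelty_scan("ACDEF", {}) == []


# ---------------------------------------------------------------------------
# helix segmentation
# ---------------------------------------------------------------------------

class TestHelixSegments:
    def test_three_segments_from_two_breaks(self):
        segs = analysis.helix_segments("HHHHHCCHHHHHCHHHH")
        assert len(segs) == 3
        assert segs == [(1, 5), (8, 12), (14, 17)]

    def test_all_coil(self):
        assert analysis.helix_segments("C" * 20) == []

    @pytest.mark.parametrize("min_len, count", [(4, 0), (3, 1)])
    def test_min_len_threshold(self, min_len, count):
        assert len(analysis.helix_segments("HHH", min_len=min_len)) == count

    def test_invariant_to_non_helix_relabeling(self, rng):
        for _ in range(30):
            ss = "".join(rng.choice(list("HEC"), size=40))
            relabeled = ss.replace("E", "C")
            assert analysis.helix_segments(ss) == analysis.helix_segments(relabeled)

    def test_run_length_oracle(self, rng):
        for _ in range(30):
            ss = "".join(rng.choice(list("HC"), size=30))
            runs = []
            k = 0
            while k < len(ss):
                if ss[k] == "H":
                    j = k
                    while j < len(ss) and ss[j] == "H":
                        j += 1
                    if j - k >= 4:
                        runs.append((k + 1, j))
                    k = j
                else:
                    k += 1
            assert analysis.helix_segments(ss) == runs


# ---------------------------------------------------------------------------
# anisotropic network model
# ---------------------------------------------------------------------------

def _helical_trace(n: int) -> CaCoordinates:
    """Idealised alpha-helical C-alpha trace (rise 1.5 Å, 100° twist, r 2.3 Å)."""
    k = np.arange(n)
    theta = np.deg2rad(100.0) * k
    return CaCoordinates(
        np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * k])
    )


class TestAnm:
    def test_two_particles_closed_form(self):
        # one spring: single stretching mode with eigenvalue 2*gamma
        coords = CaCoordinates([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        res = analysis.anm_modes(coords, analysis.AnmConfig(cutoff=5, gamma=3.0))
        positive = res.eigenvalues[res.eigenvalues > 1e-8]
        assert len(positive) == 1
        assert positive[0] == pytest.approx(6.0)

    def test_connected_network_has_six_zero_modes(self):
        res = analysis.anm_modes(_helical_trace(15))
        assert res.n_zero_modes == 6

    def test_frequencies_nondecreasing(self):
        res = analysis.anm_modes(_helical_trace(20))
        assert np.all(np.diff(res.frequencies) >= -1e-12)
        assert np.allclose(res.frequencies, np.sqrt(np.clip(res.eigenvalues, 0, None)))

    def test_hessian_symmetric_psd_with_vanishing_row_sums(self):
        coords = _helical_trace(12)
        hess = analysis.anm_hessian(coords)
        assert np.allclose(hess, hess.T)
        # translation invariance: super-element row sums vanish
        n = len(coords)
        row_sums = hess.reshape(n, 3, n, 3).sum(axis=2)
        assert np.allclose(row_sums, 0.0, atol=1e-12)
        assert np.linalg.eigvalsh(hess).min() >= -1e-8

    def test_disconnected_network_reports_extra_zero_modes(self, caplog):
        import logging

        far = np.vstack([_helical_trace(6).positions,
                         _helical_trace(6).positions + [200.0, 0, 0]])
        with caplog.at_level(logging.WARNING, logger="aminoscore.analysis"):
            res = analysis.anm_modes(CaCoordinates(far))
        assert res.n_zero_modes == 12
        assert any("disconnected" in r.message for r in caplog.records)

    def test_cutoff_must_be_positive(self):
        with pytest.raises(ValidationError):
            analysis.AnmConfig(cutoff=0)
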