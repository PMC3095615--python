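from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirseek.hairpin_fold import (
    DEFAULT_PAIR_SCORES, best_precursor, fold, validate_hairpin,
)
from mirseek.io import revcomp

WC_ONLY = {frozenset("AT"): 1.0, frozenset("GC"): 1.0}
MAXPAIR = {frozenset("AT"): 1.0, frozenset("GC"): 1.0, frozenset("GT"): 1.0}

MATURE21 = "TGACAGAAGAGAGTGAGCACA"
LOOP15 = "ACAACAAACCAACAA"


def perfect_precursor(mature=MATURE21, loop=LOOP15):
    """Mature fully paired against revcomp, 2 spare bases for the star
    3' overhang extension."""
    return mature + loop + revcomp(mature) + "AA"


def enumerate_structures(seq, min_loop=3):
    """Exhaustively enumerate every valid nested structure (pair sets)."""
    pairable = {frozenset(k) for k in (("A", "T"), ("G", "C"), ("G", "T"))}

    @lru_cache(maxsize=None)
    def region(i, j):
        if j - i < min_loop + 1:
            return [()]
        out = list(region(i, j - 1))
        for k in range(i, j - min_loop):
            if frozenset((seq[k], seq[j])) in pairable:
                for left in region(i, k - 1) if k > i else [()]:
                    for inner in region(k + 1, j - 1):
                        out.append(left + ((k, j),) + inner)
        return out

    return region(0, len(seq) - 1)


def score_structure(seq, pairs, pair_scores, stack_bonus):
    pairset = set(pairs)
    total = 0.0
    for i, j in pairs:
        total += pair_scores.get(frozenset((seq[i], seq[j])), 0.0)
        if (i + 1, j - 1) in pairset:
            total += stack_bonus
    return total


PANEL = [
    "GGGAAACCC",
    "GCGCAAAAGCGC",
    "ATGGTACAAAGTACCA",
    "TTAGCCGAAATCGGCTAA",
    "ACGTACGTACGTACGT",
    "AAGGCTTAAAGCCTTCAA",
    "CAGTGCAAAAGCACTG",
    "TGCATTTTTAAAATGCA",
    "GTGTGAAAACACAC",
    "AATTAAGAATATAACAAC",
]


class TestFold:
    def test_perfect_mini_hairpin(self):
        fr = fold("GGGAAACCC")
        assert fr.structure == "(((...)))"
        assert fr.n_pairs == 3

    def test_unpairable_sequence_all_dots(self):
        fr = fold("AAAAAAAAA")
        assert fr.structure == "." * 9
        assert fr.n_pairs == 0

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            fold("ACGTXACGT")

    def test_structure_is_wellformed_and_energy_consistent(self):
        for seq in PANEL:
            fr = fold(seq)
            assert len(fr.structure) == len(seq)
            # balanced, non-crossing, min loop respected, pairs admissible
            stack = []
            for idx, c in enumerate(fr.structure):
                if c == "(":
                    stack.append(idx)
                elif c == ")":
                    i = stack.pop()
                    assert idx - i > 3
                    assert frozenset((seq[i], seq[idx])) in DEFAULT_PAIR_SCORES
            assert not stack
            # traceback structure realises the DP optimum
            assert score_structure(seq, fr.pairs, DEFAULT_PAIR_SCORES, 1.0) \
                == pytest.approx(-fr.energy)

    @pytest.mark.parametrize("seq", PANEL)
    def test_matches_bruteforce_enumeration(self, seq):
        """DP optimum equals exhaustive enumeration, for both the default
        stacking score and the plain maximum-pairing score."""
        structures = enumerate_structures(seq)
        for scores, stack in ((DEFAULT_PAIR_SCORES, 1.0), (MAXPAIR, 0.0)):
            fr = fold(seq, pair_scores=scores, stack_bonus=stack)
            best = max(score_structure(seq, s, scores, stack) for s in structures)
            assert -fr.energy == pytest.approx(best)
        # max pair count specifically
        fr = fold(seq, pair_scores=MAXPAIR, stack_bonus=0.0)
        assert fr.n_pairs == max(len(s) for s in structures)

    @given(st.text(alphabet="ACGT", min_size=5, max_size=40))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_revcomp_symmetry_watson_crick(self, seq):
        # mirror of a valid structure is valid with identical score, so the
        # optimal score is strand-symmetric; pair count is compared under
        # pure pair-count scoring where it equals the score
        assert fold(seq, pair_scores=WC_ONLY).energy \
            == pytest.approx(fold(revcomp(seq), pair_scores=WC_ONLY).energy)
        assert fold(seq, pair_scores=WC_ONLY, stack_bonus=0.0).n_pairs \
            == fold(revcomp(seq), pair_scores=WC_ONLY, stack_bonus=0.0).n_pairs

    @given(st.text(alphabet="ACGT", min_size=5, max_size=40))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_unpairable_padding_never_adds_pairs(self, seq):
        base = fold(seq)
        padded = fold(seq + "N" * 12)
        assert padded.n_pairs == base.n_pairs

    def test_deterministic(self):
        a, b = fold(PANEL[3]), fold(PANEL[3])
        assert a.structure == b.structure and a.energy == b.energy


class TestValidateHairpin:
    def test_perfect_duplex_passes(self):
        seq = perfect_precursor()
        fr = fold(seq)
        a = validate_hairpin(fr, (0, 21))
        assert a.passes
        assert a.matched_pairs == 21
        assert a.size_diff <= 2  # star carries the 2-nt 3' overhang extension
        # inferred star sits on the opposing arm, shifted by the 2-nt
        # 3' overhang rule relative to the raw reverse complement
        lo, hi = a.star_span
        true_lo = seq.find(revcomp(MATURE21))
        assert abs(lo - true_lo) <= 2 and abs(hi - (true_lo + 21)) <= 2

    @staticmethod
    def _synthetic_fold(n, duplex_pairs):
        """FoldResult with an explicit pairing, for criterion-boundary tests."""
        import numpy as np

        from mirseek.hairpin_fold import FoldResult

        partner = np.full(n, -1, dtype=np.int64)
        for i, j in duplex_pairs:
            partner[i], partner[j] = j, i
        structure = "".join(
            "." if partner[i] < 0 else ("(" if partner[i] > i else ")")
            for i in range(n)
        )
        pairs = tuple((i, j) for i, j in duplex_pairs)
        return FoldResult("A" * n, structure, 0.0, pairs, partner)

    def test_fifteen_matched_pairs_fail(self):
        # duplex with only 15 of 21 mature positions paired
        keep = [k for k in range(21) if k not in (4, 6, 8, 10, 12, 14)]
        fr = self._synthetic_fold(60, [(k, 56 - k) for k in keep])
        a = validate_hairpin(fr, (0, 21))
        assert not a.passes
        assert a.matched_pairs == 15
        assert a.reason == "too-few-matched-pairs"

    def test_sixteen_matched_pairs_pass_boundary(self):
        keep = [k for k in range(21) if k not in (4, 6, 8, 10, 12)]
        fr = self._synthetic_fold(60, [(k, 56 - k) for k in keep])
        assert validate_hairpin(fr, (0, 21)).passes

    def test_oversized_star_fails_on_size_diff(self):
        # mature 21 nt against a 26-nt star arm (5-nt asymmetric bulge)
        pairs = [(k, 56 - k) for k in range(10)] + [(k, 51 - k) for k in range(10, 19)]
        fr = self._synthetic_fold(60, pairs)
        a = validate_hairpin(fr, (0, 21), diag_tol=8)
        assert not a.passes
        assert a.reason == "size-diff"
        assert a.size_diff > 4

    def test_mature_straddling_loop_fails_arm_in_loop(self):
        seq = perfect_precursor()
        a = validate_hairpin(fold(seq), (12, 42))
        assert not a.passes
        assert a.reason == "arm-in-loop"

    def test_unpaired_arm_reported(self):
        seq = "GGGGGGGG" + "AAACAAACAAACAAAAAACAAACAAAC" + "CCCCCCCC"
        a = validate_hairpin(fold(seq), (10, 30))
        assert not a.passes
        assert a.reason in ("unpaired-arm", "too-few-matched-pairs")

    def test_planted_mirs_pass_and_shuffled_fail(self, small_bundle, rng):
        from mirseek.synthetic_data import dinucleotide_shuffle

        _, _, truth, _ = small_bundle
        n_shuffle_pass = n_shuffle = 0
        for mir in truth.mirs:
            seq = mir.precursor_seq
            off = seq.find(mir.mature_seq)
            assert validate_hairpin(fold(seq), (off, off + len(mir.mature_seq))).passes
            for _ in range(3):
                shuffled = dinucleotide_shuffle(seq, rng)
                a = validate_hairpin(
                    fold(shuffled), (off, off + len(mir.mature_seq))
                )
                n_shuffle += 1
                n_shuffle_pass += a.passes
        assert n_shuffle_pass / n_shuffle < 0.10


class FakeWindow:
    def __init__(self, seq):
        self.seq = seq


class TestBestPrecursor:
    def test_single_passing_window_returned(self):
        win = FakeWindow(perfect_precursor())
        best = best_precursor([win], MATURE21)
        assert best is not None and best.window is win

    def test_lowest_energy_window_wins(self):
        strong = "GGG" + perfect_precursor() + "CCC"  # extra closing helix
        weak = perfect_precursor()
        best = best_precursor([FakeWindow(weak), FakeWindow(strong)], MATURE21)
        assert best.window.seq == strong

    def test_none_when_nothing_passes(self):
        assert best_precursor([FakeWindow("A" * 60 + MATURE21 + "A" * 60)],
                              MATURE21) is None

    def test_planted_hairpin_length_close_to_truth(self, small_bundle):
        """On the excised true precursor the trimmed stem-loop span matches
        the planted length; in full genomic windows occasional stem
        extensions through flanking sequence are tolerated."""
        from mirseek.genome_scan import excise_windows, map_tags
        from mirseek.preprocess import UniqueTag

        _, genome, truth, _ = small_bundle
        n_close = 0
        for mir in truth.mirs:
            exact = best_precursor([FakeWindow(mir.precursor_seq)], mir.mature_seq)
            assert exact is not None
            assert abs(exact.hairpin_len - mir.precursor_len) <= 10
            (ls,) = map_tags([UniqueTag(mir.mature_seq, 1)], genome)
            windows = [w for h in ls.hits for w in excise_windows(h, genome)]
            in_genome = best_precursor(windows, mir.mature_seq)
            assert in_genome is not None
            n_close += abs(in_genome.hairpin_len - mir.precursor_len) <= 10
        assert n_close >= 0.7 * len(truth.mirs)
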