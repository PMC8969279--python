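"""Consensus scanning, hairpin folding, and site calling."""

import itertools

import numpy as np
import pytest

from riddmap import stemloop
from riddmap.stemloop import (
    PAIR_SCORES,
    Hairpin,
    call_sites,
    dinucleotide_shuffle,
    fold_hairpin,
    pair_sites,
    scan_consensus,
    validate_hairpin,
)


class TestScan:
    def test_single_match(self):
        assert scan_consensus("AAACUGCAGAAA") == [4]

    def test_adjacent_matches(self):
        assert scan_consensus("CUGCAGCUGCAG") == [1, 7]

    def test_overlapping_matches_allowed(self):
        assert scan_consensus("CUGCUGCAGCAG") == [4]

    def test_no_match(self):
        assert scan_consensus("AAAAAAAA") == []

    def test_dna_converted_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert scan_consensus("AAACTGCAGAAA") == [4]
        assert "converting" in caplog.text

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            scan_consensus("ACGUN")


PLANTED = "AAAA" + "G" * 6 + "ACUGCAG" + "C" * 6 + "AAAA"


class TestFold:
    def test_worked_planted_hairpin(self):
        """Six G-C pairs and a 7-nt loop: energy 6*(-3) + 0.5*3 = -16.5."""
        pos = scan_consensus(PLANTED)[0]
        h = fold_hairpin(PLANTED, pos)
        assert h is not None
        assert h.energy == pytest.approx(-16.5)
        assert h.structure == "((((((.......))))))"
        assert h.stem_len == 6 and h.loop_len == 7

    def test_unstructured_context_gives_none(self):
        seq = "A" * 20 + "CUGCAG" + "A" * 20
        assert fold_hairpin(seq, 21) is None

    def test_lower_energy_stem_preferred(self):
        # two possible stems close the same loop: 4 A-U pairs vs 4 G-C pairs
        au = "UUUU" + "ACUGCAGA" + "AAAA"
        gc = "GGGG" + "ACUGCAGA" + "CCCC"
        h_au = fold_hairpin("AAA" + au + "AAA", scan_consensus(au)[0] + 3)
        h_gc = fold_hairpin("AAA" + gc + "AAA", scan_consensus(gc)[0] + 3)
        assert h_gc.energy < h_au.energy

    def test_scissile_guanine_inside_loop(self):
        pos = scan_consensus(PLANTED)[0]
        h = fold_hairpin(PLANTED, pos)
        g = pos + 2
        assert h.loop_start <= g <= h.loop_end

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        alphabet = np.array(list("ACGU"))
        for _ in range(15):
            n = int(rng.integers(20, 81))
            seq = "".join(rng.choice(alphabet, size=n))
            insert = int(rng.integers(0, n - 6))
            seq = seq[:insert] + "CUGCAG" + seq[insert + 6:]
            for pos in scan_consensus(seq):
                got = fold_hairpin(seq, pos)
                want = brute_force_fold(seq, pos)
                if want is None:
                    assert got is None
                else:
                    assert got is not None
                    assert got.energy == pytest.approx(want.energy)
                    assert (got.loop_start, got.loop_len) == (
                        want.loop_start, want.loop_len)

    @pytest.mark.parametrize("seed", range(4))
    def test_reported_structures_revalidate(self, seed):
        rng = np.random.default_rng(200 + seed)
        alphabet = np.array(list("ACGU"))
        for _ in range(20):
            seq = "".join(rng.choice(alphabet, size=70))
            for pos in scan_consensus(seq):
                h = fold_hairpin(seq, pos)
                if h is None:
                    continue
                assert validate_hairpin(seq, h) == pytest.approx(h.energy, abs=1e-9)
                assert h.structure.count("(") == h.structure.count(")")


def brute_force_fold(seq, match_pos, window=30, min_stem=4, loop_range=(4, 12)):
    """Independent exhaustive enumeration of every admissible hairpin."""
    L = len(seq)
    g = match_pos + 2
    win_lo, win_hi = max(1, match_pos - window), min(L, match_pos + 5 + window)
    candidates = []
    for loop_len, loop_start in itertools.product(
        range(loop_range[0], loop_range[1] + 1), range(1, L + 1)
    ):
        loop_end = loop_start + loop_len - 1
        if not (loop_start <= g <= loop_end):
            continue
        for s in range(min_stem, L):
            i, j = loop_start - s, loop_end + s
            if i < win_lo or j > win_hi:
                break
            pairs = [(seq[loop_start - 2 - t], seq[loop_end + t]) for t in range(s)]
            if any(p not in PAIR_SCORES for p in pairs):
                break
            energy = sum(PAIR_SCORES[p] for p in pairs) + 0.5 * max(0, loop_len - 4)
            candidates.append(Hairpin(loop_start, loop_len, s, energy))
    if not candidates:
        return None
    return min(candidates, key=lambda h: (h.energy, h.loop_len, h.loop_start))


class TestCallSites:
    def test_window_without_consensus_gives_no_call(self):
        seqs = {"t1": "A" * 200}
        assert call_sites([("g1", "t1", (50, 150))], seqs) == []

    def test_match_outside_window_needs_permissive_flag(self):
        seq = "A" * 100 + PLANTED + "A" * 100
        pos = scan_consensus(seq)[0]
        seqs = {"t1": seq}
        windows = [("g1", "t1", (1, 50))]
        assert call_sites(windows, seqs) == []
        calls = call_sites(windows, seqs, permissive=True)
        assert len(calls) == 1 and not calls[0].in_window
        assert calls[0].cleavage_after == pos + 2

    def test_planted_site_called_exactly(self):
        seq = "A" * 100 + PLANTED + "A" * 100
        pos = scan_consensus(seq)[0]
        calls = call_sites([("g1", "t1", (pos - 20, pos + 20))], {"t1": seq})
        assert len(calls) == 1
        assert calls[0].in_window and calls[0].cleavage_after == pos + 2

    def test_empty_sequence_skipped(self, caplog):
        with caplog.at_level("WARNING"):
            assert call_sites([("g1", "t1", (1, 10))], {"t1": ""}) == []
        assert "empty sequence" in caplog.text


class TestPairSites:
    def _call(self, cut, tx="t1"):
        h = Hairpin(cut - 2, 5, 4, -10.0)
        return stemloop.CleavageSiteCall("g", tx, cut - 2, cut, h, True)

    def test_nearby_sites_grouped(self):
        groups = pair_sites([self._call(400), self._call(460)])
        assert len(groups) == 1 and len(groups[0]) == 2

    def test_distant_sites_split(self):
        groups = pair_sites([self._call(400), self._call(900)])
        assert len(groups) == 2

    def test_empty_input(self):
        assert pair_sites([]) == []


class TestShuffle:
    def test_preserves_dinucleotide_counts(self):
        from collections import Counter

        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGU"), size=120))
        shuf = dinucleotide_shuffle(seq, rng)
        assert Counter(zip(shuf[:-1], shuf[1:])) == Counter(zip(seq[:-1], seq[1:]))
        assert shuf[0] == seq[0] and shuf[-1] == seq[-1]

    def test_actually_shuffles(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGU"), size=200))
        assert dinucleotide_shuffle(seq, rng) != seq
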