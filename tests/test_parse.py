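"""Prefix-free parsing: trigger scan, dictionary/parse, round trip, pattern scan."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pfpfm as pf
from conftest import (EXAMPLE_DICT, EXAMPLE_PARSE, EXAMPLE_QUERY,
                      EXAMPLE_TEXT, random_text)


def brute_force_parse(text, policy):
    """Independent oracle: enumerate cyclic windows, mark triggers, cut phrases."""
    n = len(text)
    w = policy.w
    ext = text + text[: w - 1]
    pos = [i for i in range(n - 1) if policy.is_trigger(ext[i : i + w])] + [n - 1]
    big = text * 2 + text[:w]
    order = [n - 1] + pos[:-1]
    phrases = []
    for i, s in enumerate(order):
        e = order[(i + 1) % len(order)]
        if e <= s:
            e += n
        phrases.append(big[s : e + w])
    dictionary = tuple(sorted(set(phrases), key=pf.parse.lex_key))
    return dictionary, [dictionary.index(ph) for ph in phrases], pos


class TestTriggerPositions:
    def test_worked_example_positions(self, example_policy):
        got = pf.trigger_positions(EXAMPLE_TEXT, example_policy)
        assert list(got) == [5, 10, 18, 28, 34, 40]

    def test_empty_explicit_set_keeps_only_terminator_window(self):
        pol = pf.TriggerPolicy(w=2, mode="explicit")
        assert list(pf.trigger_positions("ACGT$", pol)) == [4]

    def test_hashed_mode_is_deterministic(self, rng):
        text = random_text(rng, 300)
        pol = pf.TriggerPolicy.hashed(w=3, p=7, hash_seed=5)
        a = pf.trigger_positions(text, pol)
        b = pf.trigger_positions(text, pol)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("bad", ["ACGT", "AC$GT$", "$ACGT"])
    def test_invalid_terminator_rejected(self, bad, example_policy):
        with pytest.raises(pf.InputError):
            pf.trigger_positions(bad, example_policy)

    def test_no_window_other_than_terminator_contains_dollar(self, rng):
        text = random_text(rng, 200)
        pol = pf.TriggerPolicy.hashed(w=4, p=2)
        pos = pf.trigger_positions(text, pol)
        n = len(text)
        for i in pos[:-1]:
            assert "$" not in (text + text[:3])[i : i + 4]
        assert pos[-1] == n - 1


class TestBuildParse:
    def test_worked_example_dictionary_and_parse(self, example_parse):
        assert example_parse.dictionary == EXAMPLE_DICT
        assert tuple(example_parse.parse) == EXAMPLE_PARSE

    def test_single_cyclic_phrase(self):
        pol = pf.TriggerPolicy(w=2, mode="explicit")
        pr = pf.build_parse("ACGT$", pol)
        assert pr.dictionary == ("$ACGT$A",)
        assert list(pr.parse) == [0]

    @pytest.mark.parametrize("w,p", [(2, 3), (3, 5), (4, 11), (5, 2)])
    def test_matches_brute_force_oracle(self, rng, w, p):
        for _ in range(10):
            text = random_text(rng, int(rng.integers(w + 1, 500)))
            pol = pf.TriggerPolicy.hashed(w=w, p=p, hash_seed=3)
            pr = pf.build_parse(text, pol)
            d, parse, pos = brute_force_parse(text, pol)
            assert pr.dictionary == d
            assert list(pr.parse) == parse
            assert list(pr.trigger_positions) == pos

    def test_dictionary_is_prefix_free(self, rng):
        for _ in range(20):
            text = random_text(rng, int(rng.integers(20, 400)))
            pol = pf.TriggerPolicy.hashed(w=2, p=int(rng.integers(1, 8)))
            d = pf.build_parse(text, pol).dictionary
            for i, a in enumerate(d):
                for j, b in enumerate(d):
                    if i != j:
                        assert not b.startswith(a)

    def test_parse_length_equals_trigger_occurrences(self, rng):
        text = random_text(rng, 250)
        pol = pf.TriggerPolicy.hashed(w=3, p=4)
        pr = pf.build_parse(text, pol)
        assert len(pr.parse) == len(pr.trigger_positions)

    def test_every_phrase_bracketed_by_triggers_with_none_inside(self, rng):
        text = random_text(rng, 300)
        pol = pf.TriggerPolicy.hashed(w=2, p=5)
        pr = pf.build_parse(text, pol)
        w = pol.w
        for ph in pr.dictionary:
            inner = [i for i in range(len(ph) - w + 1)
                     if pf.TERMINATOR not in ph[i:i + w] and pol.is_trigger(ph[i:i + w])]
            # triggers occur exactly at both ends (terminator windows aside)
            assert all(i == 0 or i == len(ph) - w for i in inner)

    def test_degenerate_p1_phrase_lengths(self, rng):
        # every window is a trigger, so every phrase has length w + 1 —
        # except the single phrase crossing the terminator seam (length 2w),
        # because windows containing $ are never ordinary triggers
        text = random_text(rng, 100)
        pol = pf.TriggerPolicy.hashed(w=2, p=1)
        pr = pf.build_parse(text, pol)
        lengths = sorted(len(pr.dictionary[r]) for r in pr.parse)
        assert lengths[:-1] == [3] * (len(lengths) - 1)
        assert lengths[-1] == 4

    def test_explicit_and_hashed_modes_agree(self, rng):
        text = random_text(rng, 400)
        hashed = pf.TriggerPolicy.hashed(w=3, p=4, hash_seed=9)
        windows = {text[i:i + 3] for i in range(len(text) - 3)}
        chosen = {win for win in windows if hashed.is_trigger(win)}
        explicit = pf.TriggerPolicy.explicit(chosen, w=3)
        a = pf.build_parse(text, hashed)
        b = pf.build_parse(text, explicit)
        assert a.dictionary == b.dictionary
        assert np.array_equal(a.parse, b.parse)


class TestReconstruct:
    def test_worked_example_round_trip(self, example_parse):
        assert pf.reconstruct_text(example_parse) == EXAMPLE_TEXT

    def test_single_phrase_round_trip(self):
        pol = pf.TriggerPolicy(w=2, mode="explicit")
        assert pf.reconstruct_text(pf.build_parse("ACGT$", pol)) == "ACGT$"

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(body=st.text(alphabet="ACGT", min_size=4, max_size=200),
           w=st.integers(2, 5), p=st.integers(1, 12))
    def test_round_trip_identity_property(self, body, w, p):
        text = body + "$"
        pol = pf.TriggerPolicy.hashed(w=w, p=p)
        assert pf.reconstruct_text(pf.build_parse(text, pol)) == text

    def test_inconsistent_overlap_raises_corruption(self, example_parse):
        broken = pf.ParseResult(dictionary=example_parse.dictionary,
                                parse=example_parse.parse[::-1].copy(),
                                trigger_positions=example_parse.trigger_positions,
                                w=example_parse.w, n=example_parse.n)
        with pytest.raises(pf.CorruptionError):
            pf.reconstruct_text(broken)


class TestScanPattern:
    def test_worked_example_decomposition(self, example_policy):
        dec = pf.scan_pattern(EXAMPLE_QUERY, example_policy)
        assert dec.alpha == "CAGAA"
        assert dec.phrase_strings == ("AAGAGTA", "TATCTCCTCG",
                                      "CGACATGTTGAA", "AAGACATA")
        assert dec.beta == "TAT"

    def test_no_trigger_pattern(self, example_policy):
        dec = pf.scan_pattern("GGGG", example_policy)
        assert not dec.has_trigger and dec.alpha == "GGGG"
        assert dec.phrase_strings == () and dec.beta == ""

    def test_single_trigger_pattern_alpha_and_beta_share_it(self, example_policy):
        dec = pf.scan_pattern("AA", example_policy)
        assert dec.has_trigger
        assert dec.alpha == "AA" and dec.beta == "AA" and dec.phrase_strings == ()

    def test_overlap_collapsed_concatenation_equals_pattern(self, rng, example_policy):
        text = EXAMPLE_TEXT
        for _ in range(50):
            m = int(rng.integers(1, 30))
            s = int(rng.integers(0, len(text) - 1 - m))
            q = text[s : s + m]
            dec = pf.scan_pattern(q, example_policy)
            pieces = [x for x in (dec.alpha, *dec.phrase_strings, dec.beta) if x]
            rebuilt = pieces[0]
            for piece in pieces[1:]:
                assert rebuilt[-dec.w:] == piece[: dec.w]
                rebuilt += piece[dec.w:]
            assert rebuilt == q

    def test_substring_phrases_are_dictionary_members(self, rng):
        text = random_text(rng, 400)
        pol = pf.TriggerPolicy.hashed(w=3, p=3)
        d = set(pf.build_parse(text, pol).dictionary)
        for _ in range(60):
            m = int(rng.integers(10, 80))
            s = int(rng.integers(0, len(text) - 1 - m))
            dec = pf.scan_pattern(text[s : s + m], pol)
            assert all(ph in d for ph in dec.phrase_strings)


class TestPhraseStats:
    def test_worked_example_stats(self, example_parse):
        st_ = pf.phrase_stats(example_parse)
        assert st_.n_occurrences == 6 and st_.n_distinct == 6
        # phrase lengths in parse order: 8, 7, 10, 12, 8, 8
        assert st_.mean_length == pytest.approx(53 / 6)
        assert (st_.min_length, st_.max_length) == (7, 12)

    def test_single_phrase_average(self):
        pol = pf.TriggerPolicy(w=2, mode="explicit")
        assert pf.phrase_stats(pf.build_parse("ACGT$", pol)).mean_length == 7

    def test_matches_brute_force_lengths(self, rng):
        text = random_text(rng, 300)
        pol = pf.TriggerPolicy.hashed(w=2, p=4)
        pr = pf.build_parse(text, pol)
        lengths = [len(pr.dictionary[r]) for r in pr.parse]
        st_ = pf.phrase_stats(pr)
        assert st_.mean_length == pytest.approx(sum(lengths) / len(lengths))
        assert st_.n_occurrences == len(lengths)
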