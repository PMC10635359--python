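"""The two-level accelerated FM-index over a prefix-free parse.

The index bundles an FM-index over the characters of S, an FM-index over
the phrase IDs of the parse P, a bitvector B marking (among the
lexicographically sorted rotations of S) those that start at a trigger
occurrence, and a fingerprint map M from phrases to their dictionary
ranks.  Because phrase IDs inherit the lexicographic order of their
phrases and the dictionary is prefix-free, the i-th marked rotation of S
corresponds to the i-th smallest rotation of P, so rank/select on B
bridges character-level and phrase-level BWT intervals.

A count query backward-searches character by character only at the
pattern's two ends (the suffix beta and the prefix alpha of its
decomposition) and phrase by phrase in the middle, touching the character
index once per end character instead of once per pattern character.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, Optional, Tuple

import numpy as np

from .errors import ContractError, InputError
from .fm import EMPTY_INTERVAL, FMIndex, Interval, IntText
from .parse import (KR_MODULUS, TERMINATOR, ParseResult, TriggerPolicy,
                    build_parse, derive_base, kr_fingerprint, lex_key,
                    scan_pattern)


class MarkBitvector:
    """Length-n bits with rank/select; bit r marks the rank-r rotation of S
    that starts at a trigger occurrence.

    rank(i) counts set bits strictly before i; select(j) is 1-indexed.
    """

    def __init__(self, n: int, marked_ranks: np.ndarray):
        self.n = int(n)
        bits = np.zeros(self.n, dtype=np.uint8)
        bits[np.asarray(marked_ranks, dtype=np.int64)] = 1
        self.bits = bits
        self._prefix = np.concatenate(([0], np.cumsum(bits, dtype=np.int64)))
        self._positions = np.flatnonzero(bits).astype(np.int64)

    @property
    def popcount(self) -> int:
        return int(self._positions.size)

    def rank(self, i: int) -> int:
        """Number of set bits in bits[0..i-1]."""
        if not 0 <= i <= self.n:
            raise ContractError(f"rank index {i} out of range [0, {self.n}]")
        return int(self._prefix[i])

    def select(self, j: int) -> int:
        """Position of the j-th set bit (1-indexed)."""
        if not 1 <= j <= self.popcount:
            raise ContractError(f"select index {j} out of range [1, {self.popcount}]")
        return int(self._positions[j - 1])

    def runs_of_ones(self) -> int:
        b = self.bits
        return int(b[0]) + int(np.count_nonzero((b[1:] == 1) & (b[:-1] == 0)))


class PhraseMap:
    """Fingerprint map M from phrases to dictionary ranks, with stored
    phrases for exact character-by-character verification.

    Lookups of strings outside the dictionary return None — exactly, not
    just with high probability, because every hit is verified against the
    stored phrase.  If two dictionary phrases ever collide under the
    fingerprint, the map is rebuilt with a re-derived base.
    """

    def __init__(self, phrases: Tuple[str, ...], fp_seed: int, base: int,
                 table: Dict[int, int]):
        self.phrases = phrases
        self.fp_seed = fp_seed
        self._base = base
        self._table = table

    @classmethod
    def build(cls, phrases: Iterable[str], fp_seed: int = 2) -> "PhraseMap":
        phrases = tuple(phrases)
        seed = fp_seed
        while True:
            base = derive_base(seed)
            table: Dict[int, int] = {}
            ok = True
            for rank, ph in enumerate(phrases):
                fp = kr_fingerprint(ph, base)
                if fp in table:
                    ok = False
                    break
                table[fp] = rank
            if ok:
                return cls(phrases, seed, base, table)
            seed += 1  # collision among dictionary phrases: re-derive the base

    def lookup(self, phrase: str) -> Optional[int]:
        rank = self._table.get(kr_fingerprint(phrase, self._base))
        if rank is None or self.phrases[rank] != phrase:
            return None
        return rank

    def stored_phrase(self, rank: int) -> str:
        return self.phrases[rank]

    def __len__(self) -> int:
        return len(self.phrases)


@dataclass(frozen=True)
class PartialEncoding:
    """A query as (prefix alpha, complete-phrase ID sequence, suffix beta)."""

    alpha: str
    phrase_ids: tuple
    beta: str
    has_trigger: bool


@dataclass
class QueryStats:
    """Backward-search steps spent at each level during one count query."""

    char_steps: int = 0
    phrase_steps: int = 0


class PFPFMIndex:
    """The bundle {FM(S), FM(P), B, M, policy} answering count queries."""

    FORMAT_VERSION = 1

    def __init__(self, fm_s: FMIndex, fm_p: FMIndex, b: MarkBitvector,
                 m: PhraseMap, policy: TriggerPolicy, alphabet: Dict[str, int],
                 parse_result: Optional[ParseResult] = None):
        self.fm_s = fm_s
        self.fm_p = fm_p
        self.b = b
        self.m = m
        self.policy = policy
        self.alphabet = alphabet
        self.parse_result = parse_result
        if b.n != fm_s.n:
            raise ContractError("bitvector length disagrees with |S|")
        if b.popcount != fm_p.n:
            raise ContractError("popcount(B) disagrees with |P|")
        if fm_p.sigma != len(m):
            raise ContractError("phrase alphabet size disagrees with |D|")

    # -- construction ------------------------------------------------------

    @classmethod
    def build(cls, text: str, policy: TriggerPolicy,
              keep_parse: bool = True) -> "PFPFMIndex":
        pr = build_parse(text, policy)
        n = pr.n
        alphabet = {TERMINATOR: 0}
        for i, ch in enumerate(sorted(set(text) - {TERMINATOR})):
            alphabet[ch] = i + 1
        s_int = IntText(np.asarray([alphabet[c] for c in text], dtype=np.int64),
                        sigma=len(alphabet))
        fm_s = FMIndex.build(s_int, keep_sa=True)
        # B: mark the suffix-array rank of the rotation starting at every
        # trigger occurrence (suffix order == rotation order, $ unique smallest)
        inv_sa = np.empty(n, dtype=np.int64)
        inv_sa[fm_s.sa] = np.arange(n, dtype=np.int64)
        b = MarkBitvector(n, inv_sa[pr.trigger_positions])
        # FM over the parse: P starts with the unique 0 (terminator phrase);
        # rotate it to the end so the one SA routine applies to P as well
        p_rot = np.concatenate((pr.parse[1:], pr.parse[:1]))
        fm_p = FMIndex.build(IntText(p_rot, sigma=len(pr.dictionary)))
        m = PhraseMap.build(pr.dictionary)
        return cls(fm_s, fm_p, b, m, policy, alphabet,
                   parse_result=pr if keep_parse else None)

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        return self.fm_s.n

    @property
    def n_phrases(self) -> int:
        return self.fm_p.n

    @property
    def n_distinct_phrases(self) -> int:
        return len(self.m)

    def _sym(self, ch: str) -> int:
        return self.alphabet.get(ch, -1)

    def _syms(self, s: str) -> list:
        return [self._sym(c) for c in s]

    # -- level bridging ----------------------------------------------------

    def char_to_phrase(self, iv: Interval) -> Interval:
        """Map a character-level interval of trigger-starting rotations to
        the corresponding phrase-level interval (rank on B); size-preserving.
        """
        if iv.is_empty:
            return EMPTY_INTERVAL
        marked = self.b.rank(iv.hi + 1) - self.b.rank(iv.lo)
        if marked != iv.size:
            raise ContractError(
                "char_to_phrase called on an interval containing unmarked rows")
        return Interval(self.b.rank(iv.lo), self.b.rank(iv.hi))

    def phrase_to_char(self, iv: Interval) -> Interval:
        """Map a phrase-level interval back to character level (1-indexed
        select on B); size-preserving given the rotations share a trigger.
        """
        if iv.is_empty:
            return EMPTY_INTERVAL
        return Interval(self.b.select(iv.lo + 1), self.b.select(iv.hi + 1))

    # -- query -------------------------------------------------------------

    def encode_query(self, pattern: str) -> Optional[PartialEncoding]:
        """Partial encoding of a pattern, or None if some complete phrase
        of the pattern is absent from the dictionary (whence count 0).

        Phrase lookups are verified character by character against the
        stored phrases, so None-on-absent-phrase is exact.
        """
        dec = scan_pattern(pattern, self.policy)
        if not dec.has_trigger:
            return PartialEncoding(alpha=dec.alpha, phrase_ids=(), beta="",
                                   has_trigger=False)
        ids = []
        for ph in dec.phrase_strings:
            rank = self.m.lookup(ph)
            if rank is None:
                return None
            ids.append(rank)
        return PartialEncoding(alpha=dec.alpha, phrase_ids=tuple(ids),
                               beta=dec.beta, has_trigger=True)

    def count(self, pattern: str) -> int:
        """Number of occurrences of ``pattern`` in the indexed text
        (terminator excluded from matches)."""
        return self.count_with_stats(pattern)[0]

    def count_with_stats(self, pattern: str) -> Tuple[int, QueryStats]:
        if not pattern:
            raise InputError("pattern must be non-empty")
        s0, p0 = self.fm_s.steps, self.fm_p.steps
        cnt = self._count(pattern)
        stats = QueryStats(char_steps=self.fm_s.steps - s0,
                           phrase_steps=self.fm_p.steps - p0)
        return cnt, stats

    def _count(self, pattern: str) -> int:
        w = self.policy.w
        if TERMINATOR in pattern:
            return 0
        enc = self.encode_query(pattern)
        if enc is None:
            return 0
        if not enc.has_trigger:
            return self.fm_s.backward_search(self._syms(pattern)).size
        if enc.beta:
            iv = self.fm_s.backward_search(self._syms(enc.beta))
            if iv.is_empty:
                return 0
            if not enc.phrase_ids:
                # single trigger occurrence: the char->phrase->char round
                # trip is the identity on beta's (all-marked) interval, so
                # continue the character-level search directly
                return self.fm_s.backward_search(self._syms(enc.alpha[:-w]),
                                                 start=iv).size
            piv = self.char_to_phrase(iv)
        else:
            # pattern ends with a trigger: beta is empty and the phrase
            # search starts from the full phrase-level interval
            piv = self.fm_p.full_interval()
        piv = self.fm_p.backward_search(enc.phrase_ids, start=piv)
        if piv.is_empty:
            return 0
        if not enc.alpha:
            return piv.size  # mappings preserve size; the level is irrelevant
        civ = self.phrase_to_char(piv)
        return self.fm_s.backward_search(self._syms(enc.alpha[:-w]), start=civ).size

    def count_many(self, patterns: Iterable[str]) -> Iterator[Tuple[str, int]]:
        """Stream (pattern, count) pairs for a batch of patterns."""
        for q in patterns:
            yield q, self.count(q)


def build_index(text: str, policy: TriggerPolicy, keep_parse: bool = True) -> PFPFMIndex:
    """Functional alias for :meth:`PFPFMIndex.build`."""
    return PFPFMIndex.build(text, policy, keep_parse=keep_parse)
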