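"""Prefix-free parsing of terminated texts and of query patterns.

A text ``S`` of length n ends with a unique terminator ``$`` that sorts
below every other symbol, and is read cyclically.  A *trigger string* is a
length-w window selected either by a Karp-Rabin rolling-hash condition
(``f(window) mod p == 0``) or by membership in an explicit set; the window
starting at the terminator position (``$`` followed by the first w-1 text
characters) is always a trigger.  Consecutive trigger occurrences delimit
*phrases* that include both delimiting triggers and therefore overlap by w
characters.  The distinct phrases, lexicographically sorted with ``$``
smallest, form the dictionary D; because every phrase starts and ends with
a trigger and contains no other, D is prefix-free.  The parse P lists the
dictionary rank of each phrase occurrence, starting from the phrase that
begins at the terminator window.

Query patterns are scanned with the same trigger policy but are neither
cyclic nor terminated, which yields the (alpha, complete phrases, beta)
decomposition used by the two-level index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import CorruptionError, InputError

TERMINATOR = "$"
#: Symbols reserved by the parsing convention; never part of the alphabet.
RESERVED_SYMBOLS = frozenset({"$", "#"})

#: Karp-Rabin modulus: the Mersenne prime 2^61 - 1.
KR_MODULUS = (1 << 61) - 1
_MIX_MULT = 6364136223846793005
_MIX_INC = 1442695040888963407
_MASK64 = (1 << 64) - 1

# translation table making the terminator compare below every other symbol
_SORT_TRANS = {ord(TERMINATOR): 0}


def lex_key(s: str) -> str:
    """Sort key under which ``$`` is smaller than any alphabet symbol."""
    return s.translate(_SORT_TRANS)


def derive_base(seed: int) -> int:
    """Deterministically derive a Karp-Rabin base in [256, KR_MODULUS) from a seed."""
    x = (seed * _MIX_MULT + _MIX_INC) & _MASK64
    return 256 + x % (KR_MODULUS - 512)


def kr_fingerprint(s: str, base: int, mod: int = KR_MODULUS) -> int:
    """Polynomial rolling hash of ``s``: sum of ord(s[i]) * base^(len-1-i) mod ``mod``."""
    h = 0
    for ch in s:
        h = (h * base + ord(ch)) % mod
    return h


@dataclass(frozen=True)
class TriggerPolicy:
    """Fully determines trigger membership for any length-w window.

    Parameters
    ----------
    w:
        Window (trigger-string) length, at least 2.
    mode:
        ``"hashed"`` (Karp-Rabin condition ``f(window) mod p == 0``) or
        ``"explicit"`` (membership in ``explicit_set``).
    p:
        Hash modulus in hashed mode; larger p selects fewer windows and
        yields longer phrases on average.  ``p = 1`` makes every window a
        trigger (phrases of length w + 1 everywhere).
    hash_seed:
        Seed from which the rolling-hash base is derived; stored so that
        index-time and query-time parsing always agree.
    explicit_set:
        The trigger strings in explicit mode; each has length exactly w and
        contains no reserved symbol.
    excluded_chars:
        Windows containing any of these characters are never triggers
        (except the mandatory terminator window handled by the scanner).
    """

    w: int
    mode: str = "hashed"
    p: int = 1
    hash_seed: int = 1
    explicit_set: frozenset = frozenset()
    excluded_chars: frozenset = RESERVED_SYMBOLS

    def __post_init__(self) -> None:
        if self.w < 2:
            raise InputError(f"window length w must be >= 2, got {self.w}")
        if self.mode not in ("hashed", "explicit"):
            raise InputError(f"unknown trigger mode {self.mode!r}")
        if self.mode == "hashed" and self.p < 1:
            raise InputError(f"hash modulus p must be >= 1, got {self.p}")
        for t in self.explicit_set:
            if len(t) != self.w:
                raise InputError(f"explicit trigger {t!r} does not have length w={self.w}")
            if set(t) & RESERVED_SYMBOLS:
                raise InputError(f"explicit trigger {t!r} contains a reserved symbol")

    @classmethod
    def hashed(cls, w: int, p: int, hash_seed: int = 1, excluded_chars: Iterable[str] = ()) -> "TriggerPolicy":
        return cls(w=w, mode="hashed", p=p, hash_seed=hash_seed,
                   excluded_chars=RESERVED_SYMBOLS | frozenset(excluded_chars))

    @classmethod
    def explicit(cls, triggers: Iterable[str], w: int | None = None,
                 excluded_chars: Iterable[str] = ()) -> "TriggerPolicy":
        triggers = frozenset(triggers)
        if w is None:
            lengths = {len(t) for t in triggers}
            if len(lengths) != 1:
                raise InputError("cannot infer w from an empty or mixed-length trigger set")
            (w,) = lengths
        return cls(w=w, mode="explicit", explicit_set=triggers,
                   excluded_chars=RESERVED_SYMBOLS | frozenset(excluded_chars))

    @property
    def base(self) -> int:
        return derive_base(self.hash_seed)

    def is_trigger(self, window: str) -> bool:
        """Decide trigger membership for a single length-w window (non-cyclic)."""
        if len(window) != self.w or set(window) & self.excluded_chars:
            return False
        if self.mode == "explicit":
            return window in self.explicit_set
        return kr_fingerprint(window, self.base) % self.p == 0


@dataclass(frozen=True)
class ParseResult:
    """Dictionary + parse of one text under one trigger policy.

    ``dictionary`` is the lexicographically sorted tuple of distinct
    phrases; ``parse`` lists dictionary ranks in text order starting from
    the terminator-window phrase; ``trigger_positions`` are the 0-based
    cyclic start positions of all trigger occurrences (ascending, always
    containing n - 1).
    """

    dictionary: tuple
    parse: np.ndarray
    trigger_positions: np.ndarray
    w: int
    n: int

    @property
    def phrases_in_order(self) -> list:
        return [self.dictionary[r] for r in self.parse]


@dataclass(frozen=True)
class PatternDecomposition:
    """A pattern split as prefix alpha, complete phrases, suffix beta.

    Consecutive pieces overlap by exactly w characters; collapsing the
    overlaps reconstructs the pattern.  With no trigger in the pattern,
    ``alpha`` is the whole pattern and the rest is empty.  With exactly one
    trigger occurrence (at position t) there is no complete phrase and both
    alpha = pattern[:t+w] and beta = pattern[t:] contain the trigger.
    """

    alpha: str
    phrase_strings: tuple
    beta: str
    has_trigger: bool
    w: int


def _validate_terminated(text: str, w: int) -> int:
    n = len(text)
    if n < w:
        raise InputError(f"text of length {n} is shorter than the window length w={w}")
    if not text.endswith(TERMINATOR):
        raise InputError("text must end with the terminator '$'")
    if text.count(TERMINATOR) != 1:
        raise InputError("terminator '$' must occur exactly once, at the end")
    return n


def trigger_positions(text: str, policy: TriggerPolicy) -> np.ndarray:
    """All cyclic start positions of trigger windows in a terminated text.

    The terminator window at position n - 1 (``$`` plus the first w - 1
    characters) is always included; no other reported window contains a
    reserved or excluded character.
    """
    n = _validate_terminated(text, policy.w)
    w = policy.w
    ext = text + text[: w - 1]
    out = []
    if policy.mode == "explicit":
        for i in range(n - 1):
            if policy.is_trigger(ext[i : i + w]):
                out.append(i)
    else:
        base, p, mod = policy.base, policy.p, KR_MODULUS
        lead = pow(base, w - 1, mod)
        excluded = policy.excluded_chars
        # windows containing an excluded char, via a sliding count
        bad = np.frombuffer(bytes(1 if c in excluded else 0 for c in ext), dtype=np.uint8)
        cum = np.concatenate(([0], np.cumsum(bad, dtype=np.int64)))
        h = kr_fingerprint(ext[:w], base)
        for i in range(n - 1):
            if h % p == 0 and cum[i + w] - cum[i] == 0:
                out.append(i)
            if i + w < len(ext):
                h = ((h - ord(ext[i]) * lead) * base + ord(ext[i + w])) % mod
    out.append(n - 1)  # the mandatory terminator window
    return np.asarray(out, dtype=np.int64)


def build_parse(text: str, policy: TriggerPolicy) -> ParseResult:
    """Prefix-free parse of a terminated text: dictionary, parse, trigger positions."""
    pos = trigger_positions(text, policy)
    n = len(text)
    w = policy.w
    k = len(pos)
    # occurrence order starts at the terminator window, which is position
    # n - 1 and therefore the last element of the ascending position list
    order = np.concatenate(([n - 1], pos[:-1])).astype(np.int64)
    big = text + text + text[:w]
    phrases = []
    for i in range(k):
        s = int(order[i])
        e = int(order[(i + 1) % k])
        if e <= s:
            e += n
        phrases.append(big[s : e + w])
    dictionary = tuple(sorted(set(phrases), key=lex_key))
    rank = {d: r for r, d in enumerate(dictionary)}
    parse = np.asarray([rank[ph] for ph in phrases], dtype=np.int64)
    return ParseResult(dictionary=dictionary, parse=parse,
                       trigger_positions=pos, w=w, n=n)


def reconstruct_text(parse_result: ParseResult) -> str:
    """Overlap-collapsed cyclic concatenation of the parsed phrases.

    Inverse of :func:`build_parse`: returns the original terminated text
    (rotated so the terminator is last).  Raises :class:`CorruptionError`
    if adjacent phrases disagree on their w-character overlap.
    """
    w = parse_result.w
    phrases = parse_result.phrases_in_order
    if not phrases:
        raise CorruptionError("empty parse")
    parts = [phrases[0]]
    for prev, ph in zip(phrases, phrases[1:]):
        if prev[-w:] != ph[:w]:
            raise CorruptionError(
                f"adjacent phrases disagree on their {w}-character overlap: "
                f"{prev[-w:]!r} vs {ph[:w]!r}")
        parts.append(ph[w:])
    buf = "".join(parts)
    # cyclic wrap: the last phrase overlaps the first by w characters
    if buf[-w:] != buf[:w] or len(buf) - w != parse_result.n:
        raise CorruptionError("cyclic wrap overlap disagrees with the first phrase")
    cyc = buf[:-w]
    if cyc.count(TERMINATOR) != 1:
        raise CorruptionError("reconstructed text does not contain a unique terminator")
    i = cyc.index(TERMINATOR)
    return cyc[i + 1 :] + cyc[: i + 1]


def scan_pattern(pattern: str, policy: TriggerPolicy) -> PatternDecomposition:
    """Decompose a (non-cyclic, unterminated) pattern by the trigger policy."""
    if not pattern:
        raise InputError("pattern must be non-empty")
    w = policy.w
    m = len(pattern)
    starts = [i for i in range(m - w + 1) if policy.is_trigger(pattern[i : i + w])]
    if not starts:
        return PatternDecomposition(alpha=pattern, phrase_strings=(), beta="",
                                    has_trigger=False, w=w)
    if len(starts) == 1:
        t = starts[0]
        return PatternDecomposition(alpha=pattern[: t + w], phrase_strings=(),
                                    beta=pattern[t:], has_trigger=True, w=w)
    t0, tk = starts[0], starts[-1]
    alpha = pattern[: t0 + w] if t0 > 0 else ""
    beta = pattern[tk:] if tk + w < m else ""
    phrase_strings = tuple(pattern[starts[i] : starts[i + 1] + w]
                           for i in range(len(starts) - 1))
    return PatternDecomposition(alpha=alpha, phrase_strings=phrase_strings,
                                beta=beta, has_trigger=True, w=w)


@dataclass(frozen=True)
class PhraseStats:
    n_occurrences: int
    n_distinct: int
    mean_length: float
    min_length: int
    max_length: int


def phrase_stats(parse_result: ParseResult) -> PhraseStats:
    """Phrase-length statistics over parse *occurrences* (not distinct phrases).

    Lengths include both trigger overlaps, so they count each phrase's full
    character span.
    """
    lengths = [len(ph) for ph in parse_result.phrases_in_order]
    return PhraseStats(
        n_occurrences=len(lengths),
        n_distinct=len(parse_result.dictionary),
        mean_length=float(np.mean(lengths)),
        min_length=int(min(lengths)),
        max_length=int(max(lengths)),
    )
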