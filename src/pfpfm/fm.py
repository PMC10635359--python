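"""Suffix array, BWT and backward search over an arbitrary integer alphabet.

Used twice by the two-level index: once for the characters of the text S
and once for the phrase IDs of the parse P.  Conventions fixed package
wide: 0-based indexing, inclusive intervals, ``rank(c, i)`` counts
occurrences strictly before position i, ``select`` is 1-indexed.

The text is an integer sequence whose smallest symbol (the terminator)
occurs exactly once, so the lexicographic order of suffixes equals the
order of cyclic rotations — the property the two-level bridge relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InputError


@dataclass(frozen=True)
class IntText:
    """An integer-alphabet text with a unique smallest terminator symbol."""

    symbols: np.ndarray
    sigma: int

    def __post_init__(self) -> None:
        sym = np.ascontiguousarray(self.symbols, dtype=np.int64)
        object.__setattr__(self, "symbols", sym)
        if sym.size == 0:
            raise InputError("empty text")
        if sym.min() < 0 or sym.max() >= self.sigma:
            raise InputError("symbols out of range for alphabet size "
                             f"sigma={self.sigma}")
        t = int(sym.min())
        if int(np.count_nonzero(sym == t)) != 1:
            raise InputError("the smallest symbol (terminator) must occur exactly once")

    @property
    def n(self) -> int:
        return int(self.symbols.size)

    @property
    def terminator_rank(self) -> int:
        return int(self.symbols.min())


@dataclass(frozen=True)
class Interval:
    """Inclusive 0-based interval of BWT-matrix rows; empty iff lo > hi."""

    lo: int
    hi: int

    @property
    def is_empty(self) -> bool:
        return self.lo > self.hi

    @property
    def size(self) -> int:
        return 0 if self.is_empty else self.hi - self.lo + 1


EMPTY_INTERVAL = Interval(0, -1)


def build_suffix_array(text: IntText) -> np.ndarray:
    """Suffix array by prefix doubling (Manber-Myers) on numpy lexsorts.

    O(n log n) sorting rounds; exact for any integer alphabet.  Row 0 is
    the unique terminator suffix.
    """
    sym = text.symbols
    n = sym.size
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = sym.astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r1 = rank[order]
        r2 = key2[order]
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 0
        changed[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(changed)
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order.astype(np.int64)
        k *= 2


class FMIndex:
    """BWT + cumulative counts C + exact rank support over an integer alphabet.

    ``C[c]`` is the number of suffixes starting with a symbol smaller than
    c; rank is answered by binary search in per-symbol occurrence position
    lists.  ``steps`` counts backward-search steps (rank-operation pairs)
    for instrumentation; it has no effect on results.
    """

    def __init__(self, bwt: np.ndarray, sigma: int, sa: Optional[np.ndarray] = None):
        self.bwt = np.ascontiguousarray(bwt, dtype=np.int64)
        self.sigma = int(sigma)
        self.n = int(self.bwt.size)
        self.sa = sa
        counts = np.bincount(self.bwt, minlength=self.sigma)
        self.C = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
        # stable argsort groups equal symbols with ascending positions:
        # occurrence positions of symbol c are _occ_order[C[c]:C[c+1]]
        self._occ_order = np.argsort(self.bwt, kind="stable").astype(np.int64)
        self.steps = 0

    @classmethod
    def build(cls, text: IntText, keep_sa: bool = False) -> "FMIndex":
        sa = build_suffix_array(text)
        n = text.n
        bwt = text.symbols[(sa + n - 1) % n]
        return cls(bwt, text.sigma, sa=sa if keep_sa else None)

    # -- rank / LF ---------------------------------------------------------

    def rank(self, c: int, i: int) -> int:
        """occ(c, i): number of occurrences of c in bwt[0..i-1]."""
        if c < 0 or c >= self.sigma:
            return 0
        seg = self._occ_order[self.C[c] : self.C[c + 1]]
        return int(np.searchsorted(seg, i, side="left"))

    def lf(self, i: int) -> int:
        c = int(self.bwt[i])
        return int(self.C[c]) + self.rank(c, i)

    # -- backward search ---------------------------------------------------

    def full_interval(self) -> Interval:
        return Interval(0, self.n - 1)

    def backward_step(self, iv: Interval, c: int) -> Interval:
        """Extend the matched string by one symbol on the left.

        Empty in -> empty out; out-of-alphabet symbols yield the empty
        interval so unknown query symbols degrade to count 0.
        """
        if iv.is_empty:
            return EMPTY_INTERVAL
        self.steps += 1
        if c < 0 or c >= self.sigma:
            return EMPTY_INTERVAL
        lo = int(self.C[c]) + self.rank(c, iv.lo)
        hi = int(self.C[c]) + self.rank(c, iv.hi + 1) - 1
        return Interval(lo, hi) if lo <= hi else EMPTY_INTERVAL

    def backward_search(self, symbols: Sequence[int], start: Optional[Interval] = None) -> Interval:
        """Fold backward_step right-to-left over ``symbols`` from ``start``."""
        iv = self.full_interval() if start is None else start
        for c in reversed(list(symbols)):
            iv = self.backward_step(iv, int(c))
            if iv.is_empty:
                return EMPTY_INTERVAL
        return iv

    # -- reconstruction (tests / diagnostics) ------------------------------

    def invert(self) -> np.ndarray:
        """Rebuild the text by iterating the LF-mapping from the terminator row."""
        n = self.n
        out = np.empty(n, dtype=np.int64)
        out[n - 1] = int(self.bwt.min())
        s = 0
        for i in range(n - 2, -1, -1):
            out[i] = self.bwt[s]
            s = self.lf(s)
        return out


def build_fm(text: IntText, keep_sa: bool = False) -> FMIndex:
    """Functional alias for :meth:`FMIndex.build`."""
    return FMIndex.build(text, keep_sa=keep_sa)
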