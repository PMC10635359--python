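"""Synthetic pangenomes, pattern sampling, the naive oracle, and sweeps.

The generator emulates a collection of highly similar genomes (one
ancestor plus mutated copies), the repetitive regime in which word-based
indexing pays off: substitutions are i.i.d. per position and indels are
rare, so long phrases recur across copies.  Everything is reproducible
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InputError
from .index import PFPFMIndex
from .parse import TERMINATOR, TriggerPolicy, build_parse, phrase_stats

DNA = "ACGT"


@dataclass(frozen=True)
class PangenomeSpec:
    """Parameters of a synthetic pangenome collection.

    Defaults model a small collection of near-identical genomes: 50 copies
    of a 5 kb ancestor at 0.2% substitution and 0.02% indel divergence.
    """

    ancestor_length: int = 5000
    n_genomes: int = 50
    substitution_rate: float = 0.002
    indel_rate: float = 0.0002
    alphabet: str = DNA
    seed: int = 0

    def __post_init__(self) -> None:
        for name, r in (("substitution_rate", self.substitution_rate),
                        ("indel_rate", self.indel_rate)):
            if not 0.0 <= r <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {r}")
        if self.ancestor_length < 1 or self.n_genomes < 1:
            raise InputError("ancestor_length and n_genomes must be positive")


def gen_pangenome(spec: PangenomeSpec) -> List[Tuple[str, str]]:
    """Generate (record-id, sequence) pairs: one ancestor plus mutated copies."""
    rng = np.random.default_rng(spec.seed)
    sigma = len(spec.alphabet)
    anc = rng.integers(0, sigma, spec.ancestor_length)
    records = [("ancestor", _decode(anc, spec.alphabet))]
    for g in range(1, spec.n_genomes):
        seq = anc.copy()
        # substitutions: shift by 1..sigma-1 guarantees an actual change
        sub = rng.random(seq.size) < spec.substitution_rate
        seq[sub] = (seq[sub] + rng.integers(1, sigma, int(sub.sum()))) % sigma
        if spec.indel_rate > 0:
            keep = rng.random(seq.size) >= spec.indel_rate / 2
            ins = rng.random(seq.size) < spec.indel_rate / 2
            out = []
            for i in range(seq.size):
                if ins[i]:
                    out.append(int(rng.integers(0, sigma)))
                if keep[i]:
                    out.append(int(seq[i]))
            seq = np.asarray(out, dtype=np.int64)
        records.append((f"copy{g}", _decode(seq, spec.alphabet)))
    return records


def _decode(symbols: np.ndarray, alphabet: str) -> str:
    return "".join(alphabet[int(c)] for c in symbols)


def pangenome_text(spec: PangenomeSpec) -> str:
    """The generated collection as one terminated text (records concatenated)."""
    return "".join(seq for _, seq in gen_pangenome(spec)) + TERMINATOR


def write_fasta(records: Iterable[Tuple[str, str]], path) -> None:
    with open(path, "w") as f:
        for rid, seq in records:
            f.write(f">{rid}\n{seq}\n")


def sample_patterns(text: str, length: int, k: int, seed: int,
                    mutate: float = 0.0) -> List[str]:
    """k substrings of the terminated text at uniform start positions.

    Samples never cover the terminator.  With ``mutate > 0`` each sampled
    base is substituted with that probability, producing near-miss (often
    absent) patterns.
    """
    body = text[:-1] if text.endswith(TERMINATOR) else text
    if length > len(body):
        raise InputError(f"pattern length {length} exceeds text length {len(body)}")
    if not 0.0 <= mutate <= 1.0:
        raise InputError("mutate rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, len(body) - length + 1, k)
    out = []
    for s in starts:
        q = body[int(s) : int(s) + length]
        if mutate > 0:
            chars = list(q)
            for i in range(len(chars)):
                if rng.random() < mutate:
                    chars[i] = DNA[int(rng.integers(0, 4))]
            q = "".join(chars)
        out.append(q)
    return out


def naive_count(text: str, pattern: str) -> int:
    """Brute-force overlapping occurrence count in the linear text
    (terminator excluded)."""
    body = text[:-1] if text.endswith(TERMINATOR) else text
    if not pattern or len(pattern) > len(body):
        return 0
    cnt = 0
    i = body.find(pattern)
    while i != -1:
        cnt += 1
        i = body.find(pattern, i + 1)
    return cnt


def sweep_benchmark(text: str, w_grid: Sequence[int], p_grid: Sequence[int],
                    lengths: Sequence[int], k: int, seed: int) -> pd.DataFrame:
    """Per-(w, p, pattern-length) cell report over one text.

    Each cell records the parse shape (average phrase length, |D|, |P|),
    the total character-level and phrase-level backward steps over k
    sampled queries, and whether every count agreed with the naive oracle.
    Operation counts, not wall-clock, are the portable cost proxy.
    """
    rows = []
    for w in w_grid:
        for p in p_grid:
            policy = TriggerPolicy.hashed(w=w, p=p, hash_seed=seed + 1)
            index = PFPFMIndex.build(text, policy)
            stats = phrase_stats(index.parse_result)
            for length in lengths:
                patterns = sample_patterns(text, length, k, seed=seed + length)
                char_steps = phrase_steps = 0
                agree = True
                for q in patterns:
                    cnt, qs = index.count_with_stats(q)
                    char_steps += qs.char_steps
                    phrase_steps += qs.phrase_steps
                    if cnt != naive_count(text, q):
                        agree = False
                rows.append({
                    "w": w, "p": p, "pattern_length": length,
                    "avg_phrase_length": stats.mean_length,
                    "n_dict": stats.n_distinct, "n_parse": stats.n_occurrences,
                    "char_steps": char_steps, "phrase_steps": phrase_steps,
                    "n_queries": len(patterns), "agree": agree,
                })
    return pd.DataFrame(rows)
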