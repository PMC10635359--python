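"""FASTA / pattern input and the serialized index container.

The container is little-endian and sectioned: magic ``PFPFM1``, a format
version, a JSON header that fully determines query-time parsing (policy,
alphabet, dictionary phrases, array dtypes and lengths), then raw array
sections for the two BWTs and the packed mark bitvector.  Rank structures
are rebuilt on load, so load(save(x)) reproduces an index whose every
query answer equals x's.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path
from typing import Dict, List, Union

import numpy as np
from Bio import SeqIO

from .errors import CorruptionError, InputError
from .fm import FMIndex
from .index import MarkBitvector, PFPFMIndex, PhraseMap
from .parse import RESERVED_SYMBOLS, TERMINATOR, TriggerPolicy

MAGIC = b"PFPFM1"

PathLike = Union[str, Path]


def read_fasta(path: PathLike, record_separator: str | None = None) -> str:
    """Concatenate all records of a FASTA file into one terminated text.

    Sequences are uppercased and concatenated in file order (optionally
    joined by a single sentinel character); a single terminator ``$`` is
    appended.  Reserved symbols inside sequences are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    seqs: List[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        bad = set(s) & RESERVED_SYMBOLS
        if bad:
            raise InputError(f"record {rec.id!r} contains reserved symbol(s) {sorted(bad)}")
        seqs.append(s)
    if not seqs or not any(seqs):
        raise InputError(f"no sequence records found in {path}")
    if record_separator is not None:
        if len(record_separator) != 1 or record_separator in RESERVED_SYMBOLS:
            raise InputError("record separator must be a single non-reserved character")
        if any(record_separator in s for s in seqs):
            raise InputError("record separator occurs inside a sequence")
        body = record_separator.join(seqs)
    else:
        body = "".join(seqs)
    return body + TERMINATOR


def read_patterns(path: PathLike) -> List[str]:
    """Query patterns from a plain-text file (one per line) or a FASTA file."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    text = path.read_text()
    stripped = text.lstrip()
    if stripped.startswith(">"):
        patterns = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    else:
        patterns = [line.strip() for line in text.splitlines()]
    patterns = [q for q in patterns if q]
    if not patterns:
        raise InputError(f"no patterns found in {path}")
    return patterns


# -- index container --------------------------------------------------------


def _policy_to_dict(policy: TriggerPolicy) -> Dict:
    return {
        "w": policy.w,
        "mode": policy.mode,
        "p": policy.p,
        "hash_seed": policy.hash_seed,
        "explicit_set": sorted(policy.explicit_set),
        "excluded_chars": sorted(policy.excluded_chars),
    }


def _policy_from_dict(d: Dict) -> TriggerPolicy:
    return TriggerPolicy(w=d["w"], mode=d["mode"], p=d["p"],
                         hash_seed=d["hash_seed"],
                         explicit_set=frozenset(d["explicit_set"]),
                         excluded_chars=frozenset(d["excluded_chars"]))


def save_index(index: PFPFMIndex, path: PathLike) -> None:
    """Serialize a two-level index to the sectioned binary container."""
    header = {
        "version": PFPFMIndex.FORMAT_VERSION,
        "policy": _policy_to_dict(index.policy),
        "alphabet": sorted(index.alphabet, key=index.alphabet.get),
        "phrases": list(index.m.phrases),
        "phrase_fp_seed": index.m.fp_seed,
        "n": index.n,
        "n_parse": index.n_phrases,
        "n_dict": index.n_distinct_phrases,
        "dtype": "<u4",
    }
    hdr = json.dumps(header).encode("utf-8")
    bwt_s = index.fm_s.bwt.astype("<u4").tobytes()
    bwt_p = index.fm_p.bwt.astype("<u4").tobytes()
    bits = np.packbits(index.b.bits).tobytes()
    with open(path, "wb") as f:
        f.write(MAGIC)
        f.write(struct.pack("<H", PFPFMIndex.FORMAT_VERSION))
        f.write(struct.pack("<I", len(hdr)))
        f.write(hdr)
        for payload in (bwt_s, bwt_p, bits):
            f.write(struct.pack("<Q", len(payload)))
            f.write(payload)


def _read_exact(f, k: int) -> bytes:
    buf = f.read(k)
    if len(buf) != k:
        raise CorruptionError("truncated index file")
    return buf


def load_index(path: PathLike) -> PFPFMIndex:
    """Load an index container; magic/version mismatch or truncation raise
    :class:`CorruptionError`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    with open(path, "rb") as f:
        if _read_exact(f, len(MAGIC)) != MAGIC:
            raise CorruptionError("bad magic: not a PFPFM index file")
        (version,) = struct.unpack("<H", _read_exact(f, 2))
        if version != PFPFMIndex.FORMAT_VERSION:
            raise CorruptionError(f"unsupported index format version {version}")
        (hdr_len,) = struct.unpack("<I", _read_exact(f, 4))
        try:
            header = json.loads(_read_exact(f, hdr_len).decode("utf-8"))
        except (UnicodeDecodeError, json.JSONDecodeError) as e:
            raise CorruptionError(f"unreadable header: {e}") from e
        payloads = []
        for _ in range(3):
            (plen,) = struct.unpack("<Q", _read_exact(f, 8))
            payloads.append(_read_exact(f, plen))
        if f.read(1):
            raise CorruptionError("trailing bytes after the last section")

    n = header["n"]
    k = header["n_parse"]
    n_dict = header["n_dict"]
    dtype = header["dtype"]
    bwt_s = np.frombuffer(payloads[0], dtype=dtype).astype(np.int64)
    bwt_p = np.frombuffer(payloads[1], dtype=dtype).astype(np.int64)
    bits = np.unpackbits(np.frombuffer(payloads[2], dtype=np.uint8))[:n]
    if bwt_s.size != n or bwt_p.size != k:
        raise CorruptionError("section length disagrees with the header")
    policy = _policy_from_dict(header["policy"])
    alphabet = {ch: i for i, ch in enumerate(header["alphabet"])}
    fm_s = FMIndex(bwt_s, sigma=len(alphabet))
    fm_p = FMIndex(bwt_p, sigma=n_dict)
    b = MarkBitvector(n, np.flatnonzero(bits))
    if b.popcount != k:
        raise CorruptionError("bitvector popcount disagrees with |P|")
    m = PhraseMap.build(header["phrases"], fp_seed=header["phrase_fp_seed"])
    return PFPFMIndex(fm_s, fm_p, b, m, policy, alphabet, parse_result=None)
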