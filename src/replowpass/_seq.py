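"""Low-level nucleotide sequence helpers shared across the package.

Sequences are handled either as Python strings over ``ACGTN`` or as numpy
``uint8`` code arrays (A=0, C=1, G=2, T=3, N=4).  The code representation is
what the numba aligner and the read simulator operate on.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into uint8 codes (A=0,C=1,G=2,T=3,N=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def gc_content(seq: str) -> float:
    """GC fraction of a sequence, ignoring Ns; 0.0 for empty input."""
    if not seq:
        return 0.0
    codes = encode(seq)
    acgt = int(np.count_nonzero(codes < 4))
    if acgt == 0:
        return 0.0
    gc = int(np.count_nonzero((codes == 1) | (codes == 2)))
    return gc / acgt


def random_codes(rng: np.random.Generator, length: int, gc: float = 0.5) -> np.ndarray:
    """i.i.d. random base codes at the requested GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    return decode(random_codes(rng, length, gc))


def kmer_set(codes: np.ndarray, k: int) -> frozenset[int]:
    """Set of 2-bit packed k-mers of a code array (k-mers containing N skipped)."""
    n = len(codes) - k + 1
    if n <= 0:
        return frozenset()
    idx = np.arange(n)[:, None] + np.arange(k)[None, :]
    windows = codes[idx]
    ok = (windows < 4).all(axis=1)
    if not ok.any():
        return frozenset()
    weights = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    packed = windows[ok].astype(np.int64) @ weights
    return frozenset(packed.tolist())
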