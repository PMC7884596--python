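"""Low-level nucleotide utilities shared by the simulator, assembler and verifier."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# A,C,G,T -> 0..3; anything else (N, ambiguity codes) -> 4, which never
# matches during comparison and therefore counts as a mismatch.
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

NUCLEOTIDES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A,C,G,T -> 0..3, other -> 4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def mismatch_vector(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Boolean per-position disagreement; positions with code 4 always disagree."""
    return (a != b) | (a == 4) | (b == 4)


def kmer_index(seq: str, k: int, step: int = 1) -> dict[str, list[int]]:
    """Exact k-mer -> start positions over one string."""
    index: dict[str, list[int]] = {}
    for pos in range(0, len(seq) - k + 1, step):
        index.setdefault(seq[pos : pos + k], []).append(pos)
    return index
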