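"""Low-level DNA sequence helpers shared across modules.

Bases are encoded internally as uint8 codes 0=A, 1=C, 2=G, 3=T so that
mutation, Hamming-distance and consensus operations vectorize in numpy.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_TO_CODE[ord(_b)] = _i
    _BASE_TO_CODE[ord(_b.lower())] = _i

# complement of code i is 3 - i (A<->T, C<->G)


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as a uint8 code array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _BASE_TO_CODE[raw]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"non-ACGT character in sequence: {bad!r}")
    return codes


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to a string."""
    return _CODE_TO_BASE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return decode(3 - encode(seq)[::-1])


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes[::-1]).astype(np.uint8)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return int(np.count_nonzero(encode(a) != encode(b)))


def encode_matrix(seqs) -> np.ndarray:
    """Stack equal-length sequences into an (n, L) uint8 code matrix."""
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have mixed lengths: {sorted(lengths)}")
    return np.vstack([encode(s) for s in seqs])


def pairwise_hamming(mat: np.ndarray, block: int = 512) -> np.ndarray:
    """All-pairs Hamming distances between rows of a code matrix."""
    n = mat.shape[0]
    out = np.zeros((n, n), dtype=np.int32)
    for i0 in range(0, n, block):
        a = mat[i0 : i0 + block]
        for j0 in range(i0, n, block):
            b = mat[j0 : j0 + block]
            d = (a[:, None, :] != b[None, :, :]).sum(axis=2, dtype=np.int32)
            out[i0 : i0 + a.shape[0], j0 : j0 + b.shape[0]] = d
            out[j0 : j0 + b.shape[0], i0 : i0 + a.shape[0]] = d.T
    return out


def mutate(codes: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Return a copy where each site independently substitutes with
    probability ``p``, uniformly to one of the three other bases."""
    out = codes.copy()
    if p <= 0.0:
        return out
    mask = rng.random(codes.shape) < p
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    return out
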