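"""Low-level nucleotide encoding helpers shared across modules.

Sequences are held as ``numpy.uint8`` arrays with A,C,G,T,N -> 0..4.
Code 4 ('N') never matches anything, which is what makes masked reference
positions unalignable under the zero-mismatch rule.
"""

from __future__ import annotations

import zlib

import numpy as np

A, C, G, T, N = 0, 1, 2, 3, 4
BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case

# complement of codes 0..4 (N stays N)
_COMP = np.array([T, G, C, A, N], dtype=np.uint8)


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string into the internal uint8 representation."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)].copy()


def decode(arr: np.ndarray) -> str:
    """Decode the internal representation back into an upper-case string."""
    return BASES[arr].tobytes().decode("ascii")


def revcomp(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr[::-1]]


def random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int64).astype(np.uint8)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from one master seed.

    The stage name is hashed (CRC32, stable across runs and platforms) and
    combined with the master seed, so each pipeline stage can be re-run in
    isolation with reproducible output.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    )
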