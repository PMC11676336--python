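"""Deterministic 64-bit hash order for k-mers.

Sampling schemes in the minimizer family need a pseudo-random total order
on k-mers that is reproducible across runs, platforms and implementations.
We use the splitmix64 finalizer — an invertible avalanche permutation of
the 64-bit integers — applied to ``code XOR mix(seed)``, where ``code`` is
the big-endian base-sigma integer encoding of the k-mer.

Because the finalizer is a bijection, two k-mers whose encodings fit in 64
bits receive equal hashes only if they are equal; ties in hash therefore
coincide with ties in encoding, and the leftmost-position rule is the only
tie-break ever exercised.  Encodings longer than 64 bits wrap modulo 2^64,
which is harmless for hashing (the wrapped code is still a deterministic
function of the k-mer) but means the *lexicographic* order on codes is only
faithful for k*log2(sigma) <= 64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["splitmix64", "hash_codes", "mix_seed"]

_MASK = (1 << 64) - 1
_C1 = 0xBF58476D1CE4E5B9
_C2 = 0x94D049BB133111EB
_GOLDEN = 0x9E3779B97F4A7C15


def splitmix64(x: int) -> int:
    """Scalar splitmix64 finalizer (Python ints, mod 2^64)."""
    z = x & _MASK
    z = ((z ^ (z >> 30)) * _C1) & _MASK
    z = ((z ^ (z >> 27)) * _C2) & _MASK
    return z ^ (z >> 31)


def mix_seed(seed: int, stream: int = 0) -> int:
    """Derive the per-order 64-bit mixing constant from a user seed.

    Distinct ``stream`` values give independent orders from one seed (used
    e.g. for the t-mer and k-mer orders inside miniception).
    """
    return splitmix64((seed & _MASK) + stream * _GOLDEN)


def hash_codes(codes: np.ndarray, seed: int, stream: int = 0) -> np.ndarray:
    """Vectorized splitmix64 of ``codes XOR mix_seed(seed, stream)``.

    ``codes`` must be uint64; returns uint64 of the same shape.
    """
    z = codes.astype(np.uint64, copy=True)
    z ^= np.uint64(mix_seed(seed, stream))
    z = (z ^ (z >> np.uint64(30))) * np.uint64(_C1)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(_C2)
    return z ^ (z >> np.uint64(31))
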