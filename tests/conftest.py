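"""Shared fixtures: small schemes and sequences used across the suite."""

import numpy as np
import pytest

from minidens import io, schemes


def small_schemes(w: int, k: int, sigma: int) -> list:
    """Every built-in scheme family instantiated at (w, k, sigma)."""
    out = [
        schemes.random_minimizer(w, k, sigma, seed=11),
        schemes.mod_minimizer(w, k, sigma, seed=11, r=1),
        schemes.miniception(w, k, sigma, seed=11, t=max(1, k - 1)),
    ]
    if k * max((sigma - 1).bit_length(), 1) <= 64:
        out.append(schemes.lexicographic_minimizer(w, k, sigma))
    if k >= 2:
        out.append(schemes.double_decycling_minimizer(w, k, sigma, seed=11))
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def random_dna_1m():
    return io.random_sequence(4, 1_000_000, seed=5)
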