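"""Necklace and pure-cycle combinatorics on De Bruijn graphs.

The complete De Bruijn graph :math:`B_n` over an alphabet of size ``sigma``
has one vertex per length-``n`` string and an edge between strings that
overlap in ``n - 1`` symbols.  The rotations of any length-``n`` string
induce a *pure cycle* in :math:`B_n`; the pure cycles partition the vertex
set, and each cycle corresponds to a necklace (an equivalence class of
strings under rotation).  A necklace is *aperiodic* when all ``n`` rotations
are distinct.

The necklace counts

.. math::

    N_\\sigma(n) = \\frac{1}{n} \\sum_{p \\mid n} \\varphi(n/p)\\,\\sigma^p,
    \\qquad
    M_\\sigma(n) = \\frac{1}{n} \\sum_{p \\mid n} \\mu(n/p)\\,\\sigma^p,

with Euler's totient :math:`\\varphi` and the Möbius function :math:`\\mu`,
are the backbone of the density lower bounds in :mod:`minidens.bounds` and
of the pure-cycle cutting planes in :mod:`minidens.ilp`.

All counts are exact Python integers (arbitrary precision).  Strings are
represented over the internal integer alphabet ``[sigma] = {0, ..., sigma-1}``;
DNA maps ``A=0, C=1, G=2, T=3`` (see :mod:`minidens.io`).
"""

from __future__ import annotations

from dataclasses import dataclass

import sympy

__all__ = [
    "PureCycle",
    "euler_totient",
    "mobius",
    "necklace_count",
    "aperiodic_necklace_count",
    "enumerate_pure_cycles",
    "canonical_rotation",
]

#: Refuse whole-graph enumeration beyond this many strings by default.
DEFAULT_ENUMERATION_BUDGET = 10**7


def euler_totient(p: int) -> int:
    """Count integers in ``[p]`` coprime to ``p`` (Euler's totient).

    By convention ``euler_totient(1) == 1``.
    """
    if p < 1:
        raise ValueError(f"totient requires p >= 1, got {p}")
    return int(sympy.totient(p))


def mobius(n: int) -> int:
    """Möbius function: 0 if a square > 1 divides ``n``, else ``(-1)**q``
    with ``q`` the number of prime factors of ``n``."""
    if n < 1:
        raise ValueError(f"mobius requires n >= 1, got {n}")
    return int(sympy.mobius(n))


def necklace_count(sigma: int, n: int) -> int:
    """Number of necklaces (rotation classes) of length ``n`` over a
    ``sigma``-letter alphabet: ``N_sigma(n) = (1/n) sum_{p|n} phi(n/p) sigma^p``."""
    _check_sigma_n(sigma, n)
    total = sum(euler_totient(n // p) * sigma**p for p in sympy.divisors(n))
    assert total % n == 0
    return total // n


def aperiodic_necklace_count(sigma: int, n: int) -> int:
    """Number of aperiodic necklaces (Lyndon classes) of length ``n``:
    ``M_sigma(n) = (1/n) sum_{p|n} mu(n/p) sigma^p`` (Möbius inversion of
    ``N_sigma``)."""
    _check_sigma_n(sigma, n)
    total = sum(mobius(n // p) * sigma**p for p in sympy.divisors(n))
    assert total % n == 0
    return total // n


@dataclass(frozen=True)
class PureCycle:
    """A necklace-induced pure cycle of the order-``n`` De Bruijn graph.

    Attributes
    ----------
    canonical:
        The lexicographically least rotation, as a string of digit
        characters over ``[sigma]`` (e.g. ``"0011"``).
    length:
        Number of distinct rotations, i.e. vertices on the cycle.  Equals
        the primitive period of ``canonical`` and divides ``order``.
    order:
        De Bruijn graph order ``n`` (the string length).
    """

    canonical: str
    length: int
    order: int

    def rotations(self) -> list[str]:
        """The ``length`` distinct rotations in cycle order, starting from
        ``canonical`` (each step shifts left by one symbol)."""
        s = self.canonical
        return [s[i:] + s[:i] for i in range(self.length)]


def canonical_rotation(s: str) -> str:
    """Lexicographically least rotation of ``s`` (Booth-style by full scan;
    quadratic worst case, which is fine at necklace-enumeration sizes)."""
    if not s:
        raise ValueError("canonical_rotation requires a nonempty string")
    return min(s[i:] + s[:i] for i in range(len(s)))


def enumerate_pure_cycles(
    sigma: int, n: int, budget: int = DEFAULT_ENUMERATION_BUDGET
) -> list[PureCycle]:
    """Enumerate every pure cycle (necklace) of :math:`B_n` over ``[sigma]``.

    The cycles partition all ``sigma**n`` strings; the number of cycles of
    length ``p`` equals ``aperiodic_necklace_count(sigma, p)`` for each
    divisor ``p`` of ``n``.  Refuses when ``sigma**n > budget``: this
    enumeration exists to serve exact-density checks and ILP cuts at small
    scale, not large-scale necklace generation.
    """
    _check_sigma_n(sigma, n)
    total = sigma**n
    if total > budget:
        raise ValueError(
            f"enumerate_pure_cycles: sigma**n = {total} exceeds the enumeration "
            f"budget {budget}; raise `budget` explicitly if this is intended"
        )
    top = sigma ** (n - 1)
    seen = bytearray(total)
    cycles: list[PureCycle] = []
    for start in range(total):
        if seen[start]:
            continue
        # Walk the rotation orbit of `start`; rotate-left on the integer
        # encoding: c -> (c mod sigma^(n-1)) * sigma + (c div sigma^(n-1)).
        orbit = []
        c = start
        while not seen[c]:
            seen[c] = 1
            orbit.append(c)
            c = (c % top) * sigma + (c // top)
        canon = min(orbit)
        cycles.append(
            PureCycle(canonical=_decode(canon, sigma, n), length=len(orbit), order=n)
        )
    return cycles


def _decode(code: int, sigma: int, n: int) -> str:
    digits = []
    for _ in range(n):
        code, d = divmod(code, sigma)
        digits.append(d)
    if sigma > 10:
        raise ValueError("digit-string representation requires sigma <= 10")
    return "".join(str(d) for d in reversed(digits))


def _check_sigma_n(sigma: int, n: int) -> None:
    if sigma < 1:
        raise ValueError(f"alphabet size must be >= 1, got {sigma}")
    if n < 1:
        raise ValueError(f"length must be >= 1, got {n}")
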