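"""Density lower bounds for forward and local k-mer sampling schemes.

The central quantity is the necklace-based lower bound on the density of
any (w, k)-forward scheme over an alphabet of size ``sigma``:

.. math::

    g_\\sigma(w, k) = \\frac{1}{\\sigma^{w+k}}
        \\sum_{p \\mid (w+k)} M_\\sigma(p) \\left\\lceil p/w \\right\\rceil
    \\;\\ge\\; \\frac{\\lceil (w+k)/w \\rceil}{w+k} \\;\\ge\\; \\frac{1}{w},

where :math:`M_\\sigma(p)` counts aperiodic necklaces of length ``p`` and
the middle inequality is strict for ``w > 1``.  The bound follows from a
counting argument on the pure cycles of the order-(w+k) De Bruijn graph:
any (w, l)-universal hitting set must contain at least ``ceil(p/w)``
members of every pure cycle of length ``p``, and the charged contexts of a
forward scheme form a (w, w+k)-UHS.

Because a (w, k)-scheme can ignore trailing characters, the minimum
density is monotone non-increasing in ``k`` while ``g`` itself is not;
taking the maximum of ``g`` at ``k`` and at the next ``k' >= k`` with
``k' ≡ 1 (mod w)`` gives the improved bound ``g'``.  For (w, k)-local
schemes the same machinery applies with context length ``2w + k - 2``,
giving the bound ``g'_sigma(w, w+k-2)``.

All values are carried as exact `fractions.Fraction` rationals; floats are
derived only for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import sympy

from .combinatorics import aperiodic_necklace_count

__all__ = [
    "BoundResult",
    "lower_bound_g",
    "lower_bound_g_prime",
    "simple_bound",
    "prior_bound",
    "uhs_lower_bound",
    "local_scheme_bound",
    "mod_minimizer_asymptotic_density",
]


@dataclass(frozen=True)
class BoundResult:
    """An exact density bound together with the parameters that produced it.

    ``k_prime`` is the smallest ``k' >= k`` with ``k' ≡ 1 (mod w)``; it is
    populated for the improved bounds (``kind`` in {"g_prime", "local"}) and
    ``None`` otherwise.
    """

    w: int
    k: int
    sigma: int
    value_exact: Fraction
    kind: str
    k_prime: int | None = None

    @property
    def value_float(self) -> float:
        return float(self.value_exact)

    def rounded(self, decimals: int = 3) -> float:
        """Half-even rounding for table display (3 decimals by default)."""
        q = Fraction(1, 10**decimals)
        return float(round(self.value_exact / q) * q)


def _check(sigma: int, w: int, k: int) -> None:
    if sigma < 2:
        raise ValueError(f"alphabet size must be >= 2, got {sigma}")
    if w < 1:
        raise ValueError(f"window guarantee must be >= 1, got {w}")
    if k < 1:
        raise ValueError(f"k-mer length must be >= 1, got {k}")


def _g_numerator(sigma: int, w: int, ell: int) -> int:
    return sum(
        aperiodic_necklace_count(sigma, p) * math.ceil(p / w)
        for p in sympy.divisors(ell)
    )


def lower_bound_g(sigma: int, w: int, k: int) -> BoundResult:
    """The necklace lower bound ``g_sigma(w, k)`` on forward-scheme density.

    Exact rational ``sum_{p | (w+k)} M_sigma(p) * ceil(p/w) / sigma**(w+k)``.
    """
    _check(sigma, w, k)
    ell = w + k
    value = Fraction(_g_numerator(sigma, w, ell), sigma**ell)
    return BoundResult(w=w, k=k, sigma=sigma, value_exact=value, kind="g")


def k_prime_for(w: int, k: int) -> int:
    """Smallest ``k' >= k`` with ``k' ≡ 1 (mod w)``; equals ``k`` when
    already congruent (always ``k`` for ``w == 1``)."""
    return k + (1 - k) % w


def lower_bound_g_prime(sigma: int, w: int, k: int) -> BoundResult:
    """The improved bound ``g'_sigma(w, k) = max(g(w, k), g(w, k'))``.

    Valid because a (w, k')-scheme restricted to its first ``w + k - 1``
    window characters is a (w, k)-scheme of identical density, so the
    minimum density is non-increasing in ``k``.
    """
    _check(sigma, w, k)
    kp = k_prime_for(w, k)
    value = max(lower_bound_g(sigma, w, k).value_exact,
                lower_bound_g(sigma, w, kp).value_exact)
    return BoundResult(w=w, k=k, sigma=sigma, value_exact=value,
                       kind="g_prime", k_prime=kp)


def simple_bound(w: int, k: int) -> Fraction:
    """The alphabet-free approximation ``ceil((w+k)/w) / (w+k)``.

    Sandwiched between ``g_sigma(w, k)`` and ``1/w``; coincides with the
    large-sigma limit of ``g`` and, when ``k ≡ 1 (mod w)``, with the
    asymptotic mod-minimizer density.
    """
    if w < 1 or k < 1:
        raise ValueError("w and k must be >= 1")
    ell = w + k
    return Fraction(math.ceil(ell / w), ell)


def prior_bound(w: int, k: int) -> float:
    """Earlier literature bound ``1.5 / (w + k - 0.5)``, kept for
    comparison only; it is weaker than ``g`` everywhere."""
    if w < 1 or k < 1:
        raise ValueError("w and k must be >= 1")
    return 1.5 / (w + k - 0.5)


def uhs_lower_bound(sigma: int, w: int, ell: int) -> int:
    """Lower bound ``sum_{p | ell} M_sigma(p) * ceil(p/w)`` on the size of
    any (w, ell)-universal hitting set.

    Every pure cycle of length ``p`` in the order-``ell`` De Bruijn graph
    must contribute at least ``ceil(p/w)`` members; cycles shorter than the
    window (``p < w``) still contribute 1.  Stated for ``w >= 2`` (for
    ``w = 1`` the UHS is trivially all ell-mers).
    """
    if sigma < 2:
        raise ValueError(f"alphabet size must be >= 2, got {sigma}")
    if w < 2:
        raise ValueError(f"UHS bound requires w >= 2, got {w}")
    if ell < 1:
        raise ValueError(f"ell must be >= 1, got {ell}")
    return _g_numerator(sigma, w, ell)


def local_scheme_bound(sigma: int, w: int, k: int) -> BoundResult:
    """Density lower bound ``g'_sigma(w, w+k-2)`` for (w, k)-local schemes.

    A local scheme's charged contexts have length ``2w + k - 2`` = ``w`` +
    (``w + k - 2``), so the forward-scheme machinery applies with the
    substituted k-mer length.
    """
    _check(sigma, w, k)
    if w < 2:
        raise ValueError("local-scheme bound requires w >= 2")
    k_sub = w + k - 2
    if k_sub < 1:
        raise ValueError("w + k - 2 must be >= 1")
    inner = lower_bound_g_prime(sigma, w, k_sub)
    return BoundResult(w=w, k=k, sigma=sigma, value_exact=inner.value_exact,
                       kind="local", k_prime=inner.k_prime)


def mod_minimizer_asymptotic_density(w: int, k: int) -> Fraction:
    """Density of the mod-minimizer in the infinite-alphabet limit,
    ``(floor((w+k-2)/w) + 2) / (w+k)``, asserted for ``k ≡ 1 (mod w)``
    where it equals ``simple_bound(w, k)`` — i.e. the scheme is optimal."""
    if w < 1 or k < 1:
        raise ValueError("w and k must be >= 1")
    if k % w != 1 % w:
        raise ValueError(
            f"asymptotic mod-minimizer density is only established for "
            f"k ≡ 1 (mod w); got k={k}, w={w}"
        )
    return Fraction((w + k - 2) // w + 2, w + k)
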