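"""Exact and empirical densities of sampling schemes via charged contexts.

The *density* of a scheme is the expected proportion of sampled k-mer
positions in an infinite uniform random string.  It equals the proportion
of *charged contexts*: minimal strings whose last window samples a position
not sampled by the relevant preceding window(s).

* Forward schemes: a context is two adjacent windows, ``w + k`` symbols;
  ``W`` is charged iff ``f(W[0, w+k-1)) != f(W[1, w+k)) + 1``.
* Local schemes: a context is ``w`` consecutive windows, ``2w + k - 2``
  symbols; charged iff the last window's absolute selection differs from
  every earlier window's.

Either charged-context set is a (w, l)-universal hitting set for its
context length ``l`` — every run of ``w`` consecutive l-mers contains a
member — which is what links densities to the necklace lower bounds in
:mod:`minidens.bounds`.

Exact computations enumerate all ``sigma**l`` contexts and are guarded by
an enumeration budget (default 10^7); empirical densities run a scheme
over a (typically seeded-random) sequence and divide the number of
distinct selected positions by the number of k-mer positions
``L - k + 1`` (the window count differs by O(w), irrelevant at the 10^7
lengths used for benchmarking).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .schemes import SchemeSpec, substring_codes

__all__ = [
    "ChargedContextSet",
    "DensityEstimate",
    "all_strings",
    "charged_contexts_forward",
    "charged_contexts_local",
    "exact_density",
    "empirical_density",
    "is_forward",
    "verify_uhs",
]

DEFAULT_BUDGET = 10**7


def all_strings(sigma: int, length: int, budget: int = DEFAULT_BUDGET) -> np.ndarray:
    """All ``sigma**length`` strings as a (sigma**length, length) uint8
    array, row ``i`` being the big-endian base-sigma digits of ``i``."""
    total = sigma**length
    if total > budget:
        raise ValueError(
            f"enumeration of sigma**l = {total} strings exceeds budget {budget}"
        )
    codes = np.arange(total, dtype=np.int64)
    out = np.empty((total, length), dtype=np.uint8)
    for j in range(length):
        out[:, j] = (codes // sigma ** (length - 1 - j)) % sigma
    return out


@dataclass
class ChargedContextSet:
    """The set of charged contexts of a scheme, stored as sorted integer
    encodings of the context strings."""

    scheme: SchemeSpec
    mode: str  # "forward" | "local"
    context_length: int
    members: np.ndarray  # sorted int64 codes

    def __len__(self) -> int:
        return len(self.members)

    @property
    def density(self) -> Fraction:
        return Fraction(len(self.members),
                        self.scheme.sigma**self.context_length)


@dataclass
class DensityEstimate:
    value: float
    n: int  # contexts enumerated (exact) or k-mer positions (empirical)
    mode: str  # "exact" | "empirical"
    exact_fraction: Fraction | None = None


def charged_contexts_forward(
    scheme: SchemeSpec, budget: int = DEFAULT_BUDGET
) -> ChargedContextSet:
    """Enumerate the charged contexts of length ``w + k`` (one character
    more than the scheme's window length, whatever that is)."""
    ell = scheme.window_length + 1
    ctx = all_strings(scheme.sigma, ell, budget)
    f_prev = scheme.rule_batch(ctx[:, :-1])
    f_next = scheme.rule_batch(ctx[:, 1:])
    charged = f_prev != f_next + 1
    return ChargedContextSet(
        scheme=scheme, mode="forward", context_length=ell,
        members=np.flatnonzero(charged).astype(np.int64),
    )


def charged_contexts_local(
    scheme: SchemeSpec, budget: int = DEFAULT_BUDGET
) -> ChargedContextSet:
    """Enumerate the charged contexts of length ``2w + k - 2``.

    Context ``W`` is charged iff for every ``0 <= i <= w - 2`` the last
    window's absolute pick ``f(W[w-1, 2w+k-2)) + (w-1)`` differs from
    window ``i``'s pick ``f(W[i, i+w+k-1)) + i``.  For ``w = 1`` the
    quantifier is empty and every context is charged.
    """
    w = scheme.w
    win_len = scheme.window_length
    ell = win_len + w - 1
    ctx = all_strings(scheme.sigma, ell, budget)
    last = scheme.rule_batch(ctx[:, w - 1 : w - 1 + win_len]) + (w - 1)
    charged = np.ones(len(ctx), dtype=bool)
    for i in range(w - 1):
        pick_i = scheme.rule_batch(ctx[:, i : i + win_len]) + i
        charged &= last != pick_i
    return ChargedContextSet(
        scheme=scheme, mode="local", context_length=ell,
        members=np.flatnonzero(charged).astype(np.int64),
    )


def exact_density(
    scheme: SchemeSpec, mode: str = "forward", budget: int = DEFAULT_BUDGET
) -> DensityEstimate:
    """Exact density ``|C_f| / sigma**l`` by full context enumeration."""
    if mode == "forward":
        cs = charged_contexts_forward(scheme, budget)
    elif mode == "local":
        cs = charged_contexts_local(scheme, budget)
    else:
        raise ValueError(f"mode must be 'forward' or 'local', got {mode!r}")
    frac = cs.density
    return DensityEstimate(
        value=float(frac), n=scheme.sigma**cs.context_length,
        mode="exact", exact_fraction=frac,
    )


def empirical_density(scheme: SchemeSpec, sequence) -> DensityEstimate:
    """Fraction of k-mer positions selected on a concrete sequence:
    ``|select(S)| / (|S| - k + 1)``."""
    length = len(sequence)
    if length < scheme.window_length:
        raise ValueError(
            f"sequence of length {length} is shorter than one window "
            f"({scheme.window_length})"
        )
    positions = scheme.select(sequence)
    n_kmers = length - scheme.k + 1
    return DensityEstimate(value=len(positions) / n_kmers, n=n_kmers,
                           mode="empirical")


def is_forward(
    scheme: SchemeSpec,
    budget: int = DEFAULT_BUDGET,
    n_samples: int = 100_000,
    seed: int = 0,
) -> tuple[bool, np.ndarray | None]:
    """Check the forwardness inequality ``f(W[0, w+k-1)) <= f(W[1, w+k)) + 1``.

    Exhaustive over all ``sigma**(w+k)`` two-window contexts when that fits
    the budget; otherwise falls back to seeded random sampling (with a
    warning).  Returns ``(ok, witness)`` where ``witness`` is a violating
    context (uint8 codes) or ``None``.
    """
    ell = scheme.window_length + 1
    total = scheme.sigma**ell
    if total <= budget:
        ctx = all_strings(scheme.sigma, ell, budget)
    else:
        import warnings

        warnings.warn(
            f"is_forward: sigma**(w+k) = {total} exceeds budget; "
            f"sampling {n_samples} random contexts",
            stacklevel=2,
        )
        rng = np.random.default_rng(seed)
        ctx = rng.integers(0, scheme.sigma, size=(n_samples, ell), dtype=np.uint8)
    f_prev = scheme.rule_batch(ctx[:, :-1])
    f_next = scheme.rule_batch(ctx[:, 1:])
    bad = np.flatnonzero(f_prev > f_next + 1)
    if bad.size:
        return False, ctx[bad[0]]
    return True, None


def verify_uhs(
    context_set: ChargedContextSet | np.ndarray,
    w: int,
    *,
    sigma: int | None = None,
    ell: int | None = None,
    budget: int = DEFAULT_BUDGET,
) -> bool:
    """True iff the given set of l-mers is a (w, l)-universal hitting set:
    every string of length ``l + w - 1`` (equivalently every length-w walk
    in the order-l De Bruijn graph) contains a member as a substring.

    Accepts a :class:`ChargedContextSet` or a sorted array of l-mer codes
    (then ``sigma`` and ``ell`` are required).
    """
    if isinstance(context_set, ChargedContextSet):
        members = context_set.members
        sigma = context_set.scheme.sigma
        ell = context_set.context_length
    else:
        members = np.asarray(context_set, dtype=np.int64)
        if sigma is None or ell is None:
            raise ValueError("sigma and ell are required for a raw member array")
    if members.size == 0:
        return False
    walks = all_strings(sigma, ell + w - 1, budget)
    codes = substring_codes(walks, ell, sigma).astype(np.int64)
    hit = np.isin(codes, members)
    return bool(hit.any(axis=1).all())
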