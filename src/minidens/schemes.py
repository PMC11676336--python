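"""Concrete k-mer sampling schemes as window -> index functions.

A *(w, k)-local scheme* is a total function from windows (strings of
``w + k - 1`` symbols, i.e. ``w`` consecutive k-mers) to an index in
``[w]``: the position of the sampled k-mer within the window.  A scheme is
*forward* when the sampled position never moves backwards between adjacent
windows.  Every scheme here is forward; forwardness is checked exhaustively
in the test-suite via :func:`minidens.density.is_forward`.

Implemented schemes:

``random_minimizer``
    The classic minimizer: sample the k-mer with the smallest seeded
    64-bit hash; leftmost on ties.  Density ~ 2/(w+1) for k >~ log_sigma(w).
``lexicographic_minimizer``
    Same, ordered by the k-mer's integer encoding instead of a hash.  A
    deterministic teaching/oracle scheme.
``mod_minimizer``
    Find the leftmost-minimal t-mer in the window (t <= k, chosen so that
    t ≡ k (mod w)) at position p, and sample the k-mer at position
    ``p mod w``.  Approaches the density lower bound for k ≡ 1 (mod w) as
    sigma grows.
``miniception``
    Restrict the minimizer to "preferred" k-mers — those whose own minimal
    t-mer sits at one of the two boundary offsets 0 or k - t — falling back
    to the plain minimizer when a window has none.
``double_decycling_minimizer``
    Order k-mers first by membership in the Mykkeltveit decycling set (via
    the complex embedding ``P(u) = sum_j u_j e^{2 pi i j / k}``), then its
    negation, then the rest; break ranks by hash.
``table_scheme``
    An explicit lookup table over all sigma^(w+k-1) windows — the carrier
    for ILP solutions and hand-built schemes.

Sequences and windows are numpy ``uint8`` code arrays over the internal
alphabet ``[sigma]``; :func:`minidens.io.as_codes` converts DNA or digit
strings.  All schemes accept either form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .hashing import hash_codes

__all__ = [
    "SchemeSpec",
    "random_minimizer",
    "lexicographic_minimizer",
    "mod_minimizer",
    "miniception",
    "double_decycling_minimizer",
    "table_scheme",
    "extend_k",
    "select_positions",
    "substring_codes",
    "encode_window",
]

_TOPBIT = np.uint64(1 << 63)


def substring_codes(arr: np.ndarray, m: int, sigma: int) -> np.ndarray:
    """Big-endian base-``sigma`` integer codes of all length-``m``
    substrings along the last axis (Horner scheme, wraps mod 2^64)."""
    n_pos = arr.shape[-1] - m + 1
    if n_pos < 1:
        raise ValueError(f"array of length {arr.shape[-1]} has no {m}-mers")
    codes = np.zeros(arr.shape[:-1] + (n_pos,), dtype=np.uint64)
    s = np.uint64(sigma)
    for j in range(m):
        codes *= s
        codes += arr[..., j : j + n_pos].astype(np.uint64)
    return codes


def encode_window(window: np.ndarray, sigma: int) -> int:
    """Big-endian integer encoding of one window (exact Python int)."""
    code = 0
    for c in window:
        code = code * sigma + int(c)
    return code


def _as_code_array(seq, sigma: int) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        arr = seq.astype(np.uint8, copy=False)
    else:
        from .io import as_codes  # str / generic sequence entry point

        arr = as_codes(seq, sigma)
    if arr.size and arr.max() >= sigma:
        raise ValueError(f"symbol {arr.max()} out of range for alphabet size {sigma}")
    return arr


@dataclass
class SchemeSpec:
    """A (w, k) sampling scheme over alphabet ``[sigma]``.

    Subclasses implement :meth:`_keys`, producing one uint64 sort key per
    length-``unit`` substring along the last axis; the scheme samples, in
    each window, the position of the minimal key (leftmost on ties) mapped
    through :meth:`_map_rel`.  ``unit`` is ``k`` for minimizer-type schemes
    and ``t`` for the mod-minimizer.
    """

    w: int
    k: int
    sigma: int
    name: str = "scheme"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.w < 1 or self.k < 1 or self.sigma < 2:
            raise ValueError("need w >= 1, k >= 1, sigma >= 2")

    # -- subclass surface -------------------------------------------------
    @property
    def unit(self) -> int:
        return self.k

    def _keys(self, arr: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _map_rel(self, rel: np.ndarray) -> np.ndarray:
        return rel

    # -- generic machinery ------------------------------------------------
    @property
    def window_length(self) -> int:
        """Characters consumed per window.  ``w + k - 1`` for ordinary
        schemes; the double-decycling scheme reads one lookahead character
        and overrides this to ``w + k``."""
        return self.w + self.k - 1

    @property
    def effective_k(self) -> int:
        """Word length in the formal (w, k)-local sense: the scheme is a
        (w, effective_k)-local scheme.  Equals ``k`` unless the rule reads
        lookahead characters."""
        return self.window_length - self.w + 1

    def _indices(self, arr: np.ndarray) -> np.ndarray:
        """Sampled in-window index for every window along the last axis."""
        keys = self._keys(arr)
        per_window = self.window_length - self.unit + 1
        win = sliding_window_view(keys, per_window, axis=-1)
        rel = np.argmin(win, axis=-1)
        return self._map_rel(rel)

    def rule(self, window) -> int:
        """The sampling function on a single window of ``window_length``
        symbols (``w + k - 1`` for ordinary schemes)."""
        arr = _as_code_array(window, self.sigma)
        if arr.shape[-1] != self.window_length:
            raise ValueError(
                f"window must have length {self.window_length}, "
                f"got {arr.shape[-1]}"
            )
        return int(self._indices(arr)[0])

    def rule_batch(self, windows: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`rule` over rows of a 2-D window array."""
        if windows.shape[-1] != self.window_length:
            raise ValueError(f"window rows must have length {self.window_length}")
        return self._indices(windows)[..., 0]

    def select(self, seq) -> np.ndarray:
        """Sorted unique 0-based start positions of sampled k-mers."""
        arr = _as_code_array(seq, self.sigma)
        if arr.size < self.window_length:
            import warnings

            warnings.warn(
                f"sequence of length {arr.size} is shorter than one window "
                f"({self.window_length}); nothing sampled",
                stacklevel=2,
            )
            return np.empty(0, dtype=np.int64)
        idx = self._indices(arr)
        pos = np.arange(idx.size, dtype=np.int64) + idx
        return np.unique(pos)

    # -- serialization ----------------------------------------------------
    def to_table(self) -> np.ndarray:
        """Materialize the rule as a lookup table over all windows."""
        from .density import all_strings

        wins = all_strings(self.sigma, self.window_length)
        return self.rule_batch(wins).astype(np.int64)


def select_positions(scheme: SchemeSpec, sequence) -> np.ndarray:
    """Functional alias for :meth:`SchemeSpec.select`."""
    return scheme.select(sequence)


# ---------------------------------------------------------------------------
# minimizer family


@dataclass
class _HashMinimizer(SchemeSpec):
    seed: int = 0

    def _keys(self, arr):
        return hash_codes(substring_codes(arr, self.k, self.sigma), self.seed)


@dataclass
class _LexMinimizer(SchemeSpec):
    def _keys(self, arr):
        return substring_codes(arr, self.k, self.sigma)


def random_minimizer(w: int, k: int, sigma: int, seed: int = 0) -> SchemeSpec:
    """Random minimizer: minimal k-mer under a seeded hash order."""
    return _HashMinimizer(w, k, sigma, name="random_minimizer",
                          params={"seed": seed}, seed=seed)


def lexicographic_minimizer(w: int, k: int, sigma: int) -> SchemeSpec:
    """Minimizer under the k-mer's integer encoding (requires the encoding
    to fit 64 bits: k*log2(sigma) <= 64)."""
    if k * max((sigma - 1).bit_length(), 1) > 64:
        raise ValueError("lexicographic order needs k-mer codes to fit 64 bits")
    return _LexMinimizer(w, k, sigma, name="lexicographic_minimizer")


# ---------------------------------------------------------------------------
# mod-minimizer


def _mod_minimizer_t(w: int, k: int, r: int) -> int:
    """Smallest t >= r with t ≡ k (mod w), capped at k."""
    t = r + (k - r) % w
    return min(t, k)


@dataclass
class _ModMinimizer(SchemeSpec):
    seed: int = 0
    t: int = 1

    @property
    def unit(self) -> int:
        return self.t

    def _keys(self, arr):
        return hash_codes(substring_codes(arr, self.t, self.sigma), self.seed)

    def _map_rel(self, rel):
        return rel % self.w


def mod_minimizer(
    w: int, k: int, sigma: int, seed: int = 0, r: int = 4, t: int | None = None
) -> SchemeSpec:
    """Mod-minimizer: sample the k-mer at position ``p mod w`` where ``p``
    is the position of the window's minimal t-mer.

    ``t`` defaults to the smallest t >= r with t ≡ k (mod w) (capped at k,
    where the scheme degenerates to the random minimizer).  ``t = 1`` is
    the large-alphabet regime in which the scheme approaches the density
    lower bound for k ≡ 1 (mod w).
    """
    t_eff = _mod_minimizer_t(w, k, r) if t is None else t
    if not 1 <= t_eff <= k:
        raise ValueError(f"t must be in [1, k]; got {t_eff}")
    return _ModMinimizer(w, k, sigma, name="mod_minimizer",
                         params={"seed": seed, "r": r, "t": t_eff},
                         seed=seed, t=t_eff)


# ---------------------------------------------------------------------------
# miniception


@dataclass
class _Miniception(SchemeSpec):
    seed: int = 0
    t: int = 1

    def _keys(self, arr):
        # A k-mer is "preferred" when its own leftmost-minimal t-mer sits
        # at offset 0 or k-t (it is a "charged" k-mer of the inner (k-t+1,
        # t)-minimizer).  Preferred k-mers rank before all others; within a
        # rank, order by k-mer hash.
        k, t = self.k, self.t
        t_hash = hash_codes(substring_codes(arr, t, self.sigma), self.seed, stream=1)
        t_win = sliding_window_view(t_hash, k - t + 1, axis=-1)
        t_pos = np.argmin(t_win, axis=-1)
        preferred = (t_pos == 0) | (t_pos == k - t)
        k_hash = hash_codes(substring_codes(arr, k, self.sigma), self.seed)
        keys = k_hash >> np.uint64(1)
        return np.where(preferred, keys, keys | _TOPBIT)


def miniception(
    w: int, k: int, sigma: int, seed: int = 0, t: int | None = None
) -> SchemeSpec:
    """Miniception with inner t-mer parameter (default ``max(4, k - w)``)."""
    t_eff = max(4, k - w) if t is None else t
    t_eff = min(t_eff, k)
    if not 1 <= t_eff <= k:
        raise ValueError(f"t must be in [1, k]; got {t_eff}")
    return _Miniception(w, k, sigma, name="miniception",
                        params={"seed": seed, "t": t_eff}, seed=seed, t=t_eff)


# ---------------------------------------------------------------------------
# double decycling


@dataclass
class _DoubleDecycling(SchemeSpec):
    seed: int = 0

    @property
    def window_length(self) -> int:
        # One lookahead character: the class of the k-mer at position i
        # compares the embeddings at i and i+1, so a window spans w+k
        # characters and the scheme is formally (w, k+1)-local.
        return self.w + self.k

    @property
    def unit(self) -> int:
        return self.k + 1

    def _keys(self, arr):
        # Mykkeltveit embedding P(i) = sum_j arr[i+j] * e^(2 pi i j / k) of
        # every k-mer.  Position i is class 0 (decycling) when Im P crosses
        # zero downwards between i and i+1, class 1 (symmetric set) on an
        # upward crossing, class 2 otherwise.  On a pure cycle of B_k the
        # successor k-mer is the rotation, whose embedding is P rotated by
        # -2*pi/k: each full traversal winds P once around the origin, so
        # exactly one position per (nonzero-embedding) cycle is class 0 —
        # Mykkeltveit's decycling property — and the same holds for class 1.
        k = self.k
        n_emb = arr.shape[-1] - k + 1
        omega = np.exp(2j * np.pi * np.arange(k) / k)
        emb = np.zeros(arr.shape[:-1] + (n_emb,), dtype=np.complex128)
        for j in range(k):
            emb += arr[..., j : j + n_emb] * omega[j]
        im = emb.imag
        up, down = im[..., :-1], im[..., 1:]
        cls = np.full(up.shape, 2, dtype=np.uint64)
        cls[(up <= 0) & (down > 0)] = 1
        cls[(up > 0) & (down <= 0)] = 0
        codes = substring_codes(arr, k, self.sigma)[..., :-1]
        k_hash = hash_codes(codes, self.seed)
        return (cls << np.uint64(62)) | (k_hash >> np.uint64(2))


def double_decycling_minimizer(w: int, k: int, sigma: int, seed: int = 0) -> SchemeSpec:
    """Minimizer ordered by (decycling class, hash): k-mers entering the
    Mykkeltveit decycling set first, then those entering the symmetric
    (negated) set, then the rest.

    Membership is the zero-crossing of the imaginary part of the
    Mykkeltveit embedding between a position and its successor, which on
    De Bruijn cycles coincides with the classic one-per-necklace sector
    rule but is stable against embedding jitter on arbitrary sequences.
    Reads one character beyond the ordinary window (``window_length`` is
    ``w + k``), making it formally a (w, k+1)-local scheme that reports
    k-mer start positions.
    """
    if k < 2:
        raise ValueError("double decycling needs k >= 2")
    return _DoubleDecycling(w, k, sigma, name="double_decycling",
                            params={"seed": seed}, seed=seed)


# ---------------------------------------------------------------------------
# explicit tables


@dataclass
class _TableScheme(SchemeSpec):
    table: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def _indices(self, arr):
        codes = substring_codes(arr, self.window_length, self.sigma)
        return self.table[codes]

    def rule_batch(self, windows):
        if windows.shape[-1] != self.window_length:
            raise ValueError("window rows must have length w+k-1")
        return self._indices(windows)[..., 0]


def table_scheme(w: int, k: int, sigma: int, table) -> SchemeSpec:
    """Scheme backed by an explicit table indexed by the window's
    big-endian integer encoding; entry ``table[code]`` in ``[w]``."""
    tab = np.asarray(table, dtype=np.int64)
    expected = sigma ** (w + k - 1)
    if tab.shape != (expected,):
        raise ValueError(
            f"table must have sigma**(w+k-1) = {expected} entries, got {tab.shape}"
        )
    if tab.size and (tab.min() < 0 or tab.max() >= w):
        raise ValueError("table entries must lie in [0, w)")
    return _TableScheme(w, k, sigma, name="table_scheme", table=tab)


def scheme_to_json(scheme: SchemeSpec) -> str:
    """Serialize any scheme as an explicit table (JSON)."""
    return json.dumps(
        {
            "w": scheme.w,
            "k": scheme.k,
            "sigma": scheme.sigma,
            "name": scheme.name,
            "table": scheme.to_table().tolist(),
        }
    )


def scheme_from_json(text: str) -> SchemeSpec:
    obj = json.loads(text)
    return table_scheme(obj["w"], obj["k"], obj["sigma"], obj["table"])


# ---------------------------------------------------------------------------
# k-extension


@dataclass
class _ExtendedScheme(SchemeSpec):
    base: SchemeSpec = None  # type: ignore[assignment]

    def _indices(self, arr):
        # Windows of the extended scheme ignore their last k - base.k
        # symbols, so drop that many trailing sequence positions and
        # delegate; window counts then line up one-to-one.
        extra = self.k - self.base.k
        trimmed = arr[..., : arr.shape[-1] - extra] if extra else arr
        return self.base._indices(trimmed)

    def rule_batch(self, windows):
        if windows.shape[-1] != self.window_length:
            raise ValueError("window rows must have length w+k-1")
        return self._indices(windows)[..., 0]


def extend_k(scheme: SchemeSpec, k_new: int) -> SchemeSpec:
    """Lift a (w, k)-scheme to (w, k_new >= k) by ignoring the trailing
    ``k_new - k`` characters of each window; the exact density is unchanged."""
    if k_new < scheme.k:
        raise ValueError("k_new must be >= the base scheme's k")
    return _ExtendedScheme(scheme.w, k_new, scheme.sigma,
                           name=f"{scheme.name}_ext{k_new}", base=scheme)
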