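# Methods

## Model and definitions

A `(w, k)`-local sampling scheme over an alphabet of size `σ` is a total
function `f : Σ^(w+k-1) → [w]`; window `W` samples the k-mer starting at
in-window index `f(W)`.  The scheme is *forward* when
`f(W[0, w+k-1)) ≤ f(W[1, w+k)) + 1` for every `(w+k)`-mer `W`, i.e. the
sampled position never moves backwards as the window slides.  Density is
the expected fraction of sampled k-mer positions on an infinite uniform
random string.  It is computed here as the proportion of **charged
contexts**: for forward schemes a context is a `(w+k)`-mer charged iff
`f(prefix) ≠ f(suffix) + 1`; for local schemes a context is a
`(2w+k-2)`-mer charged iff the final window's absolute pick differs from
the picks of all `w - 1` preceding windows.  Internally every sequence is
a `uint8` code array over `[σ]`, DNA mapping `A=0, C=1, G=2, T=3`.

## Lower bounds (module `bounds`)

`g_σ(w,k) = (Σ_{p|w+k} M_σ(p)·⌈p/w⌉) / σ^(w+k)` with `M_σ` the aperiodic
necklace count; the same numerator, `uhs_lower_bound`, bounds the size of
any `(w, ℓ)`-universal hitting set.  `g'` takes the maximum of `g` at `k`
and at `k' = k + ((1-k) mod w)`; `local_scheme_bound` is `g'` at word
length `w+k-2`.  Everything is exact `fractions.Fraction` arithmetic on
Python big integers; floats appear only at display time, with half-even
rounding to 3 decimals in tables.  For `ℓ < w` the UHS formula is applied
as written: cycles shorter than the window still contribute one member
each.  The comparison-only bound `1.5/(w+k-0.5)` is provided but never
used internally.

## Schemes (module `schemes`)

All built-in schemes are minimizers under some total order on their unit
substrings, evaluated by one shared mechanism: compute a `uint64` sort key
per unit position, take the per-window `argmin` (leftmost on ties), map
the relative position to a sampled index.

* **Hash order.**  The splitmix64 finalizer applied to
  `code XOR mix(seed)`, where `code` is the big-endian base-σ encoding.
  The finalizer is a bijection on 64-bit integers, so while encodings fit
  64 bits equal hashes imply equal k-mers; the tie-break is therefore
  simply *leftmost*, which matches minimizer convention.  Encodings
  longer than 64 bits wrap; this only perturbs the (arbitrary) order, not
  determinism.  Distinct hash streams (e.g. miniception's inner t-mer
  order) are derived from the same seed with a stream offset.
* **random_minimizer** — hash order on k-mers; **lexicographic_minimizer**
  — integer-encoding order (teaching/oracle scheme, requires
  `k·log2 σ ≤ 64`).
* **mod_minimizer** — position `p` of the minimal t-mer in the window,
  sample index `p mod w`, with `t` the smallest `t ≥ r` (default `r = 4`)
  congruent to `k (mod w)`, capped at `t = k` (degenerating to the random
  minimizer).  `t = 1` is exposed for large alphabets, where the scheme
  approaches the lower bound for `k ≡ 1 (mod w)`.
* **miniception** — a k-mer is *preferred* when its own leftmost-minimal
  t-mer (`t` defaults to `max(4, k-w)`) sits at offset 0 or `k-t`;
  preferred k-mers rank before all others, hash order within a rank, so a
  window with no preferred k-mer falls back to the plain minimizer choice.
* **double_decycling_minimizer** — k-mers are ranked by a three-way class
  before hash: class 0 for positions entering the Mykkeltveit decycling
  set, class 1 for the symmetric (negated) set, class 2 otherwise.
  Membership is the *zero-crossing rule*: with the embedding
  `P(i) = Σ_j s[i+j]·e^(2πij/k)`, position `i` is class 0 when `Im P` is
  positive at `i` and non-positive at `i+1`, class 1 on the opposite
  crossing.  On a pure cycle of `B_k` the successor k-mer is the rotation
  and `P` rotates by `-2π/k` per step, so this is exactly the classical
  one-per-necklace sector rule; on arbitrary sequences `P` additionally
  drifts with the edited character, and the crossing rule (unlike a
  per-k-mer sector test, which measures ~0.089 at `w = k = 19, σ = 4`)
  keeps selections near-periodic and reproduces the published density of
  this scheme family, 0.079.  The price is one character of lookahead:
  the scheme is formally `(w, k+1)`-local (`window_length = w + k`,
  `effective_k = k + 1`), which the density and forwardness machinery
  handles by working with `window_length` throughout.
* **table_scheme** — an explicit `σ^(w+k-1)`-entry table, the carrier for
  ILP solutions; JSON round-trip preserves the rule bit-for-bit.

`select` returns de-duplicated sorted 0-based k-mer start positions; gaps
never exceed `w`.  Empirical density divides by the number of k-mer
positions `L - k + 1` rather than the window count; the two differ by
`O(w/L)`, irrelevant at the `10^7` lengths used.  Non-alphabet symbols in
FASTA input are rejected by default; `strip` and `skip-split` policies
are available, the latter mirroring the usual practice of cutting
sequences at N runs.

## Exact densities and enumeration budgets (module `density`)

Exact density enumerates all `σ^ℓ` contexts (`ℓ = window_length + 1`
forward, `window_length + w - 1` local) with vectorized batch rule
evaluation; the default budget of `10^7` contexts guards memory and time
and can be raised explicitly.  `is_forward` checks the forwardness
inequality exhaustively within budget, else falls back to seeded sampling
with a warning.  `verify_uhs` checks every length-`(ℓ+w-1)` string for a
member substring.  Two independent oracles back these paths in the test
suite: a pure-cycle walk of `B_ℓ` (each necklace rotation is a context)
and a scalar sliding-window simulation.

## ILP search (module `ilp`)

Forward mode: integer `x_W ∈ [w]` per window, binary `y_e` per De Bruijn
edge, forwardness `x_u - x_v ≤ 1`, charging linearized with the tight
big-M `M = w`, objective `min Σ y_e`.  Pure-cycle cuts (at least
`⌈|c|/w⌉` charged edges per pure cycle of `B_{w+k}`) are valid because
they restate the necklace bound; they are on by default and never change
the optimum (asserted on small instances), only the solve time.

Local mode uses a one-hot assignment encoding `b_{W,j}` with
`Σ_j b_{W,j} = 1` and, per context and final pick `j`,
`y_C ≥ b_{last,j} - Σ_{i≥j} b_{W_i, j+w-1-i}`; the `y_C` stay continuous
because their bounds are integral once the `b` are.  A big-M model over
integer `x_W` was implemented first and benchmarked: its LP relaxation is
so weak that the open-source backend finds no good incumbent at
`(σ=2, w=4, k=2)` within minutes, so the assignment model replaced it.

Backend is HiGHS via `scipy.optimize.milp` (single-threaded,
deterministic), behind a solver-agnostic sparse model description.  Every
returned table is re-validated by exhaustive charged-context enumeration;
the reported density is never read off the solver objective.

**Known limitation.**  At `(σ=2, w=4, k=2)` in local mode HiGHS cannot
close the duality gap in any desk-scale budget (the dual bound sits near
42 against an optimum of 95 after minutes of branching).  `solve_local`
is therefore a matheuristic: a bounded, deterministic branch-and-bound
pass (default `node_limit = 250`) followed by a deterministic 1- and
2-entry descent on the exhaustively recomputed charged count, seeded from
the solver incumbent and from the optimal forward scheme (always local-
feasible).  It returns status `feasible` when optimality is not proved.
The search attains 95/256 ≈ 0.371 at `(2, 4, 2)` — below the forward
optimum 96/256 = 0.375 — in well under two minutes, but its minimality is
certified only by external evidence, not by this package's solver.  Tiny
instances (e.g. `(σ=2, w=2, k≤2)`) are still proved optimal outright.

## Synthetic sequences and what the tests show

Benchmark sequences are i.i.d. uniform symbols from a seeded PCG64
generator, 10^7 characters for density benchmarks (10^6-window scale for
the large-alphabet check), matching the protocol under which the
reference densities were measured.  Uniform random text has no repeats,
skew or non-ACGT symbols; measured densities transfer to genomic
sequence only approximately (repetitive DNA shifts per-sequence selected
fractions), so FASTA-based measurement is provided for real inputs.
Empirical densities at `n ≈ 10^7` carry sampling error around `1.5·10^-4`,
comfortably inside the ±0.001 tolerance used in the tests.

## Problem sizes and defaults

Exact enumeration and ILP instances are capped by explicit budgets
(`10^7` contexts; `2^18` model contexts) reflecting their role: verifying
structure and reproducing small-parameter optima, not large-scale search.
The acceptance script uses 10^7-character benchmarks, the `(2, 4, 2)` ILP
instances and a 2·10^6-character 256-letter sequence; it completes in a
few minutes on one CPU.  Default seeds for examples are arbitrary small
integers; all randomness flows through explicit seed arguments and is
bit-reproducible across runs.
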