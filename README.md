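# minidens

Density analysis of k-mer sampling schemes: exact lower bounds, exact and
empirical densities of minimizer-family schemes, and ILP search for
provably minimum-density schemes.

## The problem

Most k-mer based methods (mappers, indexers, taxonomic classifiers) do not
look at every k-mer of a sequence: a *sampling scheme* picks one k-mer out
of every window of `w` consecutive ones, so any two sequences sharing a
long enough stretch share a sampled k-mer (the *window guarantee*).
Formally, a `(w, k)`-local scheme is a function `f : Σ^(w+k-1) → [w]`
mapping each window to the index of the sampled k-mer; it is *forward* if
the sampled position never moves backwards between adjacent windows.  The
cost of a scheme is its **density** `d(f)`: the expected fraction of k-mer
positions sampled from a uniform random string.  Lower density means
smaller indexes and faster downstream work, so the central question is how
low `d(f)` can go for given `(w, k, σ)`.

## The bound at the core

Density equals the proportion of *charged contexts* — strings of `w + k`
characters (for forward schemes) whose last window samples a fresh
position — and the charged contexts form a `(w, w+k)`-universal hitting
set: every `w` consecutive `(w+k)`-mers contain one.  Universal hitting
sets in turn must intersect every pure cycle (necklace) of the De Bruijn
graph `B_{w+k}` at least `⌈p/w⌉` times per cycle of length `p`.  Counting
necklaces with the Möbius formula `M_σ(p) = (1/p) Σ_{d|p} μ(p/d) σ^d`
gives, for every `(w, k)`-forward scheme `f`,

    d(f)  ≥  g_σ(w, k)  =  (1/σ^(w+k)) Σ_{p | w+k} M_σ(p) ⌈p/w⌉
          ≥  ⌈(w+k)/w⌉ / (w+k)  ≥  1/w ,

and, because a scheme may ignore trailing characters (so minimum density
is monotone in `k` while `g` is not),

    d(f)  ≥  g'_σ(w, k) = max( g_σ(w, k), g_σ(w, k') ),

with `k'` the smallest `k' ≥ k` congruent to `1 (mod w)`.  Local schemes
obey `d(f) ≥ g'_σ(w, w+k-2)`.  All bounds are computed in exact
big-integer rational arithmetic.

The package also implements the schemes this bound is measured against —
random (hash-ordered) minimizers, the lexicographic minimizer, the
mod-minimizer, miniception and the double-decycling minimizer — plus
exhaustive charged-context enumeration, UHS verification, and a MILP
(HiGHS) search for minimum-density forward and local schemes on small
instances, with every solver result re-verified by enumeration.

## Worked example

```python
from minidens import bounds, density, io, schemes

# exact lower bound for minimap2's HiFi defaults (w=19, k=19, DNA)
gp = bounds.lower_bound_g_prime(4, 19, 19)
print(gp.rounded(3), gp.k_prime)        # 0.077 20

# measure the double-decycling minimizer on 10M random characters
seq = io.random_sequence(4, 10_000_000, seed=42)
sch = schemes.double_decycling_minimizer(19, 19, 4, seed=7)
d = density.empirical_density(sch, seq)
print(round(d.value, 3))                # 0.079
print(round(100 * (d.value - gp.value_float) / gp.value_float, 1))  # 2.7
```

The three numbers say: no forward scheme at these parameters can have
density below 0.077; the double-decycling minimizer achieves 0.079 — only
2.7 % above the proven optimum, compared with ~50 % slack against the old
`1/w` bound.  The `examples/` directory has one short script per
capability (bounds, empirical densities, exact densities and UHS checks,
ILP optima, FASTA sampling), and the `minidens` CLI exposes the same
operations (`minidens bound`, `density`, `sample`, `optimize`,
`necklaces`, `table1`).

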