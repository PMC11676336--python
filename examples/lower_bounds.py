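"""Exact density lower bounds for forward sampling schemes.

For each (w, k) pair used by popular k-mer tools, print the necklace-based
lower bound g, the improved bound g' = max(g(k), g(k')) with k' the next
k-mer length congruent to 1 mod w, the alphabet-free approximation
ceil((w+k)/w)/(w+k), and the classic 1/w bound.  Any forward scheme's
density is at least g'; the gap between g' and the best known schemes is
only a few percent for k >= w.
"""

from minidens import bounds

print(f"{'(w, k)':>10} {'1/w':>7} {'simple':>7} {'g':>7} {'g_prime':>8} {'k_prime':>7}")
for w, k in [(5, 31), (12, 20), (19, 19)]:
    g = bounds.lower_bound_g(4, w, k)
    gp = bounds.lower_bound_g_prime(4, w, k)
    simple = bounds.simple_bound(w, k)
    print(f"({w:>3}, {k:>2}) {1 / w:7.3f} {float(simple):7.3f} "
          f"{g.value_float:7.3f} {gp.value_float:8.3f} {gp.k_prime:7d}")

print()
print("g' for (19, 19) as an exact fraction:",
      bounds.lower_bound_g_prime(4, 19, 19).value_exact)
print("The improved bound comes from k' = 20: g is not monotone in k, but")
print("minimum scheme density is, so the bound at k' also applies at k.")
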