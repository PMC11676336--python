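"""Exact densities by charged-context enumeration, and the UHS property.

At small parameters a scheme's density can be computed exactly: enumerate
every context (w + k characters for a forward scheme), and count those
whose last window samples a new position.  The charged contexts always
form a (w, w+k)-universal hitting set — every w consecutive contexts of a
longer string contain a charged one — which is verified here explicitly.
"""

from minidens import bounds, density, schemes

lex = schemes.lexicographic_minimizer(2, 1, 2)
cs = density.charged_contexts_forward(lex)
est = density.exact_density(lex)
print(f"lexicographic minimizer (w=2, k=1, sigma=2):")
print(f"  charged contexts : {len(cs)} of {2 ** cs.context_length}")
print(f"  exact density    : {est.exact_fraction} = {est.value}")
print(f"  lower bound g    : {bounds.lower_bound_g(2, 2, 1).value_exact}"
      "  (tight here: k = 1)")
print(f"  charged set is a (2, {cs.context_length})-UHS:",
      density.verify_uhs(cs, 2))

print()
mod = schemes.mod_minimizer(3, 4, 2, seed=1, r=1)
ok, _ = density.is_forward(mod)
print(f"mod-minimizer (w=3, k=4, sigma=2, t={mod.params['t']}):")
print(f"  forward (checked exhaustively): {ok}")
print(f"  exact density: {density.exact_density(mod).exact_fraction}")
print(f"  local-context density agrees: "
      f"{density.exact_density(mod, mode='local').exact_fraction}")
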