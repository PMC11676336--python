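"""Sampling k-mer positions from FASTA records.

Builds a toy FASTA file, samples it with a random minimizer, and prints
the selected k-mer start positions per record.  Consecutive selected
positions are never more than w apart (the window guarantee), which is
what makes minimizer sketches usable for indexing and seeding.
"""

import tempfile
from pathlib import Path

import numpy as np

from minidens import io, schemes

fasta = Path(tempfile.mkdtemp()) / "toy.fa"
rng = np.random.default_rng(0)
seqs = {
    "chr_toy": "".join(rng.choice(list("ACGT"), size=120)),
    "plasmid": "".join(rng.choice(list("ACGT"), size=60)),
}
fasta.write_text("".join(f">{name}\n{s}\n" for name, s in seqs.items()))

w, k = 5, 11
scheme = schemes.random_minimizer(w, k, sigma=4, seed=3)
for rec in io.read_fasta(fasta):
    pos = scheme.select(rec.seq)
    frac = len(pos) / (len(rec.seq) - k + 1)
    print(f"{rec.id}: {len(rec.seq)} bp -> {len(pos)} sampled {k}-mers "
          f"(density {frac:.2f}, max gap {np.diff(pos).max()})")
    print("  positions:", pos.tolist())
print(f"\nEvery gap is <= w = {w}; expected density ~ 2/(w+1) = {2 / (w + 1):.2f}.")
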