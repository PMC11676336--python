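"""Sequence I/O, alphabet encoding, and seeded random sequences.

Internal alphabet is always ``[sigma] = {0, ..., sigma-1}`` as uint8 codes.
DNA maps ``A->0, C->1, G->2, T->3`` (case-insensitive); digit strings
``"0".."9"`` map to their values for small non-DNA alphabets.  Out-of-
alphabet symbols in FASTA input are handled by policy: ``reject`` (error),
``skip-split`` (cut the record into valid fragments, mirroring the common
practice of splitting at N runs), or ``strip`` (drop the symbols).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "DNA_ALPHABET",
    "as_codes",
    "codes_to_dna",
    "read_fasta",
    "random_sequence",
]

DNA_ALPHABET = "ACGT"

_DNA_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(DNA_ALPHABET):
    _DNA_CODE[ord(_c)] = _i
    _DNA_CODE[ord(_c.lower())] = _i

_DIGIT_CODE = np.full(256, 255, dtype=np.uint8)
for _d in range(10):
    _DIGIT_CODE[ord(str(_d))] = _d


@dataclass
class SequenceRecord:
    id: str
    seq: np.ndarray  # uint8 codes


def as_codes(seq, sigma: int) -> np.ndarray:
    """Convert a sequence to uint8 codes over ``[sigma]``.

    Accepts a numpy array (validated), a DNA string (sigma == 4), a digit
    string (sigma <= 10), or any iterable of ints.
    """
    if isinstance(seq, np.ndarray):
        arr = seq.astype(np.uint8, copy=False)
    elif isinstance(seq, str):
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        if sigma == 4 and len(seq) and seq[0].upper() in DNA_ALPHABET:
            arr = _DNA_CODE[raw]
            if (arr == 255).any():
                bad = seq[int(np.flatnonzero(arr == 255)[0])]
                raise ValueError(f"invalid DNA symbol {bad!r}")
        else:
            arr = _DIGIT_CODE[raw]
            if (arr == 255).any():
                bad = seq[int(np.flatnonzero(arr == 255)[0])]
                raise ValueError(f"invalid digit symbol {bad!r}")
    else:
        arr = np.asarray(list(seq), dtype=np.uint8)
    if arr.size and arr.max() >= sigma:
        raise ValueError(
            f"symbol code {arr.max()} out of range for alphabet size {sigma}"
        )
    return arr


def codes_to_dna(arr: np.ndarray) -> str:
    return "".join(DNA_ALPHABET[int(c)] for c in arr)


def read_fasta(
    path: str | Path, alphabet_policy: str = "reject", sigma: int = 4
) -> list[SequenceRecord]:
    """Read a (multi-record) FASTA file into coded records.

    ``alphabet_policy``: ``reject`` raises on any out-of-alphabet symbol;
    ``skip-split`` splits each record into maximal valid fragments (ids
    suffixed ``/1``, ``/2``, ...); ``strip`` silently removes the symbols.
    """
    if alphabet_policy not in ("reject", "skip-split", "strip"):
        raise ValueError(f"unknown alphabet policy {alphabet_policy!r}")
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = np.frombuffer(str(rec.seq).encode("ascii"), dtype=np.uint8)
        table = _DNA_CODE if sigma == 4 else _DIGIT_CODE
        codes = table[raw]
        valid = codes != 255
        if sigma != 4:
            valid &= codes < sigma
        if valid.all():
            if raw.size:
                records.append(SequenceRecord(id=rec.id, seq=codes))
            continue
        if alphabet_policy == "reject":
            pos = int(np.flatnonzero(~valid)[0])
            raise ValueError(
                f"record {rec.id!r}: invalid symbol {chr(raw[pos])!r} at "
                f"position {pos} (use --policy strip or skip-split)"
            )
        if alphabet_policy == "strip":
            kept = codes[valid]
            if kept.size:
                records.append(SequenceRecord(id=rec.id, seq=kept))
            continue
        # skip-split: maximal runs of valid symbols become fragments
        boundaries = np.flatnonzero(np.diff(valid.astype(np.int8)))
        starts = [0] if valid[0] else []
        starts += [int(b) + 1 for b in boundaries if valid[b + 1]]
        ends = [int(b) + 1 for b in boundaries if valid[b]]
        if valid[-1]:
            ends.append(len(codes))
        for j, (s, e) in enumerate(zip(starts, ends), start=1):
            records.append(SequenceRecord(id=f"{rec.id}/{j}", seq=codes[s:e]))
    return records


def random_sequence(sigma: int, length: int, seed: int) -> np.ndarray:
    """I.i.d. uniform symbols over ``[sigma]``, reproducible per seed."""
    if length < 0:
        raise ValueError("length must be >= 0")
    rng = np.random.default_rng(seed)
    return rng.integers(0, sigma, size=length, dtype=np.uint8)
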