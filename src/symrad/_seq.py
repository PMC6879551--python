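"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_seq(length: int, rng: np.random.Generator) -> str:
    """Uniform i.i.d. A/C/G/T string of the given length."""
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def mutate_base(base: str, rng: np.random.Generator) -> str:
    """A uniformly chosen base different from ``base``."""
    choices = [b for b in BASES if b != base]
    return choices[rng.integers(0, 3)]
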