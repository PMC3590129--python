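"""Low-level nucleotide-sequence helpers shared across the pipeline."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA string of the given length."""
    return "".join(np.array(list(DNA))[rng.integers(0, 4, size=length)])


def phred_to_ascii(quals) -> str:
    """Encode integer Phred scores as a Phred+33 quality string."""
    return "".join(chr(q + 33) for q in quals)


def ascii_to_phred(qual_str: str) -> list[int]:
    """Decode a Phred+33 quality string to integer scores."""
    return [ord(c) - 33 for c in qual_str]
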