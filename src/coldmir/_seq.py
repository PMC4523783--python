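"""Small sequence helpers shared across the pipeline.

All sequences are held internally in the DNA alphabet (T, upper case);
miRNA-facing outputs convert back to RNA (U).
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DNA_BASES = ("A", "C", "G", "T")


def as_dna(seq: str) -> str:
    """Normalise a nucleotide string to upper-case DNA (U -> T)."""
    return seq.upper().replace("U", "T")


def as_rna(seq: str) -> str:
    """Render a (DNA-internal) sequence in the RNA alphabet."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return as_dna(seq).translate(_COMPLEMENT)[::-1]


def random_seq(length: int, rng: np.random.Generator, gc_fraction: float = 0.5) -> str:
    """Random DNA string with the requested expected GC content."""
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    return "".join(
        rng.choice(np.array(DNA_BASES), size=length, p=[p_at, p_gc, p_gc, p_at])
    )


def is_watson_crick(a: str, b: str) -> bool:
    """True if DNA bases a, b form a Watson-Crick pair (A:T or G:C)."""
    return (a, b) in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def is_wobble(a: str, b: str) -> bool:
    """True if DNA bases a, b form a G:U wobble (G:T / T:G in DNA letters)."""
    return (a, b) in {("G", "T"), ("T", "G")}


def can_pair(a: str, b: str) -> bool:
    """Watson-Crick or wobble pair."""
    return is_watson_crick(a, b) or is_wobble(a, b)
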