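"""Low-level nucleotide sequence helpers shared across modules."""
from __future__ import annotations

import numpy as np

#: alphabet the aligner understands; anything else is normalized to N on ingestion
ALPHABET = "ACGTN"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base -> integer code; 0..3 = A,C,G,T, 4 = N / anything else.
# Code 4 never matches, not even against itself.
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i

_VALID = set(ALPHABET) | set(ALPHABET.lower())


def normalize(seq: str) -> str:
    """Uppercase ``seq`` and collapse any symbol outside A/C/G/T/N to N."""
    up = seq.upper()
    if all(c in _VALID for c in seq):
        return up
    return "".join(c if c in ALPHABET else "N" for c in up)


def encode(seq: str) -> np.ndarray:
    """Encode a (normalized) sequence as int8 codes for vectorized scoring."""
    if not seq:
        return np.empty(0, dtype=np.int8)
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    """Reverse-complement over {A,C,G,T,N}, case-insensitive; N maps to N.

    Raises ValueError naming the first offending character outside the alphabet.
    """
    for c in seq:
        if c not in _VALID:
            raise ValueError(f"cannot reverse-complement unknown symbol {c!r}")
    return seq.upper().translate(_COMPLEMENT)[::-1]
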