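"""Base-level encodings shared by the simulator and the exact matcher.

Bases are encoded A=0, C=1, G=2, T=3; anything else (N, IUPAC ambiguity)
maps to 4 and is treated as unmatchable. The 2-bit code is chosen so that
``code ^ 2`` is the transition partner (A<->G, C<->T), ``code ^ 1`` and
``code ^ 3`` the two transversion partners, and ``3 - code`` the complement.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)

ENCODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    ENCODE_TABLE[ord(_b)] = _i
    ENCODE_TABLE[ord(_b.lower())] = _i

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string to uint8 codes (non-ACGT -> 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return ENCODE_TABLE[raw]


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes (all < 4) back to an ACGT string."""
    return _LETTERS[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """GC fraction over A/C/G/T calls only."""
    codes = encode(seq)
    acgt = codes < 4
    n = int(acgt.sum())
    if n == 0:
        return float("nan")
    gc = int(((codes == 1) | (codes == 2)).sum())
    return gc / n
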