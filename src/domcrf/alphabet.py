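"""The 21-letter amino-acid alphabet used for column statistics.

Gaps are treated as a 21st residue type, so every alignment column is a
categorical variable over exactly ``N_SYMBOLS = 21`` states and joint tables
over a column pair have 441 cells.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + GAP
N_SYMBOLS = len(ALPHABET)  # 21
N_JOINT = N_SYMBOLS * N_SYMBOLS  # 441

SYMBOL_INDEX: dict[str, int] = {s: i for i, s in enumerate(ALPHABET)}
GAP_CODE = SYMBOL_INDEX[GAP]

# Ambiguity/rare codes without a column of their own; mapped to gap so the
# alphabet stays exactly 21 symbols.
_NONSTANDARD = set("BZXJUO*")

_warned: set[str] = set()


def normalize_char(ch: str) -> str:
    """Map one alignment character onto the 21-letter alphabet.

    Stockholm insert-state conventions ('.' and lowercase) become the gap
    character; ambiguity codes (B, Z, X, J, U, O) and '*' are mapped to gap
    with a one-time warning per character.
    """
    if ch in SYMBOL_INDEX:
        return ch
    if ch in (".", "~") or ch.islower():
        return GAP
    up = ch.upper()
    if up in SYMBOL_INDEX:
        return up
    if up in _NONSTANDARD:
        if up not in _warned:
            _warned.add(up)
            logger.warning("non-standard residue %r mapped to gap", ch)
        return GAP
    if ch not in _warned:
        _warned.add(ch)
        logger.warning("unknown alignment character %r mapped to gap", ch)
    return GAP


def encode(seq: str) -> np.ndarray:
    """Encode an aligned sequence as int8 codes into ``ALPHABET``."""
    return np.fromiter(
        (SYMBOL_INDEX[normalize_char(c)] for c in seq), dtype=np.int8, count=len(seq)
    )


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[int(c)] for c in codes)
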