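"""The integrated sequence-structure alphabet.

An RNA hairpin carries two strings of information: the nucleotide sequence
(A/C/G/U) and the secondary structure in dot-bracket notation, where ``(``
marks the 5' partner of a base pair, ``)`` the 3' partner and ``.`` an
unpaired base.  Both are folded into a single alphabet of *ss-symbols*: one
symbol per position, combining a nucleotide notation from ``{A, C, G, U, N}``
with a structure notation from ``{L, D, R, S}``.

``L``/``D``/``R`` are the structural states derived from ``(``/``.``/``)``.
The letters ``N`` ("any nucleotide") and ``S`` ("any intra-molecular
interaction") are wildcards: a concrete hairpin position is always fully
specified (nucleotide != N and structure != S), whereas motif positions may
wildcard either character or both.
"""

from __future__ import annotations

from typing import NamedTuple

NUCLEOTIDES = "ACGUN"
STRUCTURES = "LDRS"

NUC_CODE = {c: i for i, c in enumerate(NUCLEOTIDES)}
STR_CODE = {c: i for i, c in enumerate(STRUCTURES)}

#: code of the nucleotide wildcard "N"
NUC_N = NUC_CODE["N"]
#: code of the structure wildcard "S"
STR_S = STR_CODE["S"]

DOT_TO_STRUCT = {"(": "L", ".": "D", ")": "R"}
STRUCT_TO_DOT = {v: k for k, v in DOT_TO_STRUCT.items()}


class SSSymbol(NamedTuple):
    """One position of integrated sequence-structure information."""

    nuc: str
    struct: str

    @property
    def nuc_code(self) -> int:
        return NUC_CODE[self.nuc]

    @property
    def struct_code(self) -> int:
        return STR_CODE[self.struct]

    @property
    def defined_char_count(self) -> int:
        """Number of non-wildcard characters (0, 1 or 2)."""
        return int(self.nuc != "N") + int(self.struct != "S")

    @property
    def is_concrete(self) -> bool:
        return self.nuc != "N" and self.struct != "S"

    def __str__(self) -> str:  # compact two-character rendering, e.g. "UL"
        return self.nuc + self.struct


def make_symbol(nuc: str, struct: str) -> SSSymbol:
    """Validated :class:`SSSymbol` constructor."""
    if nuc not in NUC_CODE:
        raise ValueError(f"illegal nucleotide notation {nuc!r} (expected one of {NUCLEOTIDES})")
    if struct not in STR_CODE:
        raise ValueError(f"illegal structure notation {struct!r} (expected one of {STRUCTURES})")
    return SSSymbol(nuc, struct)


def symbol_from_codes(nuc_code: int, struct_code: int) -> SSSymbol:
    return SSSymbol(NUCLEOTIDES[nuc_code], STRUCTURES[struct_code])


def symbol_matches(pattern: SSSymbol, concrete: SSSymbol) -> bool:
    """Wildcard-aware match of a pattern symbol against a concrete symbol.

    True iff the pattern nucleotide is ``N`` or equal, and the pattern
    structure is ``S`` or equal.  The concrete symbol must be fully specified.
    """
    if not concrete.is_concrete:
        raise ValueError(f"second argument must be a concrete symbol, got {concrete}")
    return (pattern.nuc == "N" or pattern.nuc == concrete.nuc) and (
        pattern.struct == "S" or pattern.struct == concrete.struct
    )


def symbols_to_text(symbols) -> str:
    """Compact serialization, e.g. ``NLULNSCS``."""
    return "".join(str(s) for s in symbols)


def symbols_to_human(symbols) -> str:
    """Human-readable serialization, e.g. ``N_L U_L N_S C_S``."""
    return " ".join(f"{s.nuc}_{s.struct}" for s in symbols)


def parse_symbols(text: str) -> tuple[SSSymbol, ...]:
    """Parse either the compact (``NLUL``) or human (``N_L U_L``) motif text."""
    text = text.strip()
    if not text:
        return ()
    if "_" in text or " " in text:
        parts = text.replace("_", "").split()
    else:
        if len(text) % 2:
            raise ValueError(f"compact ss-symbol text has odd length: {text!r}")
        parts = [text[i : i + 2] for i in range(0, len(text), 2)]
    return tuple(make_symbol(p[0], p[1]) for p in parts)
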