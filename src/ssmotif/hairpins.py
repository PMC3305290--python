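"""Hairpin records, ss-string encoding, and corpus hygiene filters.

A hairpin record pairs an RNA sequence with its secondary structure in
dot-bracket notation (equal length, well-nested, single bracket tier).  The
record is rendered as an *ss-string*: one fully-specified ss-symbol per
position, combining the base with its structural state (``(`` -> L,
``.`` -> D, ``)`` -> R).  Encoding is lossless and invertible.

Corpus hygiene follows the training-set construction used for precursor
classification: hairpins whose structure contains more than one terminal
loop are rejected, and near-identical sequences (global-alignment identity
above a threshold, default 90%) are collapsed by a greedy keep-first scan.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .alphabet import (
    DOT_TO_STRUCT,
    NUC_CODE,
    STR_CODE,
    STRUCT_TO_DOT,
    SSSymbol,
    symbol_from_codes,
    symbols_to_text,
)

_RNA_MAP = str.maketrans("acgutTn", "ACGUUUN")
_VALID_RNA = frozenset("ACGU")
_VALID_DOTS = frozenset("(.)")


def normalize_rna(sequence: str) -> str:
    """Upper-case and map T/t to U (database conventions vary)."""
    return sequence.translate(_RNA_MAP)


@dataclass(frozen=True)
class SSString:
    """A concrete hairpin as an ss-string (arrays of nucleotide/structure codes)."""

    nuc: np.ndarray
    struct: np.ndarray

    def __len__(self) -> int:
        return len(self.nuc)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SSString)
            and np.array_equal(self.nuc, other.nuc)
            and np.array_equal(self.struct, other.struct)
        )

    def __hash__(self) -> int:
        return hash((self.nuc.tobytes(), self.struct.tobytes()))

    @property
    def symbols(self) -> tuple[SSSymbol, ...]:
        return tuple(symbol_from_codes(n, s) for n, s in zip(self.nuc, self.struct))

    @property
    def text(self) -> str:
        return symbols_to_text(self.symbols)


@dataclass(frozen=True)
class MatureAnnotation:
    """0-based positions of the mature-arm boundaries on the hairpin.

    ``mir_start`` is the 5'-most nucleotide of the mature miRNA (or miRNA*,
    whichever lies on the 5' arm); ``mir_end`` the 3'-most nucleotide of the
    star (or mature) strand on the 3' arm.
    """

    mir_start: int
    mir_end: int

    def __post_init__(self):
        if not (0 <= self.mir_start < self.mir_end):
            raise ValueError(
                f"require 0 <= mir_start < mir_end, got ({self.mir_start}, {self.mir_end})"
            )


@dataclass
class Hairpin:
    """A labelled hairpin record: id, sequence, dot-bracket structure."""

    id: str
    sequence: str
    structure: str
    label: str = "unknown"
    mature: MatureAnnotation | None = None

    def __post_init__(self):
        self.sequence = normalize_rna(self.sequence)
        if len(self.sequence) != len(self.structure):
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != "
                f"structure length {len(self.structure)}"
            )
        bad = set(self.structure) - _VALID_DOTS
        if bad:
            raise ValueError(f"{self.id}: illegal structure characters {sorted(bad)}")
        if self.label not in ("positive", "negative", "unknown"):
            raise ValueError(f"{self.id}: illegal label {self.label!r}")
        if self.mature is not None and self.mature.mir_end >= len(self.sequence):
            raise ValueError(f"{self.id}: mature annotation exceeds hairpin length")

    def encode(self) -> SSString:
        return encode_ss_string(self.sequence, self.structure)

    def replace(self, **kw) -> "Hairpin":
        return dataclasses.replace(self, **kw)


def encode_ss_string(sequence: str, structure: str) -> SSString:
    """Render a sequence + dot-bracket pair as a single ss-string.

    T/t are mapped to U and the sequence case-folded before encoding;
    position ``i`` becomes the symbol ``(sequence[i], {"(": L, ".": D,
    ")": R}[structure[i]])``.  Round-trips losslessly with
    :func:`decode_ss_string`.
    """
    sequence = normalize_rna(sequence)
    if len(sequence) != len(structure):
        raise ValueError(
            f"sequence length {len(sequence)} != structure length {len(structure)}"
        )
    nuc = np.empty(len(sequence), dtype=np.uint8)
    struct = np.empty(len(sequence), dtype=np.uint8)
    for i, (b, d) in enumerate(zip(sequence, structure)):
        if b not in _VALID_RNA:
            raise ValueError(f"illegal sequence character {b!r} at position {i}")
        if d not in DOT_TO_STRUCT:
            raise ValueError(f"illegal structure character {d!r} at position {i}")
        nuc[i] = NUC_CODE[b]
        struct[i] = STR_CODE[DOT_TO_STRUCT[d]]
    return SSString(nuc=nuc, struct=struct)


def decode_ss_string(ss: SSString) -> tuple[str, str]:
    """Invert :func:`encode_ss_string`; rejects wildcard-bearing strings."""
    symbols = ss.symbols
    for i, sym in enumerate(symbols):
        if not sym.is_concrete:
            raise ValueError(f"wildcard symbol {sym} at position {i}; cannot decode")
    sequence = "".join(s.nuc for s in symbols)
    structure = "".join(STRUCT_TO_DOT[s.struct] for s in symbols)
    return sequence, structure


def check_balanced(structure: str) -> None:
    """Reject unbalanced or ill-nested dot-bracket strings."""
    depth = 0
    for i, c in enumerate(structure):
        if c not in _VALID_DOTS:
            raise ValueError(f"illegal structure character {c!r} at position {i}")
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced structure: ')' at position {i} has no partner")
    if depth != 0:
        raise ValueError(f"unbalanced structure: {depth} unclosed '('")


def is_single_loop(structure: str) -> bool:
    """True iff the structure has exactly one terminal loop.

    Equivalent, for well-nested structures, to: no ``(`` occurs after the
    first ``)``.  Bulges and internal loops are allowed; multi-branched
    structures are not.
    """
    check_balanced(structure)
    seen_close = False
    for c in structure:
        if c == ")":
            seen_close = True
        elif c == "(" and seen_close:
            return False
    return True


def pair_map(structure: str) -> dict[int, int]:
    """Map every paired position to its partner (both directions)."""
    check_balanced(structure)
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
    return pairs


def _make_aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = 0
    aligner.extend_gap_score = 0
    return aligner


def alignment_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: matches / alignment columns (end gaps count)."""
    if not seq_a or not seq_b:
        return 0.0
    aligner = _make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    return aln.counts().identities / aln.length


def filter_redundant(hairpins: list[Hairpin], identity_threshold: float = 0.9) -> list[Hairpin]:
    """Greedy keep-first redundancy filter.

    Scanning in input order, a hairpin is dropped iff its global-alignment
    identity with any already-kept hairpin exceeds the threshold.  The scan
    order makes the result deterministic, and the operation idempotent.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError(f"identity threshold must be in (0, 1], got {identity_threshold}")
    if not hairpins:
        raise ValueError("need at least one hairpin")
    kept: list[Hairpin] = []
    for hp in hairpins:
        if all(alignment_identity(hp.sequence, k.sequence) <= identity_threshold for k in kept):
            kept.append(hp)
    return kept


def split_train_test(
    positives: list[Hairpin],
    negatives: list[Hairpin],
    n_train: int,
    seed: int | np.random.Generator,
) -> tuple[list[Hairpin], list[Hairpin]]:
    """Per-class uniform random split into ``n_train`` training hairpins + rest.

    Returns ``(train, test)`` with positives preceding negatives in each part;
    reproducible given the seed.
    """
    if not positives or not negatives:
        raise ValueError("both classes must be nonempty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    train: list[Hairpin] = []
    test: list[Hairpin] = []
    for group in (positives, negatives):
        if n_train >= len(group):
            raise ValueError(f"n_train={n_train} must be < class size {len(group)}")
        order = rng.permutation(len(group))
        chosen = set(order[:n_train].tolist())
        train.extend(hp for i, hp in enumerate(group) if i in chosen)
        test.extend(hp for i, hp in enumerate(group) if i not in chosen)
    return train, test
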