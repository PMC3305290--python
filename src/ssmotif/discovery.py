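"""Maximal variable-length ss-motif discovery under the <L,W,K> constraints.

An *ss-motif* is a variable-length pattern over ss-symbols in which each
position may specify the base only (e.g. ``U_S``), the structural state only
(``N_L``), both (``A_L``) or neither (``N_S``).  Three parameters govern
discovery, in the style of Teiresias-type pattern mining:

* **density <L,W>** — writing the pattern as a character string with two
  characters per position (nucleotide char, then structure char), every
  contiguous run of ``W`` characters must contain at least ``L`` defined
  (non-wildcard) characters; patterns spanning fewer than ``W`` characters
  must contain at least ``L`` defined characters in total.  The first and
  last position must carry at least one defined character.  Defaults
  ``L=4, W=12``.
* **support K** — the pattern must occur in at least ``K`` distinct corpus
  ss-strings (sequence support, not occurrence count).
* **maximality** — no valid pattern that is strictly more specific (some
  wildcard characters replaced by literals) or longer (extended left or
  right) has the identical occurrence list.

:func:`discover_motifs` returns exactly the set of maximal valid patterns
with support >= K.  :func:`brute_force_discover` is an independent
enumeration oracle with the same contract, usable only on tiny instances.
"""

from __future__ import annotations

import itertools
import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import (
    NUC_N,
    STR_S,
    NUCLEOTIDES,
    STRUCTURES,
    SSSymbol,
    parse_symbols,
    symbols_to_human,
    symbols_to_text,
)
from .hairpins import SSString

__all__ = [
    "SSMotif",
    "MotifRecord",
    "MotifCatalog",
    "is_valid_pattern",
    "maximal_valid_windows",
    "occurrences",
    "support",
    "discover_motifs",
    "brute_force_discover",
    "merge_catalogs",
]


@dataclass(frozen=True)
class SSMotif:
    """A variable-length pattern of (possibly partially wildcarded) ss-symbols."""

    symbols: tuple[SSSymbol, ...]

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def text(self) -> str:
        return symbols_to_text(self.symbols)

    @property
    def human(self) -> str:
        return symbols_to_human(self.symbols)

    @classmethod
    def from_text(cls, text: str) -> "SSMotif":
        return cls(parse_symbols(text))

    @property
    def nuc_codes(self) -> np.ndarray:
        return np.array([s.nuc_code for s in self.symbols], dtype=np.uint8)

    @property
    def struct_codes(self) -> np.ndarray:
        return np.array([s.struct_code for s in self.symbols], dtype=np.uint8)

    @property
    def n_defined_chars(self) -> int:
        return sum(s.defined_char_count for s in self.symbols)


@dataclass
class MotifRecord:
    """Catalog entry: a motif plus per-class support, weight and rank."""

    motif: SSMotif
    support_pos: int | None = None
    support_neg: int | None = None
    origin: str = "positive"
    weight: float | None = None
    rank: int | None = None


class MotifCatalog:
    """An ordered collection of motif records, unique by pattern."""

    def __init__(self, records: list[MotifRecord] | None = None):
        self.records: list[MotifRecord] = list(records or [])
        texts = [r.motif.text for r in self.records]
        if len(set(texts)) != len(texts):
            raise ValueError("catalog contains duplicate motifs")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> MotifRecord:
        return self.records[i]

    @property
    def motifs(self) -> list[SSMotif]:
        return [r.motif for r in self.records]

    @property
    def motif_texts(self) -> list[str]:
        return [r.motif.text for r in self.records]

    def sort_lexicographic(self) -> None:
        """Canonical pre-weighting order: lexicographic on the compact text."""
        self.records.sort(key=lambda r: r.motif.text)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "motif": [r.motif.human for r in self.records],
                "length": [len(r.motif) for r in self.records],
                "support_pos": [r.support_pos for r in self.records],
                "support_neg": [r.support_neg for r in self.records],
                "origin": [r.origin for r in self.records],
                "weight": [r.weight for r in self.records],
                "rank": [r.rank for r in self.records],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MotifCatalog":
        df = pd.read_csv(path, sep="\t")
        records = []
        for _, row in df.iterrows():
            records.append(
                MotifRecord(
                    motif=SSMotif.from_text(row["motif"]),
                    support_pos=None if pd.isna(row["support_pos"]) else int(row["support_pos"]),
                    support_neg=None if pd.isna(row["support_neg"]) else int(row["support_neg"]),
                    origin=row["origin"],
                    weight=None if pd.isna(row["weight"]) else float(row["weight"]),
                    rank=None if pd.isna(row["rank"]) else int(row["rank"]),
                )
            )
        return cls(records)


# ---------------------------------------------------------------------------
# validity
# ---------------------------------------------------------------------------


def _char_flags(symbols) -> list[int]:
    """Per-character defined flags: 2 characters per position."""
    flags: list[int] = []
    for s in symbols:
        flags.append(int(s.nuc != "N"))
        flags.append(int(s.struct != "S"))
    return flags


def _density_ok(flags: list[int], L: int, W: int) -> bool:
    n = len(flags)
    if n <= W:
        return sum(flags) >= L
    run = sum(flags[:W])
    if run < L:
        return False
    for i in range(W, n):
        run += flags[i] - flags[i - W]
        if run < L:
            return False
    return True


def is_valid_pattern(motif, L: int = 4, W: int = 12, metric: str = "char") -> bool:
    """Check the terminal-defined and <L,W> density constraints.

    ``metric="char"`` (default) slides windows of ``W`` characters over the
    two-characters-per-position rendering of the pattern.  ``metric=
    "position"`` slides windows of ``W`` whole positions instead, counting
    defined characters within each; it exists for sensitivity analysis.
    """
    symbols = motif.symbols if isinstance(motif, SSMotif) else tuple(motif)
    if not symbols:
        raise ValueError("empty pattern")
    if symbols[0].defined_char_count == 0 or symbols[-1].defined_char_count == 0:
        return False
    if metric == "char":
        return _density_ok(_char_flags(symbols), L, W)
    if metric == "position":
        counts = [s.defined_char_count for s in symbols]
        m = len(counts)
        if m <= W:
            return sum(counts) >= L
        return all(sum(counts[i : i + W]) >= L for i in range(m - W + 1))
    raise ValueError(f"unknown density metric {metric!r}")


def maximal_valid_windows(motif, L: int = 4, W: int = 12, metric: str = "char") -> list[SSMotif]:
    """Decompose a pattern into its maximal contiguous valid sub-windows.

    A raw over-dense pattern that violates the <L,W> constraint still
    contains valid sub-patterns; this returns every contiguous sub-window
    that is valid and not contained in a longer valid sub-window.
    """
    symbols = motif.symbols if isinstance(motif, SSMotif) else tuple(motif)
    m = len(symbols)
    valid_spans = [
        (i, j)
        for i in range(m)
        for j in range(i + 1, m + 1)
        if is_valid_pattern(symbols[i:j], L, W, metric)
    ]
    maximal = [
        (i, j)
        for (i, j) in valid_spans
        if not any((a <= i and j <= b and (a, b) != (i, j)) for (a, b) in valid_spans)
    ]
    return [SSMotif(symbols[i:j]) for i, j in sorted(maximal)]


# ---------------------------------------------------------------------------
# occurrences and support
# ---------------------------------------------------------------------------


def occurrences(motif: SSMotif, ss: SSString) -> list[int]:
    """All start positions of the motif in the ss-string (overlaps included)."""
    m = len(motif)
    n = len(ss)
    if m == 0 or m > n:
        return []
    ok = np.ones(n - m + 1, dtype=bool)
    for j, sym in enumerate(motif.symbols):
        window_nuc = ss.nuc[j : j + n - m + 1]
        window_str = ss.struct[j : j + n - m + 1]
        if sym.nuc != "N":
            ok &= window_nuc == sym.nuc_code
        if sym.struct != "S":
            ok &= window_str == sym.struct_code
    return np.nonzero(ok)[0].tolist()


def support(motif: SSMotif, corpus: list[SSString]) -> int:
    """Number of corpus strings containing >= 1 occurrence."""
    return sum(1 for ss in corpus if occurrences(motif, ss))


# ---------------------------------------------------------------------------
# discovery
# ---------------------------------------------------------------------------

_ALL_SYMBOLS = [
    SSSymbol(n, s)
    for n in NUCLEOTIDES
    for s in STRUCTURES
]
_SEED_SYMBOLS = [s for s in _ALL_SYMBOLS if s.defined_char_count >= 1]


class _FlatCorpus:
    """Concatenated corpus arrays for vectorized occurrence filtering."""

    def __init__(self, corpus: list[SSString]):
        self.n = len(corpus)
        self.lens = np.array([len(s) for s in corpus], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(self.lens)[:-1]]).astype(np.int64)
        total = int(self.lens.sum())
        self.flat_nuc = np.empty(total, dtype=np.uint8)
        self.flat_str = np.empty(total, dtype=np.uint8)
        self.seq_id = np.empty(total, dtype=np.int64)
        for i, ss in enumerate(corpus):
            o = self.offsets[i]
            self.flat_nuc[o : o + len(ss)] = ss.nuc
            self.flat_str[o : o + len(ss)] = ss.struct
            self.seq_id[o : o + len(ss)] = i

    def match_positions(self, sym: SSSymbol, positions: np.ndarray) -> np.ndarray:
        ok = np.ones(len(positions), dtype=bool)
        if sym.nuc != "N":
            ok &= self.flat_nuc[positions] == sym.nuc_code
        if sym.struct != "S":
            ok &= self.flat_str[positions] == sym.struct_code
        return ok


def _subsumes_at(longer: tuple, d: int, shorter: tuple) -> bool:
    """True iff ``longer[d:d+len(shorter)]`` is at least as specific as ``shorter``."""
    for j, ps in enumerate(shorter):
        qs = longer[d + j]
        if ps.nuc != "N" and qs.nuc != ps.nuc:
            return False
        if ps.struct != "S" and qs.struct != ps.struct:
            return False
    return True


def _maximality_filter(emitted: list[tuple[tuple, np.ndarray, np.ndarray]]) -> list[int]:
    """Indices of maximal patterns among (symbols, occ_seq, occ_start) triples.

    Occurrence lists are sorted by (sequence, start).  A pattern is dropped
    iff another pattern with the identical occurrence list (up to a uniform
    start offset) contains a more-specific-or-equal copy of it.  Grouping by
    a shift-normalized occurrence signature makes the check exact and cheap:
    any witness necessarily shares the signature.
    """
    groups: dict = defaultdict(list)
    for idx, (symbols, occ_seq, occ_start) in enumerate(emitted):
        sig = (occ_seq.tobytes(), (occ_start - occ_start[0]).tobytes())
        groups[sig].append(idx)
    keep = []
    for idx, (p_syms, p_seq, p_start) in enumerate(emitted):
        sig = (p_seq.tobytes(), (p_start - p_start[0]).tobytes())
        dominated = False
        for j in groups[sig]:
            if j == idx:
                continue
            q_syms, _, q_start = emitted[j]
            if len(q_syms) < len(p_syms):
                continue
            d = int(p_start[0] - q_start[0])
            if d < 0 or d + len(p_syms) > len(q_syms):
                continue
            if _subsumes_at(q_syms, d, p_syms):
                dominated = True
                break
        if not dominated:
            keep.append(idx)
    return keep


def discover_motifs(
    corpus: list[SSString],
    L: int = 4,
    W: int = 12,
    K: int | None = None,
    max_len: int | None = None,
    metric: str = "char",
    origin: str = "positive",
) -> MotifCatalog:
    """All maximal valid ss-motifs with sequence support >= K.

    The search grows patterns rightward from every seed symbol, propagating
    occurrence lists; branches are pruned as soon as a density window is
    irrecoverably violated or support drops below K.  Maximality is then
    enforced by the occurrence-signature filter.  ``max_len`` optionally caps
    the pattern length (maximality is then relative to the capped pattern
    space).  Equals :func:`brute_force_discover` on small instances.
    """
    if not corpus:
        raise ValueError("corpus must be nonempty")
    if K is None:
        raise ValueError("support threshold K is required")
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    if L > W:
        raise ValueError(f"require L <= W, got L={L}, W={W}")
    if metric not in ("char", "position"):
        raise ValueError(f"unknown density metric {metric!r}")
    if K > len(corpus):
        warnings.warn(
            f"support threshold K={K} exceeds corpus size {len(corpus)}; empty catalog",
            stacklevel=2,
        )
        return MotifCatalog([])

    flat = _FlatCorpus(corpus)
    emitted: list[tuple[tuple, np.ndarray, np.ndarray]] = []

    def window_counts(flags: list[int]) -> bool:
        """Check the (at most two) complete W-windows created by the last append."""
        n = len(flags)
        if metric == "position":
            m = n // 2
            if m >= W:
                if sum(flags[-2 * W :]) < L:
                    return False
            return True
        if n >= W and sum(flags[-W:]) < L:
            return False
        if n - 1 >= W and sum(flags[-W - 1 : -1]) < L:
            return False
        return True

    def emit_ok(symbols: tuple, flags: list[int]) -> bool:
        if symbols[-1].defined_char_count == 0:
            return False
        if metric == "position":
            return is_valid_pattern(symbols, L, W, metric)
        if len(flags) <= W:
            return sum(flags) >= L
        return True  # all complete windows verified during growth

    def grow(symbols: tuple, flags: list[int], occ_g: np.ndarray, occ_seq: np.ndarray):
        t = len(symbols)
        if emit_ok(symbols, flags):
            emitted.append((symbols, occ_seq.copy(), (occ_g - flat.offsets[occ_seq]).copy()))
        if max_len is not None and t >= max_len:
            return
        within = (occ_g - flat.offsets[occ_seq]) + t < flat.lens[occ_seq]
        if not within.any():
            return
        cand_g = occ_g[within]
        cand_seq = occ_seq[within]
        next_pos = cand_g + t
        for sym in _ALL_SYMBOLS:
            new_flags = flags + [int(sym.nuc != "N"), int(sym.struct != "S")]
            if not window_counts(new_flags):
                continue
            ok = flat.match_positions(sym, next_pos)
            if not ok.any():
                continue
            new_seq = cand_seq[ok]
            if len(np.unique(new_seq)) < K:
                continue
            grow(symbols + (sym,), new_flags, cand_g[ok], new_seq)

    all_positions = np.arange(len(flat.flat_nuc), dtype=np.int64)
    for sym in _SEED_SYMBOLS:
        ok = flat.match_positions(sym, all_positions)
        occ_g = all_positions[ok]
        occ_seq = flat.seq_id[occ_g]
        if len(np.unique(occ_seq)) < K:
            continue
        grow((sym,), _char_flags([sym]), occ_g, occ_seq)

    keep = _maximality_filter(emitted)
    records = []
    for idx in keep:
        symbols, occ_seq, _ = emitted[idx]
        supp = int(len(np.unique(occ_seq)))
        assert supp >= K and is_valid_pattern(symbols, L, W, metric)  # soundness
        rec = MotifRecord(motif=SSMotif(symbols), origin=origin)
        if origin == "negative":
            rec.support_neg = supp
        else:
            rec.support_pos = supp
        records.append(rec)
    catalog = MotifCatalog(records)
    catalog.sort_lexicographic()
    return catalog


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_discover(
    corpus: list[SSString],
    L: int = 4,
    W: int = 12,
    K: int = 2,
    max_len: int = 4,
    metric: str = "char",
) -> MotifCatalog:
    """Reference semantics by exhaustive enumeration; tiny instances only.

    Enumerates every pattern up to ``max_len`` over the generalization
    closure of the symbols present in the corpus, filters by validity,
    support and the definitional maximality check.  Guarded against misuse
    on anything but toy inputs.
    """
    if not corpus:
        raise ValueError("corpus must be nonempty")
    if len(corpus) > 8 or max(len(s) for s in corpus) > 20 or max_len > 8:
        raise ValueError("brute-force oracle limited to <=8 strings, length <=20, max_len <=8")
    if K < 1:
        raise ValueError("K must be >= 1")

    concrete = set()
    for ss in corpus:
        for n, s in zip(ss.nuc, ss.struct):
            concrete.add((int(n), int(s)))
    cand = set()
    for n, s in concrete:
        cand.update({(n, s), (NUC_N, s), (n, STR_S), (NUC_N, STR_S)})
    symbols = [SSSymbol(NUCLEOTIDES[n], STRUCTURES[s]) for n, s in sorted(cand)]

    frequent: list[tuple[tuple, list[tuple[int, int]]]] = []
    for m in range(1, max_len + 1):
        # all corpus windows of length m, as (seq, start) plus code arrays
        win_meta = [
            (i, j) for i, ss in enumerate(corpus) for j in range(len(ss) - m + 1)
        ]
        if not win_meta:
            continue
        win_nuc = np.array([corpus[i].nuc[j : j + m] for i, j in win_meta], dtype=np.uint8)
        win_str = np.array([corpus[i].struct[j : j + m] for i, j in win_meta], dtype=np.uint8)
        for pat in itertools.product(symbols, repeat=m):
            if not is_valid_pattern(pat, L, W, metric):
                continue
            pn = np.array([s.nuc_code for s in pat], dtype=np.uint8)
            ps = np.array([s.struct_code for s in pat], dtype=np.uint8)
            hit = (((pn == NUC_N) | (win_nuc == pn)) & ((ps == STR_S) | (win_str == ps))).all(
                axis=1
            )
            occ = [win_meta[w] for w in np.nonzero(hit)[0]]
            if len({seq for seq, _ in occ}) >= K:
                frequent.append((pat, occ))

    records = []
    for p_idx, (p, p_occ) in enumerate(frequent):
        dominated = False
        for q_idx, (q, q_occ) in enumerate(frequent):
            if q_idx == p_idx or len(q) < len(p) or len(q_occ) != len(p_occ):
                continue
            for d in range(len(q) - len(p) + 1):
                if [(s, o + d) for s, o in q_occ] == p_occ and _subsumes_at(q, d, p):
                    dominated = True
                    break
            if dominated:
                break
        if not dominated:
            records.append(
                MotifRecord(motif=SSMotif(p), support_pos=len({s for s, _ in p_occ}))
            )
    catalog = MotifCatalog(records)
    catalog.sort_lexicographic()
    return catalog


def merge_catalogs(pos: MotifCatalog, neg: MotifCatalog) -> MotifCatalog:
    """Union with exact-pattern deduplication; shared motifs get origin ``both``."""
    merged: dict[str, MotifRecord] = {}
    for rec in pos:
        merged[rec.motif.text] = MotifRecord(
            motif=rec.motif,
            support_pos=rec.support_pos,
            support_neg=rec.support_neg,
            origin=rec.origin,
        )
    for rec in neg:
        if rec.motif.text in merged:
            prev = merged[rec.motif.text]
            prev.origin = "both"
            if prev.support_neg is None:
                prev.support_neg = rec.support_neg
            if prev.support_pos is None:
                prev.support_pos = rec.support_pos
        else:
            merged[rec.motif.text] = MotifRecord(
                motif=rec.motif,
                support_pos=rec.support_pos,
                support_neg=rec.support_neg,
                origin=rec.origin,
            )
    catalog = MotifCatalog(list(merged.values()))
    catalog.sort_lexicographic()
    return catalog
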