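"""Synthetic single-loop hairpin corpora with plantable ss-motifs.

The generator emulates the labelled-corpus design used for precursor
classification: two equally sized classes of single-loop stem-loops drawn
from the same structural background, differing only in which ss-motifs are
planted into them.  Stems pair Watson-Crick with an optional G-U wobble;
bulges and the terminal loop are unpaired.  Every record passes the hairpin
validators, and a manifest records each planting so that ground truth is
recoverable by the occurrence scanner.

Defaults mirror a 608 + 608 corpus of 55-115 nt hairpins.  Tests and the
acceptance study run explicit scaled-down configs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .alphabet import SSSymbol
from .discovery import SSMotif, is_valid_pattern, occurrences
from .hairpins import Hairpin, MatureAnnotation, is_single_loop, pair_map

__all__ = [
    "GeneratorConfig",
    "SynthCorpus",
    "random_hairpin",
    "random_motif",
    "plant_motif",
    "make_corpus",
]

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
_WOBBLE = {"G": "U", "U": "G"}
_BASES = "ACGU"


@dataclass
class GeneratorConfig:
    """Knobs of the corpus generator.

    Probabilities are per-site (``bulge_prob``, ``wobble_prob``) or
    per-sequence (``planting_prob``).  ``positive_motifs`` /
    ``negative_motifs`` take motif texts; when None, ``n_class_motifs``
    random plantable motifs are generated per class from the seed.
    ``family_blocks`` lists sizes of positive-class families, each sharing
    one extra family-private motif.
    """

    n_positive: int = 608
    n_negative: int = 608
    length_range: tuple[int, int] = (55, 115)
    stem_range: tuple[int, int] = (25, 45)
    loop_range: tuple[int, int] = (4, 12)
    bulge_prob: float = 0.05
    wobble_prob: float = 0.1
    n_class_motifs: int = 5
    motif_length_range: tuple[int, int] = (5, 7)
    motif_struct_prob: float = 0.5
    planting_prob: float = 0.8
    positive_motifs: tuple[str, ...] | None = None
    negative_motifs: tuple[str, ...] | None = None
    family_blocks: tuple[int, ...] = ()
    family_mutation_rate: float = 0.1
    mature_offset: int = 5
    seed: int = 0

    def __post_init__(self):
        for name in (
            "bulge_prob",
            "wobble_prob",
            "planting_prob",
            "motif_struct_prob",
            "family_mutation_rate",
        ):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("length_range", "stem_range", "loop_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name} must be a nonempty positive range, got ({lo}, {hi})")
        lo, hi = self.length_range
        if 2 * self.stem_range[0] + self.loop_range[0] > hi:
            raise ValueError("stem/loop ranges cannot produce a hairpin within length_range")


def random_hairpin(config: GeneratorConfig, rng: np.random.Generator, id: str = "hp") -> Hairpin:
    """One single-loop stem-loop with complementary-paired stem.

    Bulges (unpaired sites within an arm) are inserted per stem position
    with ``bulge_prob``; pairs are Watson-Crick, or G-U/U-G wobble with
    ``wobble_prob``.  Resampled until the total length falls inside
    ``length_range`` (the config validator guarantees feasibility).
    """
    lo, hi = config.length_range
    for _ in range(1000):
        stem = int(rng.integers(config.stem_range[0], config.stem_range[1] + 1))
        loop = int(rng.integers(config.loop_range[0], config.loop_range[1] + 1))
        left: list[str] = []
        right: list[str] = []
        for _ in range(stem):
            if rng.random() < config.bulge_prob:
                left.append(".")
            left.append("(")
            if rng.random() < config.bulge_prob:
                right.append(".")
            right.append(")")
        structure = "".join(left) + "." * loop + "".join(reversed(right))
        if not lo <= len(structure) <= hi:
            continue
        pairs = pair_map(structure)
        seq = [""] * len(structure)
        for i, c in enumerate(structure):
            if c == ".":
                seq[i] = _BASES[rng.integers(4)]
            elif c == "(":
                b = _BASES[rng.integers(4)]
                seq[i] = b
                if b in _WOBBLE and rng.random() < config.wobble_prob:
                    seq[pairs[i]] = _WOBBLE[b]
                else:
                    seq[pairs[i]] = _COMPLEMENT[b]
        hp = Hairpin(id=id, sequence="".join(seq), structure=structure)
        assert is_single_loop(hp.structure)
        return hp
    raise ValueError("could not generate a hairpin within length_range; ranges infeasible")


def random_motif(
    rng: np.random.Generator,
    length_range: tuple[int, int] = (5, 7),
    struct_defined_prob: float = 0.5,
) -> SSMotif:
    """A random plantable motif: defined nucleotides, optional 'L' notations.

    Every position defines its nucleotide (making chance occurrences rare);
    structure notations, where defined, are always ``L`` so that a window
    compatible with the motif exists in any hairpin whose 5' arm has an
    uninterrupted run of pairs at least as long as the motif.
    """
    m = int(rng.integers(length_range[0], length_range[1] + 1))
    symbols = tuple(
        SSSymbol(_BASES[rng.integers(4)], "L" if rng.random() < struct_defined_prob else "S")
        for _ in range(m)
    )
    motif = SSMotif(symbols)
    assert is_valid_pattern(motif)
    return motif


def plant_motif(
    hairpin: Hairpin,
    motif: SSMotif,
    rng: np.random.Generator,
    blocked: tuple[tuple[int, int], ...] = (),
) -> tuple[Hairpin, int]:
    """Overwrite sequence letters at a random structure-compatible window.

    A window is compatible when the hairpin's structural states equal the
    motif's defined structure notations position-wise.  The structure is
    never modified; where the motif defines a nucleotide the window's base
    is overwritten (the partner base of a paired site is left as is).
    ``blocked`` half-open intervals are avoided so that successive plantings
    into the same record cannot clobber one another.  Returns the planted
    hairpin and the window start.
    """
    ss = hairpin.encode()
    m = len(motif)
    struct_codes = motif.struct_codes
    defined = np.array([s.struct != "S" for s in motif.symbols])
    candidates = []
    for start in range(len(ss) - m + 1):
        if any(start < b_end and b_start < start + m for b_start, b_end in blocked):
            continue
        window = ss.struct[start : start + m]
        if np.all(window[defined] == struct_codes[defined]):
            candidates.append(start)
    if not candidates:
        raise ValueError(f"no window of {hairpin.id} is compatible with motif {motif.human}")
    start = int(candidates[rng.integers(len(candidates))])
    seq = list(hairpin.sequence)
    for j, sym in enumerate(motif.symbols):
        if sym.nuc != "N":
            seq[start + j] = sym.nuc
    planted = hairpin.replace(sequence="".join(seq))
    assert occurrences(motif, planted.encode())
    return planted, start


@dataclass
class SynthCorpus:
    positives: list[Hairpin]
    negatives: list[Hairpin]
    manifest: dict

    @property
    def all_hairpins(self) -> list[Hairpin]:
        return self.positives + self.negatives


def _attach_mature(hp: Hairpin, config: GeneratorConfig) -> Hairpin:
    start = min(config.mature_offset, len(hp.sequence) // 4)
    end = len(hp.sequence) - start - 1
    return hp.replace(mature=MatureAnnotation(mir_start=start, mir_end=end))


def make_corpus(config: GeneratorConfig) -> SynthCorpus:
    """A labelled corpus plus ground-truth manifest, reproducible by seed.

    Positives and negatives come from the same background generator and
    differ only in planted class motifs (and family-private motifs for
    positive family blocks).  The manifest records every planting as
    (hairpin id, motif text, window start) and all family memberships.
    """
    rng = np.random.default_rng(config.seed)

    def _motif():
        return random_motif(rng, config.motif_length_range, config.motif_struct_prob)

    if config.positive_motifs is not None:
        pos_motifs = [SSMotif.from_text(t) for t in config.positive_motifs]
    else:
        pos_motifs = [_motif() for _ in range(config.n_class_motifs)]
    if config.negative_motifs is not None:
        neg_motifs = [SSMotif.from_text(t) for t in config.negative_motifs]
    else:
        neg_motifs = [_motif() for _ in range(config.n_class_motifs)]
    family_motifs = [_motif() for _ in config.family_blocks]

    if sum(config.family_blocks) > config.n_positive:
        raise ValueError("family blocks exceed the number of positives")
    # Leading positives form family blocks.  A family descends from one
    # ancestral hairpin carrying the family-private motif: members share
    # the ancestor's structure and differ by point mutations outside the
    # family-motif window (the way precursor families share most of their
    # hairpin while the mature arm is near-invariant).
    family_of: dict[int, int] = {}
    cursor = 0
    for b, size in enumerate(config.family_blocks):
        for i in range(cursor, cursor + size):
            family_of[i] = b
        cursor += size

    ancestors: dict[int, tuple[Hairpin, tuple[int, int]]] = {}
    for b, fam_motif in enumerate(family_motifs):
        anc = random_hairpin(config, rng, id=f"anc_{b}")
        anc, start = plant_motif(anc, fam_motif, rng)
        ancestors[b] = (anc, (start, start + len(fam_motif)))

    plantings: list[dict] = []
    families: dict[str, list[str]] = {}

    def build_class(n: int, label: str, motifs: list[SSMotif]) -> list[Hairpin]:
        out = []
        for i in range(n):
            hp_id = f"{label[:3]}_{i:04d}"
            blocked: list[tuple[int, int]] = []
            if label == "positive" and i in family_of:
                b = family_of[i]
                anc, fam_window = ancestors[b]
                seq = list(anc.sequence)
                for j in range(len(seq)):
                    if fam_window[0] <= j < fam_window[1]:
                        continue
                    if rng.random() < config.family_mutation_rate:
                        seq[j] = _BASES[rng.integers(4)]
                hp = Hairpin(id=hp_id, sequence="".join(seq), structure=anc.structure, label=label)
                blocked.append(fam_window)
                families.setdefault(f"family_{b}", []).append(hp_id)
                plantings.append(
                    {"id": hp_id, "motif": family_motifs[b].human, "start": fam_window[0]}
                )
            else:
                hp = random_hairpin(config, rng, id=hp_id).replace(label=label)
            # class motifs are planted in random per-record order so that no
            # motif is systematically starved of windows
            for j in rng.permutation(len(motifs)):
                motif = motifs[j]
                if rng.random() < config.planting_prob:
                    try:
                        hp, start = plant_motif(hp, motif, rng, tuple(blocked))
                    except ValueError:
                        continue  # no compatible window left in this record
                    blocked.append((start, start + len(motif)))
                    plantings.append({"id": hp.id, "motif": motif.human, "start": start})
            out.append(_attach_mature(hp, config))
        return out

    positives = build_class(config.n_positive, "positive", pos_motifs)
    negatives = build_class(config.n_negative, "negative", neg_motifs)

    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "positive_motifs": [m.human for m in pos_motifs],
        "negative_motifs": [m.human for m in neg_motifs],
        "family_motifs": {f"family_{b}": m.human for b, m in enumerate(family_motifs)},
        "families": families,
        "plantings": plantings,
    }
    return SynthCorpus(positives=positives, negatives=negatives, manifest=manifest)


def write_corpus(corpus: SynthCorpus, outdir) -> None:
    """FASTA + structure file + labels TSV + annotations TSV + JSON manifest."""
    from . import io as ssio

    outdir.mkdir(parents=True, exist_ok=True)
    records = corpus.all_hairpins
    ssio.write_vienna(outdir / "hairpins.vienna", records)
    ssio.write_fasta(outdir / "hairpins.fasta", records)
    ssio.write_labels(outdir / "labels.tsv", records)
    ssio.write_annotations(outdir / "annotations.tsv", records)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(corpus.manifest, fh, indent=1, sort_keys=True)
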