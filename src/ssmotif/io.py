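"""Readers and writers for hairpin corpora.

Supported on-disk forms:

* plain FASTA (sequences only; Bio.SeqIO underneath),
* the RNAfold-style combined file: ``>id`` line, sequence line, structure
  line, with an optional trailing free energy in brackets that is ignored,
* labels TSV (``id<TAB>label``),
* mature-annotation TSV (``id<TAB>mir_start<TAB>mir_end``, 1-based inclusive
  on disk, 0-based internally).
"""

from __future__ import annotations

import re
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .hairpins import Hairpin, MatureAnnotation, normalize_rna

_ENERGY_RE = re.compile(r"\s*\(\s*-?\d+(\.\d+)?\s*\)\s*$")


def read_fasta(path) -> dict[str, str]:
    """FASTA sequences keyed by record id, RNA-normalized."""
    return {rec.id: normalize_rna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, hairpins: list[Hairpin]) -> None:
    records = [SeqRecord(Seq(hp.sequence), id=hp.id, description="") for hp in hairpins]
    SeqIO.write(records, str(path), "fasta")


def read_structures(path) -> dict[str, str]:
    """Structure-only FASTA-like file: ``>id`` then dot-bracket line(s)."""
    out: dict[str, str] = {}
    current = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            current = line[1:].split()[0]
            out[current] = ""
        elif current is not None:
            out[current] += _ENERGY_RE.sub("", line)
    return out


def read_vienna(path) -> list[Hairpin]:
    """RNAfold-style combined file: ``>id`` / sequence / structure triples.

    A trailing minimum-free-energy annotation in brackets after the
    structure (e.g. ``(((...))) (-12.30)``) is tolerated and dropped.
    """
    lines = [ln.rstrip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    hairpins = []
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"{path}: expected '>' header at line {i + 1}, got {lines[i]!r}")
        if i + 2 >= len(lines):
            raise ValueError(f"{path}: truncated record for header {lines[i]!r}")
        hp_id = lines[i][1:].split()[0]
        sequence = lines[i + 1].strip()
        structure = _ENERGY_RE.sub("", lines[i + 2]).strip()
        hairpins.append(Hairpin(id=hp_id, sequence=sequence, structure=structure))
        i += 3
    return hairpins


def write_vienna(path, hairpins: list[Hairpin]) -> None:
    with open(path, "w") as fh:
        for hp in hairpins:
            fh.write(f">{hp.id}\n{hp.sequence}\n{hp.structure}\n")


def read_labels(path) -> dict[str, str]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        hp_id, label = line.split("\t")[:2]
        out[hp_id] = label.strip()
    return out


def write_labels(path, hairpins: list[Hairpin]) -> None:
    with open(path, "w") as fh:
        for hp in hairpins:
            fh.write(f"{hp.id}\t{hp.label}\n")


def read_annotations(path) -> dict[str, MatureAnnotation]:
    """Mature-arm coordinates, converted from 1-based inclusive to 0-based."""
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("id\t"):
            continue
        hp_id, start, end = line.split("\t")[:3]
        out[hp_id] = MatureAnnotation(mir_start=int(start) - 1, mir_end=int(end) - 1)
    return out


def write_annotations(path, hairpins: list[Hairpin]) -> None:
    with open(path, "w") as fh:
        fh.write("id\tmir_start\tmir_end\n")
        for hp in hairpins:
            if hp.mature is not None:
                fh.write(f"{hp.id}\t{hp.mature.mir_start + 1}\t{hp.mature.mir_end + 1}\n")


def load_hairpins(
    vienna=None,
    fasta=None,
    structures=None,
    labels=None,
    annotations=None,
) -> list[Hairpin]:
    """Assemble hairpin records from any supported file combination."""
    if vienna is not None:
        hairpins = read_vienna(vienna)
    elif fasta is not None and structures is not None:
        seqs = read_fasta(fasta)
        structs = read_structures(structures)
        missing = sorted(set(seqs) - set(structs))
        if missing:
            raise ValueError(f"no structure for record(s): {', '.join(missing[:5])}")
        hairpins = [Hairpin(id=k, sequence=seqs[k], structure=structs[k]) for k in seqs]
    else:
        raise ValueError("supply either a combined vienna file or fasta + structures")
    if labels is not None:
        label_map = read_labels(labels)
        hairpins = [hp.replace(label=label_map.get(hp.id, hp.label)) for hp in hairpins]
    if annotations is not None:
        ann = read_annotations(annotations)
        hairpins = [hp.replace(mature=ann.get(hp.id)) for hp in hairpins]
    return hairpins


def fold_with_rnafold(sequences: dict[str, str], rnafold_bin: str = "RNAfold") -> dict[str, str]:
    """Optional shell-out to an external folding tool (never computed here).

    Requires the ``RNAfold`` executable on PATH; returns dot-bracket
    structures keyed by id.
    """
    import subprocess

    payload = "".join(f">{k}\n{v}\n" for k, v in sequences.items())
    proc = subprocess.run(
        [rnafold_bin, "--noPS"], input=payload, capture_output=True, text=True, check=True
    )
    out: dict[str, str] = {}
    current = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            current = line[1:].split()[0]
        elif current is not None and set(line.split()[0]) <= set("(.)"):
            out[current] = line.split()[0]
            current = None
    return out
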