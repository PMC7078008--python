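"""Readers and writers for the external formats the toolkit touches.

FASTA (multi-chain records use '/' inside the sequence line), aligned
secondary-structure strings, classic DSSP output (collapsed to the 3-class
H/E/C alphabet), TSV contact tables, MIDI scores, C-alpha coordinates from
PDB or plain xyz TSV, and YAML/JSON configuration.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from ._smf import read_midi, write_midi  # re-exported  # noqa: F401
from .types import (
    AA_ALPHABET,
    CaCoordinates,
    Chain,
    ContactTable,
    SequenceRecord,
    ValidationError,
)

#: DSSP 8-class -> 3-class collapse: helical {H, G, I} -> H, extended
#: {E, B} -> E, everything else (T, S, P, blank) -> C.
DSSP_COLLAPSE = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


def read_fasta(path) -> list[SequenceRecord]:
    """Read FASTA into records; '/' inside a sequence separates chains.

    Secondary structure is left unset; attach it with :func:`read_ss` or
    :func:`parse_dssp`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"{path}: empty FASTA file")
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        chains = []
        for part in seq.split("/"):
            for pos, aa in enumerate(part):
                if aa not in AA_ALPHABET:
                    raise ValidationError(
                        f"{path}: record {rec.id!r}: non-standard amino acid "
                        f"{aa!r} at chain position {pos + 1}"
                    )
            chains.append(Chain(part))
        if not any(len(c) for c in chains):
            raise ValidationError(f"{path}: record {rec.id!r} has an empty sequence")
        out.append(SequenceRecord(rec.id, [c for c in chains if len(c)]))
    return out


def write_fasta(records: list[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.record_id}\n")
            fh.write("/".join(c.sequence for c in rec.chains) + "\n")


def read_ss(path) -> list[str]:
    """Read an aligned secondary-structure file: one '/'-separated line per
    record, same layout as the FASTA sequence lines."""
    lines = [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith(">")
    ]
    for ln in lines:
        for ch in ln:
            if ch not in "HEC/":
                raise ValidationError(f"{path}: bad secondary-structure symbol {ch!r}")
    return lines


def attach_ss(records: list[SequenceRecord], ss_lines: list[str]) -> list[SequenceRecord]:
    """Pair FASTA records with aligned secondary-structure lines in order."""
    if len(records) != len(ss_lines):
        raise ValidationError(
            f"{len(records)} records but {len(ss_lines)} secondary-structure lines"
        )
    out = []
    for rec, line in zip(records, ss_lines):
        parts = line.split("/")
        if len(parts) != len(rec.chains):
            raise ValidationError(
                f"record {rec.record_id!r}: {len(rec.chains)} chains but "
                f"{len(parts)} secondary-structure segments"
            )
        out.append(
            SequenceRecord(
                rec.record_id,
                [Chain(c.sequence, ss) for c, ss in zip(rec.chains, parts)],
            )
        )
    return out


def parse_dssp(path) -> str:
    """Collapse a classic DSSP output file to a 3-class string.

    Returns one H/E/C character per residue line; chain breaks (the '!'
    rows DSSP emits between chains) become '/' boundaries, matching the
    multi-chain FASTA convention.
    """
    lines = Path(path).read_text().splitlines()
    start = None
    for idx, line in enumerate(lines):
        if line.lstrip().startswith("#") and "RESIDUE" in line and "AA" in line:
            start = idx + 1
            break
    if start is None:
        raise ValidationError(f"{path}: no '#  RESIDUE AA' header found")
    out: list[str] = []
    for lineno, line in enumerate(lines[start:], start + 1):
        if not line.strip():
            continue
        if len(line) < 14:
            raise ValidationError(f"{path}:{lineno}: residue line too short")
        aa = line[13]
        if aa == "!":  # chain break marker (break rows carry no ss column)
            if out and out[-1] != "/":
                out.append("/")
            continue
        if len(line) < 17:
            raise ValidationError(f"{path}:{lineno}: residue line too short")
        code = line[16]
        out.append(DSSP_COLLAPSE.get(code, "C"))
    if out and out[-1] == "/":
        out.pop()
    if not out:
        raise ValidationError(f"{path}: no residue lines parsed")
    return "".join(out)


def read_contacts(path) -> ContactTable:
    """Read a two-column TSV of 1-based residue index pairs."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValidationError(f"{path}: cannot parse contact table: {exc}") from exc
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: contact table needs two columns")
    pairs = []
    for row in df.itertuples(index=False):
        i, j = row[0], row[1]
        if not (float(i).is_integer() and float(j).is_integer()):
            raise ValidationError(f"{path}: non-integer contact indices ({i}, {j})")
        pairs.append((int(i), int(j)))
    return ContactTable(pairs)


def write_contacts(table: ContactTable, path) -> None:
    with open(path, "w") as fh:
        for i, j in table.pairs:
            fh.write(f"{i}\t{j}\n")


def read_ca_coords(path) -> CaCoordinates:
    """C-alpha coordinates from a PDB file (ATOM records, all chains in file
    order) or from a plain TSV/xyz table of x, y, z columns."""
    path = Path(path)
    if path.suffix.lower() in (".pdb", ".ent"):
        from Bio.PDB import PDBParser

        structure = PDBParser(QUIET=True).get_structure("s", str(path))
        model = next(structure.get_models())
        coords = [
            atom.coord
            for chain in model
            for residue in chain
            if "CA" in residue
            for atom in [residue["CA"]]
        ]
        if len(coords) < 2:
            raise ValidationError(f"{path}: fewer than 2 C-alpha atoms found")
        return CaCoordinates(np.array(coords, dtype=float))
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValidationError(f"{path}: coordinate table needs three columns")
    return CaCoordinates(df.iloc[:, :3].to_numpy(dtype=float))


def load_config(path) -> dict:
    """Load a YAML (or JSON) configuration mapping."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: configuration must be a mapping")
    return data
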