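"""Readers and writers for the plain-text formats the pipeline consumes.

* FASTA primary sequences (via Biopython).
* PSI-BLAST ASCII PSSMs (the ``-out_ascii_pssm`` dialect: per-residue rows of
  20 log-odds columns followed by 20 weighted observed percentage columns).
* Bond tables: TSV of (protein_id, pos_a, pos_b) with 1-based residue
  positions of the two bonded cysteines.
* Annotation tracks: TSV with a header of label names, one row per residue.
* Bonding probability matrices: whitespace-delimited square matrix with a
  one-line ``protein_id n`` header.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Union

import numpy as np
from Bio import SeqIO

from .core import (
    TRACK_LABELS,
    AnnotationTrack,
    BondingProbabilityMatrix,
    DisulfidePattern,
    Protein,
    ValidityError,
)

PathLike = Union[str, Path]


class ParseError(ValueError):
    pass


def read_fasta(path: PathLike) -> List[Protein]:
    """Read a FASTA file into :class:`Protein` objects (AA track attached)."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: empty FASTA file")
    with open(path) as handle:
        first = handle.readline()
        if not first.startswith(">"):
            raise ParseError(f"{path}:1: expected FASTA header, got {first!r}")
    proteins = []
    for record in SeqIO.parse(str(path), "fasta"):
        if not record.id:
            raise ParseError(f"{path}: record with empty header")
        proteins.append(Protein(id=record.id, sequence=str(record.seq)))
    return proteins


def write_fasta(proteins: List[Protein], path: PathLike) -> None:
    with open(path, "w") as out:
        for p in proteins:
            out.write(f">{p.id}\n{p.sequence}\n")


def read_psiblast_pssm(
    path: PathLike, protein: Protein, transform: str = "percent"
) -> AnnotationTrack:
    """Parse a PSI-BLAST ASCII PSSM aligned to ``protein``.

    transform:
        "percent"  -- weighted observed percentages / 100 (default; rows lie
                      in [0, 1] but are not forced to sum to 1).
        "logistic" -- 1 / (1 + exp(-score)) applied to the log-odds columns.
    """
    if transform not in ("percent", "logistic"):
        raise ValueError(f"unknown PSSM transform {transform!r}")
    path = Path(path)
    labels = list(TRACK_LABELS["PSSM"])
    rows: List[np.ndarray] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            tokens = line.split()
            # residue rows start with a position number then the residue letter
            if len(tokens) >= 42 and tokens[0].isdigit() and len(tokens[1]) == 1:
                try:
                    numbers = [float(t) for t in tokens[2:42]]
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: unparseable PSSM row")
                log_odds = np.array(numbers[:20])
                percents = np.array(numbers[20:40])
                if transform == "percent":
                    rows.append(percents / 100.0)
                else:
                    rows.append(1.0 / (1.0 + np.exp(-log_odds)))
            elif len(tokens) == 40 and all(len(t) == 1 and t.isalpha() for t in tokens):
                labels = tokens[:20]  # header names the column order
    if len(rows) != protein.length:
        raise ParseError(
            f"{path}: {len(rows)} PSSM rows for length-{protein.length}"
            f" protein {protein.id!r}"
        )
    return AnnotationTrack(
        "PSSM", labels, np.vstack(rows), probabilistic=(transform == "percent")
    )


def read_track_tsv(path: PathLike, name: str, protein: Protein) -> AnnotationTrack:
    """Read a per-residue label-probability track (header = label names)."""
    path = Path(path)
    with open(path) as handle:
        header = handle.readline().split()
        if not header:
            raise ParseError(f"{path}:1: missing track header")
        rows = []
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            values = line.split()
            if len(values) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} values,"
                    f" got {len(values)}"
                )
            try:
                rows.append([float(v) for v in values])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric value")
    if len(rows) != protein.length:
        raise ParseError(
            f"{path}: {len(rows)} rows for length-{protein.length}"
            f" protein {protein.id!r}"
        )
    return AnnotationTrack(name, header, np.array(rows), probabilistic=True)


def write_track_tsv(track: AnnotationTrack, path: PathLike) -> None:
    with open(path, "w") as out:
        out.write("\t".join(track.labels) + "\n")
        for row in track.values:
            out.write("\t".join(f"{v:.6g}" for v in row) + "\n")


def read_bond_table(
    path: PathLike, proteins: List[Protein]
) -> Dict[str, DisulfidePattern]:
    """Read a TSV bond table and map residue positions to cysteine indices.

    Every listed protein gets an entry (empty pattern when it has no rows).
    Positions in the file are 1-based residue coordinates.
    """
    by_id = {p.id: p for p in proteins}
    bonds: Dict[str, list] = {pid: [] for pid in by_id}
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 'protein_id pos_a pos_b'"
                )
            pid, pos_a, pos_b = fields[0], int(fields[1]), int(fields[2])
            if pid not in by_id:
                raise ParseError(f"{path}:{lineno}: unknown protein {pid!r}")
            protein = by_id[pid]
            cys_pos = protein.cysteine_positions
            indices = []
            for pos in (pos_a, pos_b):
                residue_index = pos - 1
                if residue_index not in cys_pos:
                    raise ParseError(
                        f"{path}:{lineno}: position {pos} of {pid!r} is not"
                        " a cysteine"
                    )
                indices.append(cys_pos.index(residue_index))
            bonds[pid].append(tuple(indices))
    patterns = {}
    for pid, pair_list in bonds.items():
        try:
            patterns[pid] = DisulfidePattern(pair_list)
        except ValidityError as exc:
            raise ValidityError(f"{path}: protein {pid!r}: {exc}") from exc
    return patterns


def write_bond_table(
    patterns: Dict[str, DisulfidePattern],
    proteins: List[Protein],
    path: PathLike,
) -> None:
    """Write patterns as a 1-based residue-position bond table."""
    by_id = {p.id: p for p in proteins}
    with open(path, "w") as out:
        for pid in sorted(patterns):
            cys_pos = by_id[pid].cysteine_positions
            for a, b in patterns[pid].sorted_bonds():
                out.write(f"{pid}\t{cys_pos[a] + 1}\t{cys_pos[b] + 1}\n")


def read_probability_matrix(path: PathLike) -> tuple:
    """Read a ``protein_id n`` header plus a square probability matrix."""
    path = Path(path)
    with open(path) as handle:
        header = handle.readline().split()
        if len(header) != 2:
            raise ParseError(f"{path}:1: expected 'protein_id n' header")
        pid, n = header[0], int(header[1])
        matrix = np.loadtxt(handle, ndmin=2)
    if matrix.shape != (n, n):
        raise ParseError(f"{path}: expected a {n}x{n} matrix, got {matrix.shape}")
    return pid, BondingProbabilityMatrix(matrix)


def write_probability_matrix(
    pid: str, matrix: BondingProbabilityMatrix, path: PathLike
) -> None:
    with open(path, "w") as out:
        out.write(f"{pid} {matrix.n}\n")
        for row in matrix.probs:
            out.write(" ".join(f"{v:.6f}" for v in row) + "\n")
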