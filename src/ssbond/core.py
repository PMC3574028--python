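"""Domain types for disulfide connectivity prediction.

A protein is represented by its primary sequence plus per-residue annotation
tracks (PSSM, predicted secondary structure, ...).  Cysteines are addressed by
their *cysteine index* -- the rank of the residue among the protein's cysteines
in sequence order -- and a disulfide connectivity pattern is a set of unordered
cysteine-index pairs in which no cysteine appears twice.

Residue positions are 0-based internally; file formats and user-facing
messages use the 1-based bioinformatics convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

#: Label sets of the built-in annotation tracks.
TRACK_LABELS: Dict[str, List[str]] = {
    "AA": list(AMINO_ACIDS) + [GAP],          # twenty amino acids and the gap
    "PSSM": list("ARNDCQEGHILKMFPSTWYV"),     # PSI-BLAST column order
    "SS3": ["H", "E", "C"],
    "SS8": ["H", "G", "I", "E", "B", "T", "S", "C"],
    "SA": ["buried", "exposed"],
    "DR": ["ordered", "disordered"],
    "StAl": [f"s{i}" for i in range(27)],
}

Bond = Tuple[int, int]


class ValidityError(ValueError):
    """A disulfide pattern violates the at-most-one-partner constraint."""


@dataclass
class AnnotationTrack:
    """Per-residue label-value matrix over a fixed label set.

    For probabilistic tracks every entry lies in [0, 1] and (for predicted
    tracks) each row sums to one.  The PSSM track is non-probabilistic until
    transformed by the reader (see :func:`ssbond.io.read_psiblast_pssm`).
    """

    name: str
    labels: List[str]
    values: np.ndarray  # (L, |labels|)
    probabilistic: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.labels):
            raise ValueError(
                f"track {self.name!r}: values must be (L, {len(self.labels)}),"
                f" got {self.values.shape}"
            )
        if self.probabilistic:
            if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
                raise ValueError(
                    f"track {self.name!r}: probabilistic entries must be in [0,1]"
                )

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class Protein:
    """A primary sequence with its ordered cysteines and annotation tracks."""

    id: str
    sequence: str
    tracks: Dict[str, AnnotationTrack] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        for i, pos in enumerate(self.cysteine_positions):
            if not 0 <= pos < self.length or self.sequence[pos] != "C":
                raise ValueError(f"{self.id}: bad cysteine position {pos + 1}")
        for name, track in self.tracks.items():
            if len(track) != self.length:
                raise ValueError(
                    f"{self.id}: track {name!r} has {len(track)} rows for a"
                    f" length-{self.length} protein"
                )
        if "AA" not in self.tracks:
            self.tracks["AA"] = aa_one_hot_track(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def cysteine_positions(self) -> List[int]:
        # strictly increasing by construction: sequence scan order
        return [i for i, r in enumerate(self.sequence) if r == "C"]

    @property
    def n_cys(self) -> int:
        return len(self.cysteine_positions)

    def attach(self, track: AnnotationTrack) -> "Protein":
        if len(track) != self.length:
            raise ValueError(
                f"{self.id}: track {track.name!r} has {len(track)} rows,"
                f" expected {self.length}"
            )
        self.tracks[track.name] = track
        return self

    def track(self, name: str) -> AnnotationTrack:
        try:
            return self.tracks[name]
        except KeyError:
            raise KeyError(
                f"{self.id}: annotation track {name!r} is not attached"
            ) from None


def aa_one_hot_track(sequence: str) -> AnnotationTrack:
    """One-hot AA track; unknown residues ('X', 'U', ...) map to the gap label."""
    labels = TRACK_LABELS["AA"]
    index = {a: i for i, a in enumerate(labels)}
    values = np.zeros((len(sequence), len(labels)))
    for row, residue in enumerate(sequence.upper()):
        values[row, index.get(residue, index[GAP])] = 1.0
    return AnnotationTrack("AA", labels, values, probabilistic=True)


def is_valid_pattern(bonds: Iterable[Bond], n_cys: int) -> bool:
    """True iff ``bonds`` is a valid connectivity pattern on ``n_cys`` cysteines.

    Valid means: all indices in range, no self-pair, and each cysteine bonded
    to at most one other cysteine.  Total function -- never raises.
    """
    seen: set = set()
    for a, b in bonds:
        if a == b or not (0 <= a < n_cys) or not (0 <= b < n_cys):
            return False
        if a in seen or b in seen:
            return False
        seen.add(a)
        seen.add(b)
    return True


@dataclass(frozen=True)
class DisulfidePattern:
    """A set of unordered cysteine-index pairs, each index used at most once."""

    bonds: FrozenSet[Bond]

    def __init__(self, bonds: Iterable[Bond] = ()):
        normalized = frozenset(
            (min(a, b), max(a, b)) for a, b in bonds
        )
        seen: set = set()
        for a, b in sorted(normalized):
            if a == b:
                raise ValidityError(f"self-bond ({a + 1}, {b + 1})")
            if a in seen or b in seen:
                raise ValidityError(
                    "a given cysteine can be bonded to at most one other"
                    f" cysteine; index {a if a in seen else b} repeats"
                )
            seen.update((a, b))
        object.__setattr__(self, "bonds", normalized)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def bonded_indices(self) -> FrozenSet[int]:
        return frozenset(i for bond in self.bonds for i in bond)

    def sorted_bonds(self) -> List[Bond]:
        return sorted(self.bonds)

    def is_valid_for(self, n_cys: int) -> bool:
        return is_valid_pattern(self.bonds, n_cys)

    def __iter__(self):
        return iter(self.sorted_bonds())

    def __len__(self) -> int:
        return len(self.bonds)


EMPTY_PATTERN = DisulfidePattern()


@dataclass
class BondingProbabilityMatrix:
    """Symmetric matrix of pairwise bonding probabilities for one protein.

    The diagonal is ignored by all consumers.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != self.probs.shape[1]:
            raise ValueError("probability matrix must be square")
        if self.probs.size and (self.probs.min() < -1e-9 or self.probs.max() > 1 + 1e-9):
            raise ValueError("bonding probabilities must lie in [0, 1]")
        if not np.allclose(self.probs, self.probs.T, atol=1e-9):
            raise ValueError("bonding probability matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.probs.shape[0]

    def __getitem__(self, pair: Bond) -> float:
        a, b = pair
        return float(self.probs[a, b])


@dataclass
class LabeledDataset:
    """Proteins with ground-truth patterns and optional train/test splits."""

    proteins: List[Protein]
    patterns: Dict[str, DisulfidePattern]
    splits: Optional[List[Tuple[List[str], List[str]]]] = None

    def __post_init__(self) -> None:
        by_id = {p.id: p for p in self.proteins}
        if len(by_id) != len(self.proteins):
            raise ValueError("duplicate protein ids in dataset")
        for pid, pattern in self.patterns.items():
            if pid not in by_id:
                raise ValueError(f"pattern for unknown protein {pid!r}")
            if not pattern.is_valid_for(by_id[pid].n_cys):
                raise ValidityError(f"invalid pattern for protein {pid!r}")
        if self.splits is not None:
            ids = set(by_id)
            for train, test in self.splits:
                if set(train) & set(test):
                    raise ValueError("train and test ids of a split overlap")
                if set(train) | set(test) != ids:
                    raise ValueError("a split does not cover the dataset")

    def __len__(self) -> int:
        return len(self.proteins)

    def __iter__(self):
        return iter(self.proteins)

    def protein(self, pid: str) -> Protein:
        for p in self.proteins:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def pattern(self, pid: str) -> DisulfidePattern:
        return self.patterns.get(pid, EMPTY_PATTERN)

    def subset(self, ids: Iterable[str]) -> "LabeledDataset":
        wanted = set(ids)
        proteins = [p for p in self.proteins if p.id in wanted]
        patterns = {p.id: self.pattern(p.id) for p in proteins}
        return LabeledDataset(proteins, patterns)
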