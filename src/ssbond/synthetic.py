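"""Synthetic proteins with planted disulfide patterns and annotation signal.

The generator emulates the statistical structure the prediction pipeline
assumes in real data:

* bonded cysteine pairs share an evolutionary-profile motif: the PSSM rows
  around both partners of a bridge carry a common prototype (one of a small
  fixed dictionary, drawn per bridge).  The motif is antisymmetric around
  the cysteine -- elevated on the prototype columns upstream, depressed
  downstream -- so its window *mean* equals the background and only a
  position-resolved local window can read it, not a histogram;
* all bonded cysteines additionally carry a common bonding-state motif, so
  the cysteine bonding state is learnable from the same windows;
* cysteines bonded to a sequence-consecutive partner sit closer together
  than free neighbours, so the cysteine separation profile is informative;
* bridge-free proteins have a shifted global amino-acid composition, so
  chain classification is learnable from global histograms.

All four effects scale with the signal strength ``s``; at s = 0 the dataset
carries no information beyond chance.  Generation is fully deterministic
given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .core import (
    AMINO_ACIDS,
    TRACK_LABELS,
    AnnotationTrack,
    DisulfidePattern,
    LabeledDataset,
    Protein,
)
from .matching import enumerate_patterns

_NON_CYS = [a for a in AMINO_ACIDS if a != "C"]
#: residues over-represented in bridge-free proteins (composition shift)
_SHIFT_RESIDUES = set("AGPST")

_N_PROTOTYPES = 6
#: background PSSM values are uniform on [_BG_LO, _BG_HI] (mean _BG_MEAN)
_BG_LO, _BG_HI = 0.2, 0.4
_BG_MEAN = (_BG_LO + _BG_HI) / 2
_MOTIF_DELTA = 0.2     # prototype amplitude around the background mean
_STATE_DELTA = 0.2     # bonding-state amplitude (columns 0 and 1)


def _prototype_columns(index: int) -> List[int]:
    """Two PSSM columns carrying prototype ``index`` (columns 0-1 are the
    bonding-state columns)."""
    return [2 + 2 * index, 3 + 2 * index]


@dataclass
class SyntheticConfig:
    """Study conditions for a generated dataset.

    Defaults describe a homogeneous benchmark of 500 fully-bonded proteins
    with four cysteines and two bridges at full signal strength.
    """

    n_proteins: int = 500
    length_range: Tuple[int, int] = (60, 120)
    n_cys: int = 4
    n_bridges: int = 2
    frac_bridge_free: float = 0.0
    frac_partial: float = 0.0
    signal: float = 1.0
    motif_half_width: int = 2
    noise_sd: float = 0.05
    dirichlet_concentration: float = 1.0
    extra_tracks: Tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.signal <= 1.0:
            raise ValueError("signal strength must lie in [0, 1]")
        if self.frac_bridge_free + self.frac_partial > 1.0 + 1e-9:
            raise ValueError("strata fractions exceed 1")
        if 2 * self.n_bridges > self.n_cys:
            raise ValueError(
                f"{self.n_bridges} bridges need at least {2 * self.n_bridges}"
                f" cysteines, config has {self.n_cys}"
            )
        if self.n_bridges > _N_PROTOTYPES:
            raise ValueError(f"at most {_N_PROTOTYPES} bridges are supported")
        if self.length_range[0] > self.length_range[1] or self.length_range[0] < 12:
            raise ValueError("invalid length range")


def _strata(config: SyntheticConfig, rng: np.random.Generator) -> List[str]:
    n_none = round(config.frac_bridge_free * config.n_proteins)
    n_mix = round(config.frac_partial * config.n_proteins)
    if n_none + n_mix > config.n_proteins:
        n_mix = config.n_proteins - n_none
    labels = (
        ["none"] * n_none
        + ["mix"] * n_mix
        + ["all"] * (config.n_proteins - n_none - n_mix)
    )
    rng.shuffle(labels)
    return labels


def _draw_positions(
    config: SyntheticConfig,
    bonds: frozenset,
    rng: np.random.Generator,
) -> Tuple[List[int], int]:
    """Cysteine positions; consecutive bonded cysteines sit closer (signal)."""
    positions = [int(rng.integers(3, 9))]
    for i in range(1, config.n_cys):
        consecutive_bonded = (i - 1, i) in bonds
        if consecutive_bonded and rng.random() < config.signal:
            gap = max(5, int(round(rng.normal(8.0, 2.0))))
        else:
            gap = max(5, int(round(rng.normal(12.0, 4.0))))
        positions.append(positions[-1] + gap)
    length = int(rng.integers(*config.length_range))
    length = max(length, positions[-1] + 5)
    return positions, length


def _draw_sequence(
    length: int,
    cys_positions: Sequence[int],
    bridge_free: bool,
    signal: float,
    rng: np.random.Generator,
) -> str:
    base = np.full(len(_NON_CYS), 1.0 / len(_NON_CYS))
    if bridge_free:
        shifted = np.array(
            [3.0 if a in _SHIFT_RESIDUES else 1.0 for a in _NON_CYS]
        )
        shifted /= shifted.sum()
        base = (1.0 - signal) * base + signal * shifted
    residues = rng.choice(list(_NON_CYS), size=length, p=base)
    for pos in cys_positions:
        residues[pos] = "C"
    return "".join(residues)


def _pssm_track(
    config: SyntheticConfig,
    length: int,
    cys_positions: Sequence[int],
    bonds: frozenset,
    rng: np.random.Generator,
) -> AnnotationTrack:
    values = rng.uniform(_BG_LO, _BG_HI, size=(length, 20))
    s, h = config.signal, config.motif_half_width
    if bonds:
        chosen = rng.choice(_N_PROTOTYPES, size=len(bonds), replace=False)
        for prototype_idx, (a, b) in zip(chosen, sorted(bonds)):
            columns = _prototype_columns(int(prototype_idx))
            for cys in (a, b):
                center = cys_positions[cys]
                # antisymmetric prototype: upstream rows elevated, downstream
                # rows depressed, so window means stay at the background level
                for offset in range(-h, 0):
                    row = center + offset
                    if 0 <= row < length:
                        values[row, columns] += s * _MOTIF_DELTA
                for offset in range(1, h + 1):
                    row = center + offset
                    if 0 <= row < length:
                        values[row, columns] -= s * _MOTIF_DELTA
                # bonding-state motif on the cysteine's own row
                values[center, [0, 1]] += s * _STATE_DELTA
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, size=values.shape)
    np.clip(values, 0.0, 1.0, out=values)
    return AnnotationTrack(
        "PSSM", list(TRACK_LABELS["PSSM"]), values, probabilistic=True
    )


def make_uninformative_track(
    protein: Protein, labels: Sequence[str], seed: int, name: str = "noise",
    concentration: float = 1.0,
) -> AnnotationTrack:
    """Rows drawn from a symmetric Dirichlet; no bonding information."""
    if not labels:
        raise ValueError("label set must be non-empty")
    rng = np.random.default_rng(seed)
    values = rng.dirichlet(
        np.full(len(labels), concentration), size=protein.length
    )
    return AnnotationTrack(name, list(labels), values, probabilistic=True)


def generate_dataset(config: SyntheticConfig) -> LabeledDataset:
    """Generate a labeled dataset under ``config`` (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    strata = _strata(config, rng)
    proteins: List[Protein] = []
    patterns: Dict[str, DisulfidePattern] = {}
    for index, stratum in enumerate(strata):
        if stratum == "none":
            n_bridges = 0
        elif stratum == "mix":
            n_bridges = max(1, min(config.n_bridges - 1, (config.n_cys - 1) // 2))
        else:
            n_bridges = config.n_bridges
        candidates = enumerate_patterns(config.n_cys, n_bridges)
        pattern = candidates[int(rng.integers(len(candidates)))]
        positions, length = _draw_positions(config, pattern.bonds, rng)
        sequence = _draw_sequence(
            length, positions, stratum == "none", config.signal, rng
        )
        protein = Protein(id=f"syn{index:04d}", sequence=sequence)
        assert protein.cysteine_positions == list(positions)
        protein.attach(_pssm_track(config, length, positions, pattern.bonds, rng))
        for track_name in config.extra_tracks:
            labels = TRACK_LABELS.get(track_name)
            if labels is None:
                raise ValueError(f"unknown extra track {track_name!r}")
            track = make_uninformative_track(
                protein,
                labels,
                seed=int(rng.integers(2 ** 31)),
                name=track_name,
                concentration=config.dirichlet_concentration,
            )
            protein.attach(track)
        proteins.append(protein)
        patterns[protein.id] = pattern
    return LabeledDataset(proteins, patterns)


def strata_counts(dataset: LabeledDataset) -> Dict[str, int]:
    """Count proteins by bonding stratum (all / none / mix)."""
    counts = {"all": 0, "none": 0, "mix": 0}
    for protein in dataset:
        bonded = dataset.pattern(protein.id).bonded_indices
        if not bonded:
            counts["none"] += 1
        elif len(bonded) == protein.n_cys:
            counts["all"] += 1
        else:
            counts["mix"] += 1
    return counts
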