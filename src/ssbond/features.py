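"""Feature functions encoding proteins, cysteines and cysteine pairs.

Twelve families are available:

====== ========== ======================================================
symbol arity      description
====== ========== ======================================================
Nr     protein    number of residues
Nc     protein    number of cysteines
Par    protein    parity of the number of cysteines
RelPos pair       relative residue positions of the two cysteines
PosDiff pair      normalized residue-position difference (always > 0)
RelIdx pair       relative cysteine indices
IdxDiff pair      normalized cysteine-index difference
CSP(w) cysteine   cysteine separation profile window
Hglob(A) protein  labels global histogram over annotation A
Hint(A) pair      labels interval histogram between the two cysteines
Hloc(A,w) cysteine labels local histogram (+ out-of-bounds fraction)
LW(A,w) cysteine  labels local window (out-of-bounds entries set to 0)
====== ========== ======================================================

Cysteine-arity members contribute once per cysteine of a pair (a first,
then b), doubling their single-cysteine dimensionality.  Feature order
within a vector is: member order, then cysteine a before b, then window
offset ascending, then labels in track order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import TRACK_LABELS, Protein

#: window-size grids used by the selection module
CSP_GRID = tuple(range(1, 20, 2))              # 1, 3, ..., 19
HLOC_GRID = tuple(range(10, 91, 10))           # 10, 20, ..., 90
LW_GRID = (1, 5, 9, 11, 15, 19, 21, 25)

SCALAR_SYMBOLS = ("Nr", "Nc", "Par", "RelPos", "PosDiff", "RelIdx", "IdxDiff")
PROTEIN_ARITY = ("Nr", "Nc", "Par", "Hglob")
CYSTEINE_ARITY = ("CSP", "Hloc", "LW")
PAIR_ARITY = ("RelPos", "PosDiff", "RelIdx", "IdxDiff", "Hint")


class ConfigurationError(ValueError):
    pass


def _n_labels(annotation: str) -> int:
    if annotation in TRACK_LABELS:
        return len(TRACK_LABELS[annotation])
    raise ConfigurationError(
        f"unknown annotation {annotation!r}; built-ins are"
        f" {sorted(TRACK_LABELS)}"
    )


@dataclass(frozen=True)
class FeatureFunction:
    """A parameterized feature function with a known dimensionality."""

    symbol: str
    annotation: Optional[str] = None
    window: Optional[int] = None

    def __post_init__(self):
        if self.symbol in SCALAR_SYMBOLS:
            if self.annotation is not None or self.window is not None:
                raise ConfigurationError(f"{self.symbol} takes no parameters")
        elif self.symbol == "CSP":
            if self.window is None or self.window < 1 or self.window % 2 == 0:
                raise ConfigurationError("CSP window must be a positive odd integer")
        elif self.symbol in ("Hglob", "Hint"):
            if self.annotation is None or self.window is not None:
                raise ConfigurationError(f"{self.symbol} needs an annotation only")
            _n_labels(self.annotation)
        elif self.symbol == "Hloc":
            if self.annotation is None or self.window is None or self.window < 1:
                raise ConfigurationError("Hloc needs an annotation and window >= 1")
            _n_labels(self.annotation)
        elif self.symbol == "LW":
            if self.annotation is None or self.window is None:
                raise ConfigurationError("LW needs an annotation and a window")
            if self.window < 1 or self.window % 2 == 0:
                raise ConfigurationError("LW window must be a positive odd integer")
            _n_labels(self.annotation)
        else:
            raise ConfigurationError(f"unknown feature function {self.symbol!r}")

    @property
    def arity(self) -> str:
        if self.symbol in ("Nr", "Nc", "Par", "Hglob"):
            return "protein"
        if self.symbol in ("CSP", "Hloc", "LW"):
            return "cysteine"
        return "pair"

    @property
    def d_single(self) -> int:
        """Dimensionality per evaluation (per cysteine for cysteine arity)."""
        if self.symbol in ("Nr", "Nc", "Par", "PosDiff", "IdxDiff"):
            return 1
        if self.symbol in ("RelPos", "RelIdx"):
            return 2
        if self.symbol == "CSP":
            return self.window
        if self.symbol in ("Hglob", "Hint"):
            return _n_labels(self.annotation)
        if self.symbol == "Hloc":
            return _n_labels(self.annotation) + 1
        return self.window * _n_labels(self.annotation)  # LW

    @property
    def d_pair(self) -> int:
        """Dimensionality contributed to a pair encoding."""
        return 2 * self.d_single if self.arity == "cysteine" else self.d_single

    def __str__(self) -> str:
        parts = [self.symbol]
        if self.annotation is not None:
            parts.append(self.annotation)
        if self.window is not None:
            parts.append(str(self.window))
        return ":".join(parts)


@dataclass
class FeatureFunctionSet:
    """Ordered collection of feature functions; one member per family."""

    functions: List[FeatureFunction]

    def __post_init__(self):
        keys = [(f.symbol, f.annotation) for f in self.functions]
        if len(set(keys)) != len(keys):
            raise ConfigurationError(
                "a feature function set holds at most one alternative per"
                " (symbol, annotation) family"
            )

    @property
    def total_d(self) -> int:
        return sum(f.d_pair for f in self.functions)

    @property
    def group_sizes(self) -> List[int]:
        """Per-member pair-encoding dimensionalities (for group normalization)."""
        return [f.d_pair for f in self.functions]

    def total_d_cysteine(self) -> int:
        return sum(f.d_single for f in self.functions)

    def total_d_protein(self) -> int:
        return sum(f.d_single for f in self.functions)

    def __iter__(self):
        return iter(self.functions)

    def __len__(self):
        return len(self.functions)

    def __str__(self) -> str:
        return ",".join(str(f) for f in self.functions)

    @classmethod
    def from_spec(cls, spec: str) -> "FeatureFunctionSet":
        """Parse a spec string like ``"LW:PSSM:15,CSP:17,Hloc:SS8:30,Nr"``."""
        functions = []
        for token in spec.split(","):
            token = token.strip()
            if not token:
                continue
            parts = token.split(":")
            symbol = parts[0]
            if symbol in SCALAR_SYMBOLS:
                if len(parts) != 1:
                    raise ConfigurationError(f"{symbol} takes no parameters: {token!r}")
                functions.append(FeatureFunction(symbol))
            elif symbol == "CSP":
                if len(parts) != 2:
                    raise ConfigurationError(f"expected CSP:<window>: {token!r}")
                functions.append(FeatureFunction("CSP", window=int(parts[1])))
            elif symbol in ("Hglob", "Hint"):
                if len(parts) != 2:
                    raise ConfigurationError(f"expected {symbol}:<track>: {token!r}")
                functions.append(FeatureFunction(symbol, annotation=parts[1]))
            elif symbol in ("Hloc", "LW"):
                if len(parts) != 3:
                    raise ConfigurationError(
                        f"expected {symbol}:<track>:<window>: {token!r}"
                    )
                functions.append(
                    FeatureFunction(symbol, annotation=parts[1], window=int(parts[2]))
                )
            else:
                raise ConfigurationError(f"unknown feature function {symbol!r}")
        return cls(functions)

    def describe(self) -> str:
        lines = [f"{str(f):<16s} arity={f.arity:<8s} d={f.d_pair}" for f in self]
        lines.append(f"{'total':<16s} {'':8s}   d={self.total_d}")
        return "\n".join(lines)


def scalar_features(
    protein: Protein, pair: Optional[Tuple[int, int]], symbol: str
) -> np.ndarray:
    """Evaluate one of the parameterless primary-structure feature functions."""
    L, n = protein.length, protein.n_cys
    if symbol == "Nr":
        return np.array([float(L)])
    if symbol == "Nc":
        return np.array([float(n)])
    if symbol == "Par":
        return np.array([float(n % 2)])
    if pair is None:
        raise ValueError(f"{symbol} is a pair feature function and needs a pair")
    a, b = pair
    if not 0 <= a < b < n:
        raise ValueError(f"pair ({a}, {b}) out of range for n_cys={n}")
    pos = protein.cysteine_positions
    if symbol == "RelPos":
        return np.array([(pos[a] + 1) / L, (pos[b] + 1) / L])
    if symbol == "PosDiff":
        return np.array([(pos[b] - pos[a]) / L])
    if symbol == "RelIdx":
        return np.array([(a + 1) / n, (b + 1) / n])
    if symbol == "IdxDiff":
        return np.array([(b - a) / n])
    raise ValueError(f"unknown scalar feature function {symbol!r}")


def csp_window(protein: Protein, cys_index: int, w: int) -> np.ndarray:
    """Cysteine separation profile: normalized position differences to the
    ``(w-1)/2`` neighbouring cysteines on each side (0 when out of bounds;
    the center slot is always 0)."""
    if w % 2 == 0 or w < 1:
        raise ConfigurationError("CSP window must be a positive odd integer")
    pos = protein.cysteine_positions
    n, L = protein.n_cys, protein.length
    if not 0 <= cys_index < n:
        raise ValueError(f"cysteine index {cys_index} out of range")
    half = (w - 1) // 2
    out = np.zeros(w)
    for slot, delta in enumerate(range(-half, half + 1)):
        neighbor = cys_index + delta
        if 0 <= neighbor < n:
            out[slot] = (pos[neighbor] - pos[cys_index]) / L
    return out


def global_histogram(protein: Protein, annotation: str) -> np.ndarray:
    """Per-label mean of the track values over the whole chain."""
    track = protein.track(annotation)
    return track.values.mean(axis=0)


def interval_histogram(
    protein: Protein, pair: Tuple[int, int], annotation: str
) -> np.ndarray:
    """Per-label mean over residues between the two cysteines (inclusive)."""
    a, b = pair
    if not a < b:
        raise ValueError("interval histogram requires a < b")
    track = protein.track(annotation)
    pos = protein.cysteine_positions
    return track.values[pos[a]: pos[b] + 1].mean(axis=0)


def local_histogram(
    protein: Protein, cys_index: int, annotation: str, w: int
) -> np.ndarray:
    """Per-label mean over a w-residue block around the cysteine, plus the
    fraction of the w positions falling outside the chain.

    The block covers offsets -floor(w/2) .. ceil(w/2)-1 (exactly w positions
    including the cysteine; for odd w this is symmetric).  The label means are
    taken over the in-bounds positions only; the boundary information is
    carried by the final out-of-bounds feature.
    """
    if w < 1:
        raise ConfigurationError("Hloc window must be >= 1")
    track = protein.track(annotation)
    center = protein.cysteine_positions[cys_index]
    lo, hi = center - w // 2, center + (w + 1) // 2  # [lo, hi) has w positions
    in_lo, in_hi = max(lo, 0), min(hi, protein.length)
    n_in = max(in_hi - in_lo, 0)
    if n_in > 0:
        label_part = track.values[in_lo:in_hi].mean(axis=0)
    else:
        label_part = np.zeros(track.n_labels)
    oob = (w - n_in) / w
    return np.concatenate([label_part, [oob]])


def local_window(
    protein: Protein, cys_index: int, annotation: str, w: int
) -> np.ndarray:
    """Raw track values over the centered odd window; out-of-bounds rows are 0."""
    if w % 2 == 0 or w < 1:
        raise ConfigurationError("LW window must be a positive odd integer")
    track = protein.track(annotation)
    center = protein.cysteine_positions[cys_index]
    half = (w - 1) // 2
    out = np.zeros((w, track.n_labels))
    for slot, delta in enumerate(range(-half, half + 1)):
        position = center + delta
        if 0 <= position < protein.length:
            out[slot] = track.values[position]
    return out.ravel()


def _evaluate_cysteine(
    protein: Protein, cys_index: int, function: FeatureFunction
) -> np.ndarray:
    if function.symbol == "CSP":
        return csp_window(protein, cys_index, function.window)
    if function.symbol == "Hloc":
        return local_histogram(protein, cys_index, function.annotation, function.window)
    return local_window(protein, cys_index, function.annotation, function.window)


def encode_pair(
    protein: Protein, pair: Tuple[int, int], feature_set: FeatureFunctionSet
) -> np.ndarray:
    """Concatenated encoding of a cysteine pair (a < b) under ``feature_set``."""
    a, b = pair
    if not 0 <= a < b < protein.n_cys:
        raise ValueError(f"pair ({a}, {b}) out of range for n_cys={protein.n_cys}")
    blocks: List[np.ndarray] = []
    for function in feature_set:
        if function.arity == "protein":
            if function.symbol == "Hglob":
                blocks.append(global_histogram(protein, function.annotation))
            else:
                blocks.append(scalar_features(protein, None, function.symbol))
        elif function.arity == "pair":
            if function.symbol == "Hint":
                blocks.append(interval_histogram(protein, pair, function.annotation))
            else:
                blocks.append(scalar_features(protein, pair, function.symbol))
        else:  # cysteine arity: a first, then b
            blocks.append(_evaluate_cysteine(protein, a, function))
            blocks.append(_evaluate_cysteine(protein, b, function))
    if not blocks:
        return np.zeros(0)
    vector = np.concatenate(blocks)
    assert vector.shape[0] == feature_set.total_d
    return vector


def encode_cysteine(
    protein: Protein, cys_index: int, feature_set: FeatureFunctionSet
) -> np.ndarray:
    """Encoding of a single cysteine (protein- and cysteine-arity members only)."""
    blocks: List[np.ndarray] = []
    for function in feature_set:
        if function.arity == "pair":
            raise ConfigurationError(
                f"{function} is pair-arity and cannot encode a single cysteine"
            )
        if function.arity == "protein":
            if function.symbol == "Hglob":
                blocks.append(global_histogram(protein, function.annotation))
            else:
                blocks.append(scalar_features(protein, None, function.symbol))
        else:
            blocks.append(_evaluate_cysteine(protein, cys_index, function))
    return np.concatenate(blocks) if blocks else np.zeros(0)


def encode_protein(protein: Protein, feature_set: FeatureFunctionSet) -> np.ndarray:
    """Encoding of a whole protein (protein-arity members only)."""
    blocks: List[np.ndarray] = []
    for function in feature_set:
        if function.arity != "protein":
            raise ConfigurationError(
                f"{function} is {function.arity}-arity and cannot encode a protein"
            )
        if function.symbol == "Hglob":
            blocks.append(global_histogram(protein, function.annotation))
        else:
            blocks.append(scalar_features(protein, None, function.symbol))
    return np.concatenate(blocks) if blocks else np.zeros(0)
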