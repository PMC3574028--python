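"""Forward feature-function selection and the nested evaluation protocol.

Feature functions are grouped into *parameterized families* -- one family
per (symbol, annotation), holding one alternative per window size (or a
singleton for parameterless functions).  The greedy forward algorithm starts
from an empty set and, at each iteration, evaluates every alternative of
every remaining family appended to the current set, inserts the best one and
removes its whole family from the candidate pool.  The objective is the
cross-validated Qp of the whole pipeline, so selection optimizes what the
final predictor is scored on rather than raw classifier accuracy.

To avoid selection bias, the nested protocol re-runs the whole selection
once per train/test split: selection only ever sees the train part (scored
by internal cross-validation), and the held-out part provides a verification
score that never influences any choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .classifiers import ClassifierConfig, train_pair_classifier, predict_pair_matrix
from .classifiers import pair_training_data
from .core import DisulfidePattern, LabeledDataset
from .features import (
    CSP_GRID,
    HLOC_GRID,
    LW_GRID,
    SCALAR_SYMBOLS,
    FeatureFunction,
    FeatureFunctionSet,
)
from .matching import max_weight_pattern
from .metrics import qp
from .model import assign_folds

logger = logging.getLogger(__name__)


@dataclass
class ParameterizedFamily:
    """A set of alternative feature functions differing only in window size."""

    family_id: str
    alternatives: List[FeatureFunction]

    def __post_init__(self):
        if not self.alternatives:
            raise ValueError(f"family {self.family_id!r} has no alternatives")
        symbols = {(f.symbol, f.annotation) for f in self.alternatives}
        if len(symbols) != 1:
            raise ValueError(
                f"family {self.family_id!r}: alternatives must share symbol"
                " and annotation"
            )

    @property
    def symbol(self) -> str:
        return self.alternatives[0].symbol

    def __len__(self):
        return len(self.alternatives)


def default_families(
    annotations: Sequence[str] = ("PSSM",),
    csp_grid: Sequence[int] = CSP_GRID,
    hloc_grid: Sequence[int] = HLOC_GRID,
    lw_grid: Sequence[int] = LW_GRID,
) -> List[ParameterizedFamily]:
    """The full candidate space: 7 parameterless primary functions, the CSP
    family, and per annotation one Hglob, one Hint, the Hloc grid and the LW
    grid."""
    families = [
        ParameterizedFamily(symbol, [FeatureFunction(symbol)])
        for symbol in SCALAR_SYMBOLS
    ]
    families.append(
        ParameterizedFamily(
            "CSP", [FeatureFunction("CSP", window=w) for w in csp_grid]
        )
    )
    for annotation in annotations:
        families.append(
            ParameterizedFamily(
                f"Hglob:{annotation}",
                [FeatureFunction("Hglob", annotation=annotation)],
            )
        )
        families.append(
            ParameterizedFamily(
                f"Hint:{annotation}",
                [FeatureFunction("Hint", annotation=annotation)],
            )
        )
        families.append(
            ParameterizedFamily(
                f"Hloc:{annotation}",
                [
                    FeatureFunction("Hloc", annotation=annotation, window=w)
                    for w in hloc_grid
                ],
            )
        )
        families.append(
            ParameterizedFamily(
                f"LW:{annotation}",
                [
                    FeatureFunction("LW", annotation=annotation, window=w)
                    for w in lw_grid
                ],
            )
        )
    return families


def candidate_count(families: Sequence[ParameterizedFamily]) -> int:
    """Total number of candidate feature functions across all families."""
    return sum(len(family) for family in families)


def cross_validated_objective(
    feature_set: FeatureFunctionSet,
    classifier_config: ClassifierConfig,
    dataset: LabeledDataset,
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Mean over CV folds of the test-fold Qp of the full pipeline.

    The protein-to-fold assignment is a deterministic function of ``seed``,
    so different feature sets scored with the same seed are compared on
    identical folds.
    """
    fold_of = assign_folds([p.id for p in dataset], folds, seed)
    scores = []
    for fold in range(folds):
        train = [p for p in dataset if fold_of[p.id] != fold]
        test = [p for p in dataset if fold_of[p.id] == fold]
        if not test:
            raise ValueError(f"fold {fold} has no test protein")
        X, y = pair_training_data(train, dataset.patterns, feature_set)
        model = train_pair_classifier(
            X, y, feature_set, classifier_config, seed=seed
        )
        predictions = {
            p.id: max_weight_pattern(predict_pair_matrix(model, p)).pattern
            if p.n_cys >= 2
            else DisulfidePattern()
            for p in test
        }
        truth = {p.id: dataset.pattern(p.id) for p in test}
        scores.append(qp(predictions, truth))
    return float(np.mean(scores))


@dataclass
class SelectionStep:
    function: FeatureFunction
    cv_score: float
    verification_score: Optional[float] = None


@dataclass
class SelectionTrace:
    steps: List[SelectionStep] = field(default_factory=list)

    @property
    def selected(self) -> FeatureFunctionSet:
        return FeatureFunctionSet([step.function for step in self.steps])

    @property
    def cv_scores(self) -> List[float]:
        return [step.cv_score for step in self.steps]

    @property
    def verification_scores(self) -> List[Optional[float]]:
        return [step.verification_score for step in self.steps]

    def to_rows(self) -> List[Dict[str, object]]:
        return [
            {
                "iteration": i + 1,
                "function": str(step.function),
                "cv_score": step.cv_score,
                "verification_score": step.verification_score,
            }
            for i, step in enumerate(self.steps)
        ]

    def to_tsv(self, path) -> None:
        with open(path, "w") as out:
            out.write("iteration\tfunction\tcv_score\tverification_score\n")
            for row in self.to_rows():
                verification = (
                    "" if row["verification_score"] is None
                    else f"{row['verification_score']:.4f}"
                )
                out.write(
                    f"{row['iteration']}\t{row['function']}\t"
                    f"{row['cv_score']:.4f}\t{verification}\n"
                )

    def plot(self, ax=None):
        """Cross-validated (solid) vs verification (dashed) score curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        iterations = range(1, len(self.steps) + 1)
        ax.plot(iterations, self.cv_scores, "r-", label="cross-validated")
        if any(v is not None for v in self.verification_scores):
            ax.plot(
                iterations,
                [v for v in self.verification_scores],
                "b--",
                label="verification",
            )
        ax.set_xlabel("iteration")
        ax.set_ylabel("Qp")
        ax.legend()
        return ax


def forward_select(
    families: Sequence[ParameterizedFamily],
    objective: Callable[[FeatureFunctionSet], float],
    max_iterations: int = 5,
    verification: Optional[Callable[[FeatureFunctionSet], float]] = None,
) -> SelectionTrace:
    """Greedy forward selection over feature-function families.

    At each iteration every alternative of every remaining family is
    evaluated appended to the current set; the best-scoring alternative is
    inserted and its family removed.  Objective ties go to the first
    candidate in family/alternative enumeration order.  Stops after
    ``max_iterations`` (or when no family remains).
    """
    if not families:
        raise ValueError("no candidate families")
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    remaining = list(families)
    current: List[FeatureFunction] = []
    trace = SelectionTrace()
    previous_best: Optional[float] = None
    for _ in range(max_iterations):
        if not remaining:
            break
        best_score: Optional[float] = None
        best_function: Optional[FeatureFunction] = None
        best_family_index: Optional[int] = None
        for family_index, family in enumerate(remaining):
            for alternative in family.alternatives:
                candidate = FeatureFunctionSet(current + [alternative])
                try:
                    score = objective(candidate)
                except Exception as exc:
                    raise RuntimeError(
                        f"objective failed on candidate {alternative}: {exc}"
                    ) from exc
                if best_score is None or score > best_score:
                    best_score = score
                    best_function = alternative
                    best_family_index = family_index
        current.append(best_function)
        del remaining[best_family_index]
        if previous_best is not None and best_score < previous_best:
            logger.warning(
                "cross-validated score decreased from %.4f to %.4f at %s",
                previous_best,
                best_score,
                best_function,
            )
        previous_best = best_score
        verification_score = (
            verification(FeatureFunctionSet(current))
            if verification is not None
            else None
        )
        trace.steps.append(
            SelectionStep(best_function, best_score, verification_score)
        )
    return trace


def make_splits(
    dataset: LabeledDataset,
    n_splits: int = 10,
    test_fraction: float = 0.1,
    seed: int = 0,
) -> List[Tuple[List[str], List[str]]]:
    """Independent train/test splits (default 90/10) at the protein level."""
    ids = [p.id for p in dataset]
    n_test = max(1, round(test_fraction * len(ids)))
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_splits):
        order = list(ids)
        rng.shuffle(order)
        splits.append((sorted(order[n_test:]), sorted(order[:n_test])))
    return splits


def nested_selection_protocol(
    dataset: LabeledDataset,
    splits: Sequence[Tuple[List[str], List[str]]],
    families: Sequence[ParameterizedFamily],
    classifier_config: ClassifierConfig,
    iterations: int = 5,
    seed: int = 0,
    cv_folds: int = 10,
) -> List[SelectionTrace]:
    """Run forward selection once per train/test split.

    Selection is driven entirely by cross-validation inside the train part;
    the held-out part only provides the per-iteration verification score.
    Overlapping train/test ids are rejected (selection-bias guard).
    """
    traces = []
    for split_index, (train_ids, test_ids) in enumerate(splits):
        if set(train_ids) & set(test_ids):
            raise ValueError(
                f"split {split_index}: train and test ids overlap"
            )
        train_set = dataset.subset(train_ids)
        test_set = dataset.subset(test_ids)

        def objective(feature_set: FeatureFunctionSet) -> float:
            return cross_validated_objective(
                feature_set, classifier_config, train_set,
                folds=cv_folds, seed=seed,
            )

        def verification(feature_set: FeatureFunctionSet) -> float:
            X, y = pair_training_data(
                train_set.proteins, train_set.patterns, feature_set
            )
            model = train_pair_classifier(
                X, y, feature_set, classifier_config, seed=seed
            )
            predictions = {
                p.id: max_weight_pattern(predict_pair_matrix(model, p)).pattern
                for p in test_set
            }
            truth = {p.id: test_set.pattern(p.id) for p in test_set}
            return qp(predictions, truth)

        traces.append(
            forward_select(
                families, objective, max_iterations=iterations,
                verification=verification,
            )
        )
    return traces


#: Default window-size distributions for the random sampling harness.
_LW_SAMPLER = (15.0, 6.0)    # Normal(mean, sd) snapped to the LW grid
_HLOC_SAMPLER = (40.0, 20.0)  # Normal(mean, sd) snapped to the Hloc grid


def _snap(value: float, grid: Sequence[int]) -> int:
    return min(grid, key=lambda g: (abs(g - value), g))


def sample_random_feature_set(
    size: int,
    families: Sequence[ParameterizedFamily],
    seed: int = 0,
) -> FeatureFunctionSet:
    """Draw ``size`` distinct families, then one alternative each.

    Local-window and local-histogram sizes come from truncated Gaussians
    snapped to their grids; CSP sizes are uniform on the CSP grid.
    """
    if not 1 <= size <= len(families):
        raise ValueError(
            f"size must lie in [1, {len(families)}], got {size}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(families), size=size, replace=False)
    functions = []
    for family_index in sorted(chosen):
        family = families[family_index]
        windows = [f.window for f in family.alternatives]
        if len(family) == 1:
            functions.append(family.alternatives[0])
        elif family.symbol == "LW":
            w = _snap(rng.normal(*_LW_SAMPLER), windows)
            functions.append(next(f for f in family.alternatives if f.window == w))
        elif family.symbol == "Hloc":
            w = _snap(rng.normal(*_HLOC_SAMPLER), windows)
            functions.append(next(f for f in family.alternatives if f.window == w))
        else:  # CSP: uniform on the grid
            w = windows[int(rng.integers(len(windows)))]
            functions.append(next(f for f in family.alternatives if f.window == w))
    return FeatureFunctionSet(functions)
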