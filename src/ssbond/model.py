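"""Model / Results classes for the three prediction tasks.

Each model is built from a :class:`~ssbond.core.LabeledDataset`; ``fit()``
runs a protein-level cross-validation of the full pipeline and returns a
Results object carrying out-of-fold predictions, the evaluation report and a
``summary()`` table.  Test proteins are never seen by the models that
predict them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .classifiers import (
    ClassifierConfig,
    TrainedPairClassifier,
    pair_training_data,
    predict_pair_matrix,
    train_pair_classifier,
)
from .core import DisulfidePattern, LabeledDataset, Protein
from .features import FeatureFunctionSet, encode_cysteine, encode_protein
from .matching import max_weight_pattern
from .metrics import EvaluationReport, binary_accuracy, mcc

DEFAULT_PATTERN_FEATURES = "LW:PSSM:15,CSP:17"
DEFAULT_STATE_FEATURES = "LW:PSSM:15,CSP:17"
DEFAULT_CHAIN_FEATURES = "Hglob:AA,Nr,Nc,Par"

SCENARIOS = (
    "none",
    "chain_known",
    "chain_predicted",
    "states_known",
    "states_predicted",
)


def _as_feature_set(spec: Union[str, FeatureFunctionSet]) -> FeatureFunctionSet:
    if isinstance(spec, FeatureFunctionSet):
        return spec
    return FeatureFunctionSet.from_spec(spec)


def assign_folds(
    ids: Sequence[str], folds: int, seed: int
) -> Dict[str, int]:
    """Deterministic protein-to-fold assignment (each fold non-empty)."""
    if folds < 2:
        raise ValueError("cross-validation needs at least 2 folds")
    if folds > len(ids):
        raise ValueError(
            f"{folds}-fold CV is impossible with {len(ids)} proteins"
        )
    rng = np.random.default_rng(seed)
    order = list(ids)
    rng.shuffle(order)
    return {pid: i % folds for i, pid in enumerate(order)}


def restricted_matching(
    matrix, bonded: Sequence[int]
) -> DisulfidePattern:
    """Match the subgraph induced by the admissible (bonded) cysteines.

    Equivalent to zeroing pair probabilities touching non-bonded cysteines;
    an odd admissible count leaves one cysteine unpaired (leave-one-out).
    """
    from .core import BondingProbabilityMatrix

    bonded = sorted(bonded)
    if len(bonded) < 2:
        return DisulfidePattern()
    sub = matrix.probs[np.ix_(bonded, bonded)]
    result = max_weight_pattern(BondingProbabilityMatrix(sub))
    return DisulfidePattern(
        (bonded[a], bonded[b]) for a, b in result.pattern.bonds
    )


# ---------------------------------------------------------------------------
# Cysteine bonding state model
# ---------------------------------------------------------------------------


def cysteine_training_data(
    proteins: Sequence[Protein],
    patterns,
    feature_set: FeatureFunctionSet,
) -> Tuple[np.ndarray, np.ndarray]:
    rows, labels = [], []
    for protein in proteins:
        bonded = patterns[protein.id].bonded_indices
        for k in range(protein.n_cys):
            rows.append(encode_cysteine(protein, k, feature_set))
            labels.append(1 if k in bonded else 0)
    if not rows:
        raise ValueError("no cysteines in the training proteins")
    return np.vstack(rows), np.array(labels, dtype=int)


@dataclass
class BondingStateResults:
    """Out-of-fold cysteine bonding-state predictions and accuracies."""

    probabilities: Dict[str, np.ndarray]
    states: Dict[str, List[bool]]
    truth: Dict[str, List[bool]]
    threshold: float
    fold_of: Dict[str, int]
    train_ids_per_fold: List[List[str]]

    @property
    def accuracy(self) -> float:
        pred = [s for pid in sorted(self.states) for s in self.states[pid]]
        true = [s for pid in sorted(self.truth) for s in self.truth[pid]]
        return binary_accuracy(pred, true)

    @property
    def mcc(self) -> float:
        pred = [s for pid in sorted(self.states) for s in self.states[pid]]
        true = [s for pid in sorted(self.truth) for s in self.truth[pid]]
        return mcc(pred, true)

    @property
    def chain_predictions(self) -> Dict[str, bool]:
        """Chain classification by the any-bonded-cysteine rule."""
        return {pid: any(states) for pid, states in self.states.items()}

    @property
    def chain_accuracy(self) -> float:
        pred = [self.chain_predictions[pid] for pid in sorted(self.states)]
        true = [any(self.truth[pid]) for pid in sorted(self.truth)]
        return binary_accuracy(pred, true)

    def summary(self) -> str:
        return (
            "Cysteine bonding state prediction\n"
            f"  proteins:        {len(self.states)}\n"
            f"  cysteines:       {sum(len(v) for v in self.states.values())}\n"
            f"  threshold:       {self.threshold}\n"
            f"  binary accuracy: {self.accuracy:.3f}\n"
            f"  MCC:             {self.mcc:.3f}\n"
            f"  chain accuracy (any-bonded rule): {self.chain_accuracy:.3f}"
        )


class BondingStateModel:
    """Classify cysteines into disulfide-bonded and free."""

    def __init__(
        self,
        dataset: LabeledDataset,
        feature_set: Union[str, FeatureFunctionSet] = DEFAULT_STATE_FEATURES,
        classifier: Optional[ClassifierConfig] = None,
        threshold: float = 0.5,
    ):
        if not 0.0 < threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        self.dataset = dataset
        self.feature_set = _as_feature_set(feature_set)
        for function in self.feature_set:
            if function.arity == "pair":
                raise ValueError(
                    f"{function} is pair-arity; bonding-state features must be"
                    " protein- or cysteine-arity"
                )
        self.classifier = classifier or ClassifierConfig.et()
        self.threshold = threshold

    def fit(self, folds: int = 10, seed: int = 0) -> BondingStateResults:
        fold_of = assign_folds([p.id for p in self.dataset], folds, seed)
        group_sizes = [f.d_single for f in self.feature_set]
        probabilities: Dict[str, np.ndarray] = {}
        states: Dict[str, List[bool]] = {}
        truth: Dict[str, List[bool]] = {}
        train_ids_per_fold: List[List[str]] = []
        for fold in range(folds):
            train = [p for p in self.dataset if fold_of[p.id] != fold]
            test = [p for p in self.dataset if fold_of[p.id] == fold]
            train_ids_per_fold.append([p.id for p in train])
            X, y = cysteine_training_data(
                train, self.dataset.patterns, self.feature_set
            )
            model = train_pair_classifier(
                X, y, self.feature_set, self.classifier, seed=seed,
                group_sizes=group_sizes,
            )
            for protein in test:
                if protein.n_cys == 0:
                    probabilities[protein.id] = np.zeros(0)
                    states[protein.id] = []
                else:
                    rows = np.vstack(
                        [
                            encode_cysteine(protein, k, self.feature_set)
                            for k in range(protein.n_cys)
                        ]
                    )
                    p = model.predict_proba(rows)
                    probabilities[protein.id] = p
                    states[protein.id] = [v >= self.threshold for v in p]
                bonded = self.dataset.pattern(protein.id).bonded_indices
                truth[protein.id] = [
                    k in bonded for k in range(protein.n_cys)
                ]
        return BondingStateResults(
            probabilities, states, truth, self.threshold, fold_of,
            train_ids_per_fold,
        )


# ---------------------------------------------------------------------------
# Chain classification model
# ---------------------------------------------------------------------------


@dataclass
class ChainClassificationResults:
    probabilities: Dict[str, float]
    predictions: Dict[str, bool]
    truth: Dict[str, bool]
    fold_of: Dict[str, int]

    @property
    def accuracy(self) -> float:
        ids = sorted(self.truth)
        return binary_accuracy(
            [self.predictions[i] for i in ids], [self.truth[i] for i in ids]
        )

    def summary(self) -> str:
        return (
            "Chain classification (any intra-chain bridge?)\n"
            f"  proteins: {len(self.truth)}\n"
            f"  accuracy: {self.accuracy:.3f}"
        )


class ChainClassificationModel:
    """Classify proteins into bridge-containing and bridge-free."""

    def __init__(
        self,
        dataset: LabeledDataset,
        feature_set: Union[str, FeatureFunctionSet] = DEFAULT_CHAIN_FEATURES,
        classifier: Optional[ClassifierConfig] = None,
    ):
        self.dataset = dataset
        self.feature_set = _as_feature_set(feature_set)
        for function in self.feature_set:
            if function.arity != "protein":
                raise ValueError(
                    f"{function} is {function.arity}-arity; chain features"
                    " must be protein-arity (Nr, Nc, Par, Hglob)"
                )
        self.classifier = classifier or ClassifierConfig.et()

    def fit(self, folds: int = 10, seed: int = 0) -> ChainClassificationResults:
        fold_of = assign_folds([p.id for p in self.dataset], folds, seed)
        group_sizes = [f.d_single for f in self.feature_set]
        labels = {
            p.id: bool(self.dataset.pattern(p.id).bonds) for p in self.dataset
        }
        probabilities: Dict[str, float] = {}
        for fold in range(folds):
            train = [p for p in self.dataset if fold_of[p.id] != fold]
            test = [p for p in self.dataset if fold_of[p.id] == fold]
            X = np.vstack([encode_protein(p, self.feature_set) for p in train])
            y = np.array([int(labels[p.id]) for p in train])
            model = train_pair_classifier(
                X, y, self.feature_set, self.classifier, seed=seed,
                group_sizes=group_sizes,
            )
            rows = np.vstack([encode_protein(p, self.feature_set) for p in test])
            for protein, p in zip(test, model.predict_proba(rows)):
                probabilities[protein.id] = float(p)
        predictions = {pid: p >= 0.5 for pid, p in probabilities.items()}
        return ChainClassificationResults(probabilities, predictions, labels, fold_of)


# ---------------------------------------------------------------------------
# Disulfide pattern model
# ---------------------------------------------------------------------------


@dataclass
class DisulfidePatternResults:
    """Out-of-fold pattern predictions with their evaluation report."""

    predictions: Dict[str, DisulfidePattern]
    report: EvaluationReport
    scenario: str
    fold_of: Dict[str, int]
    train_ids_per_fold: List[List[str]]
    state_results: Optional[BondingStateResults] = None
    diagnostics: Dict[str, int] = field(default_factory=dict)

    @property
    def qp(self) -> float:
        return self.report.qp

    @property
    def q2(self) -> float:
        return self.report.q2

    def summary(self) -> str:
        lines = [
            "Disulfide pattern prediction",
            f"  scenario:  {self.scenario}",
            f"  proteins:  {len(self.predictions)}",
            f"  Qp:        {self.report.qp:.3f}",
            f"  Q2:        {self.report.q2:.3f}",
            "  Qp by true bridge count:",
        ]
        for bridges, value in self.report.by_bridge_count.items():
            lines.append(f"    {bridges:>3s}: {value:.3f}")
        for key, value in self.diagnostics.items():
            lines.append(f"  {key}: {value}")
        return "\n".join(lines)


class DisulfidePatternModel:
    """Three-step pattern predictor: encode pairs, classify, match.

    ``scenario`` selects the filter applied before matching:

    * ``none`` -- always construct a full pattern;
    * ``chain_known`` / ``chain_predicted`` -- empty pattern for (known /
      predicted) bridge-free chains;
    * ``states_known`` / ``states_predicted`` -- restrict matching to the
      (known / predicted) bonded cysteines.
    """

    def __init__(
        self,
        dataset: LabeledDataset,
        feature_set: Union[str, FeatureFunctionSet] = DEFAULT_PATTERN_FEATURES,
        classifier: Optional[ClassifierConfig] = None,
        scenario: str = "none",
        state_feature_set: Union[str, FeatureFunctionSet] = DEFAULT_STATE_FEATURES,
        state_classifier: Optional[ClassifierConfig] = None,
        threshold: float = 0.5,
    ):
        if scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        self.dataset = dataset
        self.feature_set = _as_feature_set(feature_set)
        self.classifier = classifier or ClassifierConfig.et()
        self.scenario = scenario
        self.state_feature_set = _as_feature_set(state_feature_set)
        self.state_classifier = state_classifier or ClassifierConfig.et()
        self.threshold = threshold

    @classmethod
    def from_files(
        cls, fasta_path, bond_table_path, pssm_paths=None, **kwargs
    ) -> "DisulfidePatternModel":
        """Build a model from FASTA + bond table (+ optional per-id PSSMs)."""
        from .io import read_bond_table, read_fasta, read_psiblast_pssm

        proteins = read_fasta(fasta_path)
        if pssm_paths:
            for protein in proteins:
                if protein.id in pssm_paths:
                    protein.attach(
                        read_psiblast_pssm(pssm_paths[protein.id], protein)
                    )
        patterns = read_bond_table(bond_table_path, proteins)
        return cls(LabeledDataset(proteins, patterns), **kwargs)

    def _needs_states(self) -> bool:
        return self.scenario in ("chain_predicted", "states_predicted")

    def fit(self, folds: int = 10, seed: int = 0) -> DisulfidePatternResults:
        dataset = self.dataset
        fold_of = assign_folds([p.id for p in dataset], folds, seed)
        state_results = None
        if self._needs_states():
            state_model = BondingStateModel(
                dataset,
                self.state_feature_set,
                self.state_classifier,
                self.threshold,
            )
            state_results = state_model.fit(folds=folds, seed=seed)
        predictions: Dict[str, DisulfidePattern] = {}
        train_ids_per_fold: List[List[str]] = []
        unrecoverable = 0
        for fold in range(folds):
            train = [p for p in dataset if fold_of[p.id] != fold]
            test = [p for p in dataset if fold_of[p.id] == fold]
            train_ids_per_fold.append([p.id for p in train])
            X, y = pair_training_data(train, dataset.patterns, self.feature_set)
            model = train_pair_classifier(
                X, y, self.feature_set, self.classifier, seed=seed
            )
            for protein in test:
                truth = dataset.pattern(protein.id)
                predictions[protein.id] = self._predict_one(
                    protein, model, truth, state_results
                )
                if self.scenario == "states_predicted":
                    predicted_bonded = {
                        k
                        for k, s in enumerate(state_results.states[protein.id])
                        if s
                    }
                    if truth.bonded_indices - predicted_bonded:
                        unrecoverable += 1
        report = EvaluationReport.build(
            predictions,
            dataset.patterns,
            {p.id: p.n_cys for p in dataset},
        )
        diagnostics = {}
        if self.scenario == "states_predicted":
            diagnostics["unrecoverable_proteins"] = unrecoverable
        return DisulfidePatternResults(
            predictions,
            report,
            self.scenario,
            fold_of,
            train_ids_per_fold,
            state_results,
            diagnostics,
        )

    def _predict_one(
        self,
        protein: Protein,
        model: TrainedPairClassifier,
        truth: DisulfidePattern,
        state_results: Optional[BondingStateResults],
    ) -> DisulfidePattern:
        if protein.n_cys < 2:
            return DisulfidePattern()
        scenario = self.scenario
        if scenario == "chain_known" and not truth.bonds:
            return DisulfidePattern()
        if scenario == "chain_predicted":
            if not any(state_results.states[protein.id]):
                return DisulfidePattern()
        matrix = predict_pair_matrix(model, protein)
        if scenario == "states_known":
            bonded = sorted(truth.bonded_indices)
            if len(bonded) % 2 == 1:
                warnings.warn(
                    f"{protein.id}: odd number of known bonded cysteines;"
                    " one is left unpaired"
                )
            return restricted_matching(matrix, bonded)
        if scenario == "states_predicted":
            bonded = [
                k for k, s in enumerate(state_results.states[protein.id]) if s
            ]
            if len(bonded) % 2 == 1:
                warnings.warn(
                    f"{protein.id}: odd number of predicted bonded cysteines;"
                    " one is left unpaired"
                )
            return restricted_matching(matrix, bonded)
        return max_weight_pattern(matrix).pattern
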