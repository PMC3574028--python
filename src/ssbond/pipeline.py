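"""End-to-end predictors for the three tasks and the filter scenarios.

The three tasks are disulfide pattern prediction, chain classification
(does the protein contain any intra-chain bridge?) and cysteine bonding
state prediction.  Five scenarios control how the two auxiliary tasks
filter the pattern predictor: ``none``, ``chain_known``, ``chain_predicted``,
``states_known`` and ``states_predicted``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .classifiers import (
    ClassifierConfig,
    TrainedPairClassifier,
    predict_pair_matrix,
    train_pair_classifier,
)
from .core import DisulfidePattern, LabeledDataset, Protein
from .features import FeatureFunctionSet, encode_cysteine, encode_protein
from .matching import max_weight_pattern
from .metrics import EvaluationReport, binary_accuracy
from .model import (
    DEFAULT_CHAIN_FEATURES,
    DEFAULT_PATTERN_FEATURES,
    DEFAULT_STATE_FEATURES,
    SCENARIOS,
    BondingStateModel,
    BondingStateResults,
    DisulfidePatternModel,
    DisulfidePatternResults,
    _as_feature_set,
    restricted_matching,
)


@dataclass
class PipelineConfig:
    """Feature sets, classifier configs and scenario for the full pipeline."""

    pattern_features: str = DEFAULT_PATTERN_FEATURES
    state_features: str = DEFAULT_STATE_FEATURES
    chain_features: str = DEFAULT_CHAIN_FEATURES
    pattern_classifier: ClassifierConfig = field(default_factory=ClassifierConfig.et)
    state_classifier: ClassifierConfig = field(default_factory=ClassifierConfig.et)
    chain_classifier: ClassifierConfig = field(default_factory=ClassifierConfig.et)
    scenario: str = "none"
    threshold: float = 0.5
    folds: int = 10

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


def predict_bonding_states(
    protein: Protein,
    classifier: TrainedPairClassifier,
    threshold: float = 0.5,
) -> Tuple[List[bool], np.ndarray]:
    """Per-cysteine bonded/free calls plus the underlying probabilities."""
    if protein.n_cys == 0:
        return [], np.zeros(0)
    rows = np.vstack(
        [
            encode_cysteine(protein, k, classifier.feature_set)
            for k in range(protein.n_cys)
        ]
    )
    probabilities = classifier.predict_proba(rows)
    return [p >= threshold for p in probabilities], probabilities


def chain_class_from_states(states: Sequence[bool]) -> bool:
    """True iff at least one cysteine is (predicted) bonded."""
    return any(states)


def train_chain_classifier(
    dataset: LabeledDataset,
    feature_set=DEFAULT_CHAIN_FEATURES,
    classifier: Optional[ClassifierConfig] = None,
    seed: int = 0,
) -> TrainedPairClassifier:
    """Fit a protein-level bridge/no-bridge classifier on the whole dataset."""
    feature_set = _as_feature_set(feature_set)
    X = np.vstack([encode_protein(p, feature_set) for p in dataset])
    y = np.array(
        [int(bool(dataset.pattern(p.id).bonds)) for p in dataset]
    )
    return train_pair_classifier(
        X,
        y,
        feature_set,
        classifier or ClassifierConfig.et(),
        seed=seed,
        group_sizes=[f.d_single for f in feature_set],
    )


def predict_pattern(
    protein: Protein,
    classifier: TrainedPairClassifier,
    scenario: str = "none",
    has_bridges: Optional[bool] = None,
    bonded_states: Optional[Sequence[bool]] = None,
) -> DisulfidePattern:
    """Predict one protein's pattern under a scenario filter.

    ``has_bridges`` feeds the chain scenarios; ``bonded_states`` feeds the
    cysteine-state scenarios (known or predicted upstream).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    if protein.n_cys < 2:
        return DisulfidePattern()
    if scenario in ("chain_known", "chain_predicted"):
        if has_bridges is None:
            raise ValueError(f"scenario {scenario!r} needs has_bridges")
        if not has_bridges:
            return DisulfidePattern()
        matrix = predict_pair_matrix(classifier, protein)
        return max_weight_pattern(matrix).pattern
    if scenario in ("states_known", "states_predicted"):
        if bonded_states is None:
            raise ValueError(f"scenario {scenario!r} needs bonded_states")
        bonded = [k for k, s in enumerate(bonded_states) if s]
        if len(bonded) % 2 == 1:
            warnings.warn(
                f"{protein.id}: odd number of bonded cysteines; one is left"
                " unpaired"
            )
        matrix = predict_pair_matrix(classifier, protein)
        return restricted_matching(matrix, bonded)
    matrix = predict_pair_matrix(classifier, protein)
    return max_weight_pattern(matrix).pattern


@dataclass
class ScenarioResult:
    scenario: str
    pattern_results: Optional[DisulfidePatternResults] = None
    state_results: Optional[BondingStateResults] = None
    chain_accuracy: Optional[float] = None
    skipped: Optional[str] = None

    @property
    def report(self) -> Optional[EvaluationReport]:
        return self.pattern_results.report if self.pattern_results else None

    def summary(self) -> str:
        if self.skipped:
            return f"[{self.scenario}] skipped: {self.skipped}"
        lines = [f"[{self.scenario}] Qp={self.report.qp:.3f} Q2={self.report.q2:.3f}"]
        if self.state_results is not None:
            lines.append(
                f"  bonding-state accuracy={self.state_results.accuracy:.3f}"
            )
        if self.chain_accuracy is not None:
            lines.append(f"  chain accuracy={self.chain_accuracy:.3f}")
        for key, value in self.pattern_results.diagnostics.items():
            lines.append(f"  {key}={value}")
        return "\n".join(lines)


def run_scenarios(
    dataset: LabeledDataset,
    config: Optional[PipelineConfig] = None,
    seed: int = 0,
    scenarios: Sequence[str] = SCENARIOS,
) -> Dict[str, ScenarioResult]:
    """Cross-validated evaluation of the pattern predictor per scenario.

    Chain scenarios are skipped (with a notice) when the dataset has no
    bridge-free protein, since filtering can then change nothing.
    """
    config = config or PipelineConfig()
    has_bridge_free = any(not dataset.pattern(p.id).bonds for p in dataset)
    results: Dict[str, ScenarioResult] = {}
    state_results: Optional[BondingStateResults] = None
    for scenario in scenarios:
        if scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {scenario!r}")
        if scenario in ("chain_known", "chain_predicted") and not has_bridge_free:
            results[scenario] = ScenarioResult(
                scenario,
                skipped="dataset has no bridge-free protein; chain filters"
                " are irrelevant",
            )
            continue
        model = DisulfidePatternModel(
            dataset,
            feature_set=config.pattern_features,
            classifier=config.pattern_classifier,
            scenario=scenario,
            state_feature_set=config.state_features,
            state_classifier=config.state_classifier,
            threshold=config.threshold,
        )
        fitted = model.fit(folds=config.folds, seed=seed)
        chain_accuracy = None
        if fitted.state_results is not None:
            state_results = fitted.state_results
            chain_accuracy = fitted.state_results.chain_accuracy
        results[scenario] = ScenarioResult(
            scenario, fitted, fitted.state_results, chain_accuracy
        )
    return results
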