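"""Evaluation measures for disulfide prediction.

Qp is the protein-level pattern accuracy: the proportion of proteins whose
entire predicted bond set equals the true bond set.  Q2 is the pair-level
accuracy: the proportion of cysteine pairs (a < b, pooled over proteins)
correctly labeled bonded / non-bonded.  Both equal 1 for perfect predictions
but are not perfectly correlated in general.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, sqrt
from typing import Dict, List, Mapping, Optional, Sequence

from .core import DisulfidePattern


def _check_ids(predicted: Mapping, truth: Mapping) -> None:
    if set(predicted) != set(truth):
        missing = set(predicted) ^ set(truth)
        raise ValueError(f"protein id sets differ: {sorted(missing)[:5]}")


def qp(
    predicted: Mapping[str, DisulfidePattern],
    truth: Mapping[str, DisulfidePattern],
) -> float:
    """Fraction of proteins whose predicted pattern is exactly correct."""
    _check_ids(predicted, truth)
    if not truth:
        raise ValueError("qp is undefined on an empty dataset")
    exact = sum(predicted[pid].bonds == truth[pid].bonds for pid in truth)
    return exact / len(truth)


def q2(
    predicted: Mapping[str, DisulfidePattern],
    truth: Mapping[str, DisulfidePattern],
    n_cys: Mapping[str, int],
    pooled: bool = True,
) -> float:
    """Fraction of cysteine pairs correctly labeled bonded / non-bonded.

    The pair universe is all a < b per protein; proteins with fewer than two
    cysteines contribute no pairs.  ``pooled=True`` micro-averages over all
    pairs across proteins; ``pooled=False`` macro-averages per-protein rates.
    """
    _check_ids(predicted, truth)
    per_protein: List[tuple] = []
    for pid in truth:
        n = n_cys[pid]
        total = comb(n, 2)
        if total == 0:
            continue
        pred, true = predicted[pid].bonds, truth[pid].bonds
        wrong = len(pred ^ true)  # each mislabeled pair appears in exactly one set
        per_protein.append((total - wrong, total))
    if not per_protein:
        raise ValueError("q2 is undefined: no protein contributes pairs")
    if pooled:
        correct = sum(c for c, _ in per_protein)
        total = sum(t for _, t in per_protein)
        return correct / total
    return sum(c / t for c, t in per_protein) / len(per_protein)


def binary_accuracy(predicted: Sequence[int], truth: Sequence[int]) -> float:
    """Fraction of matching binary labels."""
    if len(predicted) != len(truth):
        raise ValueError("label vectors differ in length")
    if len(truth) == 0:
        raise ValueError("accuracy is undefined on empty input")
    return sum(int(p) == int(t) for p, t in zip(predicted, truth)) / len(truth)


def mcc(predicted: Sequence[int], truth: Sequence[int]) -> float:
    """Matthews correlation coefficient; 0 when the denominator vanishes."""
    if len(predicted) != len(truth):
        raise ValueError("label vectors differ in length")
    tp = fp = tn = fn = 0
    for p, t in zip(predicted, truth):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / sqrt(denom)


@dataclass
class EvaluationReport:
    """Qp/Q2 with per-protein correctness flags and a per-bridge breakdown."""

    qp: float
    q2: float
    correct: Dict[str, bool]
    by_bridge_count: Dict[str, float] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        predicted: Mapping[str, DisulfidePattern],
        truth: Mapping[str, DisulfidePattern],
        n_cys: Mapping[str, int],
        pooled_q2: bool = True,
    ) -> "EvaluationReport":
        _check_ids(predicted, truth)
        flags = {pid: predicted[pid].bonds == truth[pid].bonds for pid in truth}
        breakdown: Dict[str, float] = {}
        counts = sorted({truth[pid].n_bonds for pid in truth})
        for b in counts:
            ids = [pid for pid in truth if truth[pid].n_bonds == b]
            breakdown[str(b)] = sum(flags[pid] for pid in ids) / len(ids)
        breakdown["all"] = sum(flags.values()) / len(flags)
        return cls(
            qp=qp(predicted, truth),
            q2=q2(predicted, truth, n_cys, pooled=pooled_q2),
            correct=flags,
            by_bridge_count=breakdown,
        )

    def to_rows(self) -> List[Dict[str, object]]:
        return [
            {"bridges": key, "qp": value}
            for key, value in self.by_bridge_count.items()
        ]

    def to_tsv(self, path) -> None:
        with open(path, "w") as out:
            out.write("bridges\tqp\n")
            for row in self.to_rows():
                out.write(f"{row['bridges']}\t{row['qp']:.4f}\n")

    def to_dict(self) -> Dict[str, object]:
        return {
            "qp": self.qp,
            "q2": self.q2,
            "by_bridge_count": self.by_bridge_count,
        }
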