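"""Score predictions and tool combinations against a reference annotation.

Matching is by (strand, stop position).  Reference genes are classified as
perfect (a prediction matches start and stop), partial (stop matched, start
differs), or missed; predictions matching no reference stop are spurious.
Tool combinations are merged with the consensus rules before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

from .merge import merge_coordinates
from .predictions import GenePrediction

__all__ = ["EvaluationReport", "evaluate", "evaluate_combinations"]


@dataclass(frozen=True)
class EvaluationReport:
    n_reference: int
    n_predicted: int
    perfect: int
    partial: int
    missed: int
    spurious: int

    def __post_init__(self) -> None:
        assert self.perfect + self.partial + self.missed == self.n_reference

    @property
    def rank_key(self) -> tuple[int, int, int]:
        # more perfect, then more partial, then fewer spurious
        return (-self.perfect, -self.partial, self.spurious)


def _stop_key(p: GenePrediction) -> tuple[str, str, int]:
    return (p.contig_id, p.strand, p.stop_position)


def evaluate(predictions: Sequence[GenePrediction],
             reference: Sequence[GenePrediction],
             merge_first: bool = True) -> EvaluationReport:
    """Classify predictions against reference genes by shared stop position.

    With ``merge_first`` (default) predictions are consensus-merged, so each
    (strand, stop) contributes one prediction; every prediction and every
    reference gene is classified exactly once.
    """
    if not reference:
        raise ValueError("empty reference annotation")
    if merge_first:
        preds = [w for w, _tools in merge_coordinates(predictions)]
    else:
        preds = list(predictions)
    pred_by_stop: dict[tuple[str, str, int], list[GenePrediction]] = {}
    for p in preds:
        pred_by_stop.setdefault(_stop_key(p), []).append(p)

    perfect = partial = missed = 0
    matched_keys: set[tuple[str, str, int]] = set()
    for ref in reference:
        key = _stop_key(ref)
        candidates = pred_by_stop.get(key, [])
        if not candidates:
            missed += 1
            continue
        matched_keys.add(key)
        if any((p.start, p.end) == (ref.start, ref.end) for p in candidates):
            perfect += 1
        else:
            partial += 1
    spurious = sum(len(v) for k, v in pred_by_stop.items()
                   if k not in matched_keys)
    return EvaluationReport(len(reference), len(preds), perfect, partial,
                            missed, spurious)


def evaluate_combinations(per_tool_predictions: Mapping[str, Sequence[GenePrediction]],
                          reference: Sequence[GenePrediction],
                          k: int = 3,
                          ) -> list[tuple[tuple[str, ...], EvaluationReport]]:
    """Score every k-subset of tools after consensus-merging their output.

    Returns (tool combination, report) pairs ranked best-first by perfect
    count, then partial count, then fewest spurious predictions.
    """
    tools = sorted(per_tool_predictions)
    if k > len(tools):
        raise ValueError(f"k={k} exceeds the {len(tools)} available tools")
    ranked = []
    for combo in combinations(tools, k):
        pooled = [p for t in combo for p in per_tool_predictions[t]]
        ranked.append((combo, evaluate(pooled, reference)))
    ranked.sort(key=lambda pair: (pair[1].rank_key, pair[0]))
    return ranked
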