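"""Ranking-quality metrics for condition recommendation.

MRR@K — mean over reactions of 1 / (best rank of an experimentally observed
combination within the top K); a reaction with no observed combination in
the top K contributes 0, keeping the metric in [0, 1].  Ranks are 1-based.

P@K — percentage of reactions for which at least one observed combination
appears within the top K.

component_accuracy generalizes P@K to a subset of the four condition
components: a top-K prediction matches when the selected components all agree
with some experimental combination, the other components being ignored.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .conditions import ConditionCombination
from .rankers import RankedConditions

COMPONENTS = ("temperature", "pressure", "catalyst", "additives")


@dataclass
class RelevanceJudgment:
    """Per reaction: the set of experimentally observed combinations."""

    relevant: list[set[ConditionCombination]]

    def __post_init__(self) -> None:
        if any(not s for s in self.relevant):
            raise ValueError("every reaction needs a non-empty relevant set")

    def __len__(self) -> int:
        return len(self.relevant)


def _check_aligned(rankings: Sequence[RankedConditions], judgments: RelevanceJudgment, k: int) -> None:
    if len(rankings) != len(judgments):
        raise ValueError(
            f"{len(rankings)} rankings vs {len(judgments)} judgments"
        )
    if k < 1:
        raise ValueError(f"K must be >= 1, got {k}")


def mrr_at_k(
    rankings: Sequence[RankedConditions],
    judgments: RelevanceJudgment,
    k: int,
) -> float:
    _check_aligned(rankings, judgments, k)
    total = 0.0
    for ranking, relevant in zip(rankings, judgments.relevant):
        for rank, combo in enumerate(ranking.top(k), start=1):
            if combo in relevant:
                total += 1.0 / rank
                break
    return total / len(judgments)


def p_at_k(
    rankings: Sequence[RankedConditions],
    judgments: RelevanceJudgment,
    k: int,
) -> float:
    """Percentage in [0, 100]."""
    _check_aligned(rankings, judgments, k)
    hits = sum(
        any(c in relevant for c in ranking.top(k))
        for ranking, relevant in zip(rankings, judgments.relevant)
    )
    return 100.0 * hits / len(judgments)


def _project(c: ConditionCombination, components: Sequence[str]) -> tuple:
    key = []
    for comp in components:
        if comp == "temperature":
            key.append(c.temperature_bin)
        elif comp == "pressure":
            key.append(c.pressure_bin)
        elif comp == "catalyst":
            key.append(c.catalyst)
        elif comp == "additives":
            key.append((c.acid, c.base, c.poison))
        else:
            raise ValueError(f"unknown component {comp!r}")
    return tuple(key)


def component_accuracy(
    rankings: Sequence[RankedConditions],
    judgments: RelevanceJudgment,
    k: int,
    components: Sequence[str],
) -> float:
    """P@K counting a hit when the chosen components match some experimental
    combination, ignoring the rest.  With all four components this equals
    p_at_k."""
    if not components:
        raise ValueError("components must be non-empty")
    _check_aligned(rankings, judgments, k)
    hits = 0
    for ranking, relevant in zip(rankings, judgments.relevant):
        targets = {_project(r, components) for r in relevant}
        if any(_project(c, components) in targets for c in ranking.top(k)):
            hits += 1
    return 100.0 * hits / len(judgments)


def evaluation_report(
    rankings_by_model: dict[str, Sequence[RankedConditions]],
    judgments: RelevanceJudgment,
    ks: Iterable[int],
    component_subsets: Sequence[Sequence[str]] = (COMPONENTS,),
) -> list[dict]:
    """Rows of {model, K, components, mrr, p} for every model/K/subset."""
    rows = []
    for model, rankings in rankings_by_model.items():
        for k in ks:
            rows.append({
                "model": model,
                "K": k,
                "components": "+".join(COMPONENTS),
                "mrr": mrr_at_k(rankings, judgments, k),
                "p": p_at_k(rankings, judgments, k),
            })
            for subset in component_subsets:
                if tuple(subset) == COMPONENTS:
                    continue
                rows.append({
                    "model": model,
                    "K": k,
                    "components": "+".join(subset),
                    "mrr": float("nan"),
                    "p": component_accuracy(rankings, judgments, k, subset),
                })
    return rows


def write_report(path: str | Path, rows: list[dict]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["model", "K", "components", "mrr", "p"])
        writer.writeheader()
        writer.writerows(rows)
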