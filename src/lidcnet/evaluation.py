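"""Essential-set selection and evaluation against a gold standard.

Ranked score tables are turned into predicted essential sets either by
absolute rank (top-k, the 100..600 ranking ranges) or by fraction of the
scored network (top 20% is the conventional choice).  Predictions are scored
with precision / recall / F-score over an explicit evaluation universe —
normally the pruned network that was actually ranked — and with a jackknife
curve: the cumulative count of true essentials as the ranking is traversed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GoldStandard

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvaluationResult:
    """Confusion counts and derived metrics for one predicted set."""

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    fscore: float
    universe_size: int
    universe: str = "evaluated network"


def select_top_k(table: pd.DataFrame, k: int) -> set[str]:
    """First k proteins of the final ranking."""
    n = len(table)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    return set(table["protein"].iloc[:k])


def select_top_fraction(table: pd.DataFrame, fraction: float, *,
                        rounding: str = "ceil") -> set[str]:
    """Top ``fraction`` of the final ranking.

    The count is ``ceil(fraction * N)`` by default; ``rounding`` may also be
    ``"round"`` or ``"floor"`` (the rounding convention behind published
    top-20% counts is not always consistent, so it is a switch rather than a
    constant).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = len(table)
    if rounding == "ceil":
        k = math.ceil(fraction * n)
    elif rounding == "floor":
        k = math.floor(fraction * n)
    elif rounding == "round":
        k = round(fraction * n)
    else:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    return set(table["protein"].iloc[:k])


def classification_metrics(predicted: set[str], gold: GoldStandard,
                           universe: set[str], *,
                           recall_denominator: str = "universe",
                           strict_gold: bool = False) -> EvaluationResult:
    """Precision, recall and F-score of a predicted essential set.

    ``universe`` is the set of evaluable proteins (normally the nodes of the
    ranked network); ``predicted`` must be a subset of it.  Anything in the
    universe not listed essential is treated as non-essential unless
    ``strict_gold`` is set, in which case proteins absent from both gold lists
    are excluded from the bookkeeping entirely.

    ``recall_denominator="universe"`` (default) restricts the recall
    denominator to gold-essential proteins present in the universe;
    ``"full"`` uses the entire gold essential list.
    """
    if not universe:
        raise ValueError("evaluation universe is empty")
    if not predicted <= universe:
        raise ValueError("predicted set is not a subset of the universe")
    if strict_gold and gold.nonessential is not None:
        listed = gold.essential | gold.nonessential
        universe = universe & listed
        predicted = predicted & listed
    essential_in_universe = gold.essential & universe
    tp = len(predicted & essential_in_universe)
    fp = len(predicted) - tp
    if recall_denominator == "universe":
        fn = len(essential_in_universe - predicted)
    elif recall_denominator == "full":
        fn = len(gold.essential - predicted)
    else:
        raise ValueError(f"unknown recall_denominator {recall_denominator!r}")
    tn = len(universe) - len(predicted) - len(essential_in_universe - predicted)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    fscore = (2 * precision * recall / (precision + recall)
              if precision + recall > 0 else 0.0)
    return EvaluationResult(tp=tp, fp=fp, fn=fn, tn=tn,
                            precision=precision, recall=recall, fscore=fscore,
                            universe_size=len(universe))


def jackknife_curve(table: pd.DataFrame, gold: GoldStandard,
                    max_rank: int) -> np.ndarray:
    """Cumulative count of gold-essential proteins along the final ranking.

    Entry r-1 is the number of true essentials among the top r proteins,
    r = 1..max_rank.  ``max_rank`` beyond the table length is clamped with a
    warning.
    """
    if max_rank < 1:
        raise ValueError(f"max_rank must be positive, got {max_rank}")
    n = len(table)
    if max_rank > n:
        logger.warning("max_rank %d exceeds table size %d; clamped", max_rank, n)
        max_rank = n
    hits = table["protein"].iloc[:max_rank].isin(gold.essential)
    return np.cumsum(hits.to_numpy(dtype=int))
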