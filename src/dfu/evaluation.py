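"""Correlation of polarization measures with gold human judgments.

Given histograms paired with an averaged human polarization judgment
(the "gold" score), computes Spearman/Pearson correlations per measure
and emits the measure-comparison table.  The gold axis is treated as an
opaque monotone score — all rank/linear correlation requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .baselines import MEASURES
from .core import Histogram

__all__ = ["GoldJudgment", "correlate_with_gold", "measure_comparison"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GoldJudgment:
    """Mean perceived-polarization judgment for one histogram, in [0, 100]."""

    histogram_id: str
    gold: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.gold <= 100.0:
            raise ValueError(f"gold judgment {self.gold} outside [0, 100]")


def _gold_map(gold: Iterable[GoldJudgment] | Mapping[str, float]) -> dict[str, float]:
    if isinstance(gold, Mapping):
        return {str(k): float(v) for k, v in gold.items()}
    return {g.histogram_id: g.gold for g in gold}


def correlate_with_gold(scores: Mapping[str, float],
                        gold: Iterable[GoldJudgment] | Mapping[str, float],
                        method: str = "spearman") -> float:
    """Spearman's rho or Pearson's r between a measure and gold judgments.

    Only the ids present on both sides are used (a warning names how
    many were dropped).  Spearman uses average ranks for ties.

    Raises
    ------
    ValueError
        With fewer than 3 matched pairs, or when either variable is
        constant (undefined correlation).
    """
    gold_map = _gold_map(gold)
    ids = sorted(set(scores) & set(gold_map))
    dropped = (len(scores) - len(ids)) + (len(gold_map) - len(ids))
    if dropped:
        log.warning("%d unmatched histogram id(s); using the %d-id intersection",
                    dropped, len(ids))
    if len(ids) < 3:
        raise ValueError(f"need >= 3 matched pairs, have {len(ids)}")
    x = np.array([scores[i] for i in ids], dtype=float)
    y = np.array([gold_map[i] for i in ids], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant input")
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}; use 'spearman' or 'pearson'")


def measure_comparison(histograms: Mapping[str, Histogram | Sequence[float]],
                       gold: Iterable[GoldJudgment] | Mapping[str, float],
                       measures: Sequence[str] = ("dfu", "std", "leik", "d2", "kurtosis"),
                       ) -> pd.DataFrame:
    """One row per measure with its Spearman and Pearson against gold.

    Duplicate measure names are deduplicated (warned).  Baselines that
    track gold inversely keep their signed coefficients — a negative
    value is meaningful output, not an error.
    """
    seen: list[str] = []
    for m in measures:
        if m in seen:
            log.warning("duplicate measure %r requested; keeping one", m)
        else:
            seen.append(m)
    rows = []
    for name in seen:
        if name not in MEASURES:
            raise KeyError(f"unknown measure {name!r}; choose from {sorted(MEASURES)}")
        fn = MEASURES[name]
        scores = {hid: float(fn(h)) for hid, h in histograms.items()}
        rows.append((
            name,
            correlate_with_gold(scores, gold, "spearman"),
            correlate_with_gold(scores, gold, "pearson"),
        ))
    return pd.DataFrame(rows, columns=["measure", "spearman", "pearson"])
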