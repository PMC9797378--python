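"""Per-cluster polarization of continuous sentiment scores.

Valence scores in [0, 1] are discretized into a 3-class ordinal scale
(negative < neutral < positive) with the thresholds of the sentiment
benchmark the scores come from: positive above 0.61, negative below
0.43, neutral otherwise.  Scores are grouped by a cluster key — usually
(date, region) — and each cluster's DFU is computed; a cluster with
DFU > 0 is flagged as a polarization peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import pandas as pd

from .core import Histogram, OrdinalScale, build_histogram, dfu

__all__ = [
    "SENTIMENT_SCALE",
    "POS_THRESHOLD",
    "NEG_THRESHOLD",
    "ScoredItem",
    "discretize_sentiment",
    "cluster_polarization",
    "daily_mean_sentiment",
]

SENTIMENT_SCALE = OrdinalScale(("negative", "neutral", "positive"))

#: default valence thresholds: > 0.61 positive, < 0.43 negative
POS_THRESHOLD = 0.61
NEG_THRESHOLD = 0.43


@dataclass(frozen=True)
class ScoredItem:
    """A continuous sentiment score in [0, 1] with its cluster key."""

    item_id: str
    score: float
    cluster_key: tuple

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
        if not self.cluster_key:
            raise ValueError("cluster_key must be non-empty")


def discretize_sentiment(score: float,
                         pos_threshold: float = POS_THRESHOLD,
                         neg_threshold: float = NEG_THRESHOLD) -> str:
    """Map a valence score to negative / neutral / positive.

    Strict inequalities: a score exactly at either threshold is neutral.
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    if neg_threshold >= pos_threshold:
        raise ValueError("neg_threshold must be below pos_threshold")
    if score > pos_threshold:
        return "positive"
    if score < neg_threshold:
        return "negative"
    return "neutral"


def _to_frame(items: Iterable[ScoredItem] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(items, pd.DataFrame):
        df = items.copy()
        if "cluster_key" not in df.columns:
            key_cols = [c for c in ("date", "region") if c in df.columns]
            if not key_cols:
                raise ValueError("need a cluster_key column or date/region columns")
            df["cluster_key"] = list(zip(*(df[c] for c in key_cols)))
        return df
    rows = [(it.item_id, it.score, it.cluster_key) for it in items]
    return pd.DataFrame(rows, columns=["item_id", "score", "cluster_key"])


def cluster_polarization(items: Iterable[ScoredItem] | pd.DataFrame,
                         pos_threshold: float = POS_THRESHOLD,
                         neg_threshold: float = NEG_THRESHOLD,
                         peak_threshold: float = 0.0) -> pd.DataFrame:
    """Per-cluster 3-class histogram, DFU and peak flag.

    Returns a DataFrame sorted by cluster key with columns
    ``cluster_key, n, f_neg, f_neu, f_pos, dfu, peak``; its ``attrs``
    carry summary counts of unimodal (DFU = 0) and peak clusters.  A
    peak is a cluster with DFU strictly above ``peak_threshold``
    (default 0, i.e. any departure from unimodality).
    """
    df = _to_frame(items)
    if df.empty:
        raise ValueError("no scored items")
    bad = ~df["score"].between(0.0, 1.0)
    if bad.any():
        raise ValueError(f"score {df.loc[bad, 'score'].iloc[0]} outside [0, 1]")
    df["cls"] = [discretize_sentiment(s, pos_threshold, neg_threshold)
                 for s in df["score"]]

    rows = []
    for key, grp in sorted(df.groupby("cluster_key", sort=False),
                           key=lambda kv: kv[0]):
        h = build_histogram(grp["cls"].tolist(), SENTIMENT_SCALE)
        score = float(dfu(h))
        rows.append((key, len(grp), *h.freqs, score, score > peak_threshold))
    out = pd.DataFrame(
        rows, columns=["cluster_key", "n", "f_neg", "f_neu", "f_pos", "dfu", "peak"]
    )
    out.attrs["n_items"] = int(out["n"].sum())
    out.attrs["n_unimodal"] = int((out["dfu"] == 0.0).sum())
    out.attrs["n_peaks"] = int(out["peak"].sum())
    return out


def daily_mean_sentiment(items: Iterable[ScoredItem] | pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of the raw (un-discretized) scores per cluster."""
    df = _to_frame(items)
    if df.empty:
        raise ValueError("no scored items")
    out = (df.groupby("cluster_key", sort=False)["score"].mean()
           .reset_index(name="mean_score"))
    return out.sort_values("cluster_key", key=lambda s: s.map(tuple),
                           ignore_index=True)
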