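"""Per-item polarization from multi-rater ordinal annotations.

Aggregates raw annotation records (item, rater, ordinal label, optional
rater country) into per-item histograms and DFU scores, and runs the
country-diversity resampling comparison between high- and low-DFU items.
A synthetic-corpus generator provides seed-reproducible test inputs with
a controllable share of polarized items and an optional dependence of
rater-country diversity on polarization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Histogram, OrdinalScale, build_histogram, dfu

__all__ = [
    "AnnotationRecord",
    "TOXICITY_SCALE",
    "ResamplingResult",
    "aggregate_annotations",
    "country_diversity_resampling",
    "generate_synthetic_annotations",
    "records_to_frame",
]

log = logging.getLogger(__name__)

#: Default 4-level toxicity scale.  "hard to say" is placed between
#: "not toxic" and "toxic" as a middle judgment; the scale is
#: configuration, not a hard-coded assumption, so pass your own
#: OrdinalScale wherever the ordering should differ.
TOXICITY_SCALE = OrdinalScale(("not toxic", "hard to say", "toxic", "very toxic"))


@dataclass(frozen=True)
class AnnotationRecord:
    """One rater's ordinal label on one item."""

    item_id: str
    rater_id: str
    label: str
    country: Optional[str] = None


def records_to_frame(records: Iterable[AnnotationRecord]) -> pd.DataFrame:
    rows = [(r.item_id, r.rater_id, r.label, r.country) for r in records]
    return pd.DataFrame(rows, columns=["item_id", "rater_id", "label", "country"])


def aggregate_annotations(records: Iterable[AnnotationRecord] | pd.DataFrame,
                          scale: OrdinalScale) -> pd.DataFrame:
    """One row per item: rater count, histogram, DFU, distinct countries.

    Returns a DataFrame with columns ``item_id``, ``n_raters``,
    ``f1..fK`` (relative frequencies along the scale), ``dfu`` and
    ``n_countries`` (distinct non-missing rater countries).  Duplicate
    (item_id, rater_id) pairs are legal but logged as a warning.

    Raises
    ------
    ValueError
        On empty input, or on a label outside the scale (the item and
        label are named).
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise ValueError("no annotation records to aggregate")
    dup = df.duplicated(subset=["item_id", "rater_id"])
    if dup.any():
        log.warning("%d duplicate (item_id, rater_id) pairs in input", int(dup.sum()))

    bad = ~df["label"].isin(scale.labels)
    if bad.any():
        first = df[bad].iloc[0]
        raise ValueError(
            f"item {first['item_id']!r}: label {first['label']!r} is not on "
            f"the scale {list(scale.labels)}"
        )

    rows = []
    for item_id, grp in df.groupby("item_id", sort=True):
        h = build_histogram(grp["label"].tolist(), scale)
        countries = grp["country"].dropna()
        countries = countries[countries != ""]
        rows.append(
            (item_id, len(grp), *h.freqs, float(dfu(h)), countries.nunique())
        )
    fcols = [f"f{i}" for i in range(1, scale.k + 1)]
    return pd.DataFrame(
        rows, columns=["item_id", "n_raters", *fcols, "dfu", "n_countries"]
    )


@dataclass(frozen=True)
class ResamplingResult:
    """Outcome of the high- vs low-DFU country-diversity comparison.

    ``successes`` counts the repetitions in which the mean distinct-
    country count of the high-DFU sample strictly exceeded the low-DFU
    sample's; ``p_value`` is a one-sided sign test over repetitions
    (supporting, not replacing, the success count).
    """

    repetitions: int
    successes: int
    mean_high: float
    mean_low: float
    p_value: float
    sample_size: int
    seed: int

    def __post_init__(self) -> None:
        if not 0 <= self.successes <= self.repetitions:
            raise ValueError("successes out of range")


def country_diversity_resampling(table: pd.DataFrame,
                                 quantile: float = 0.75,
                                 sample_size: int = 1000,
                                 repetitions: int = 100,
                                 seed: int = 0) -> ResamplingResult:
    """Compare rater-country diversity between high- and low-DFU items.

    The items are split at the ``quantile``-th quantile of their DFU
    scores (ties at the quantile fall on the low side).  Each repetition
    draws, without replacement, ``sample_size`` items from each side and
    compares their mean distinct-country counts; a repetition is a
    success when the high side's mean is strictly larger.  If either
    side holds fewer than ``sample_size`` items the sample size is
    lowered to the smaller side's size (logged).

    Raises
    ------
    ValueError
        When every DFU value is identical (degenerate quantile split).
    """
    dfu_vals = table["dfu"].to_numpy(float)
    countries = table["n_countries"].to_numpy(float)
    q = float(np.quantile(dfu_vals, quantile))
    high = np.flatnonzero(dfu_vals > q)
    low = np.flatnonzero(dfu_vals <= q)
    if len(high) == 0 or len(low) == 0:
        raise ValueError("degenerate quantile split: all DFU values identical")

    avail = min(len(high), len(low))
    if sample_size > avail:
        log.warning("sample_size %d exceeds the smaller side (%d); clamped",
                    sample_size, avail)
        sample_size = avail

    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(seed).spawn(repetitions)]
    successes = 0
    means_high = np.empty(repetitions)
    means_low = np.empty(repetitions)
    for r, rng in enumerate(streams):
        hi = rng.choice(high, size=sample_size, replace=False)
        lo = rng.choice(low, size=sample_size, replace=False)
        means_high[r] = countries[hi].mean()
        means_low[r] = countries[lo].mean()
        if means_high[r] > means_low[r]:
            successes += 1
    p = float(stats.binomtest(successes, repetitions, 0.5,
                              alternative="greater").pvalue)
    return ResamplingResult(
        repetitions=repetitions,
        successes=successes,
        mean_high=float(means_high.mean()),
        mean_low=float(means_low.mean()),
        p_value=p,
        sample_size=sample_size,
        seed=seed,
    )


# country pools for the synthetic corpus; polarized items draw from the
# wide pool when the country effect is on
_POOL_NARROW = ["US", "GB", "CA"]
_POOL_BASE = ["US", "GB", "CA", "AU", "IE", "NZ"]
_POOL_WIDE = _POOL_BASE + ["IN", "DE", "FR", "BR", "PH", "ZA"]


def _unimodal_arrangement(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rearrange bin counts into a guaranteed-unimodal ordering.

    Sorting the counts and placing them center-out yields a histogram
    that rises to a single mode and falls after it, whatever the drawn
    counts were.
    """
    k = len(counts)
    order = np.sort(counts)[::-1]
    out = np.zeros(k, dtype=counts.dtype)
    center = int(rng.integers(0, k))
    positions = sorted(range(k), key=lambda i: (abs(i - center), i))
    for pos, c in zip(positions, order):
        out[pos] = c
    return out


def generate_synthetic_annotations(n_items: int,
                                   raters_per_item: int,
                                   polarized_fraction: float,
                                   country_effect: bool = False,
                                   scale: OrdinalScale = TOXICITY_SCALE,
                                   seed: int = 0) -> list[AnnotationRecord]:
    """Seed-reproducible synthetic multi-rater annotation corpus.

    A ``polarized_fraction`` share of items receives labels split
    between the two extreme categories with at least one rater at each
    extreme, so their histograms are bimodal and DFU > 0 by
    construction.  The remaining items receive labels arranged into a
    unimodal histogram, so DFU = 0 by construction.  With
    ``country_effect`` on, raters of polarized items are drawn from a
    wider country pool than raters of unpolarized items, inducing the
    diversity difference the resampling analysis is designed to detect;
    off, all raters share one pool and no dependence exists.
    """
    if n_items < 1:
        raise ValueError(f"n_items must be >= 1, got {n_items}")
    if raters_per_item < 2:
        raise ValueError(f"raters_per_item must be >= 2, got {raters_per_item}")
    if not 0.0 <= polarized_fraction <= 1.0:
        raise ValueError(f"polarized_fraction must be in [0, 1], got {polarized_fraction}")

    rng = np.random.default_rng(seed)
    k = scale.k
    lo_label, hi_label = scale.labels[0], scale.labels[-1]
    n_polarized = int(round(n_items * polarized_fraction))
    polarized = np.zeros(n_items, dtype=bool)
    polarized[rng.choice(n_items, size=n_polarized, replace=False)] = True

    records: list[AnnotationRecord] = []
    for j in range(n_items):
        item_id = f"item{j:05d}"
        if polarized[j]:
            # one rater forced to each extreme; the rest split at random
            labels = [lo_label, hi_label] + [
                lo_label if rng.random() < 0.5 else hi_label
                for _ in range(raters_per_item - 2)
            ]
            rng.shuffle(labels)
            pool = _POOL_WIDE if country_effect else _POOL_BASE
        else:
            counts = rng.multinomial(raters_per_item, np.full(k, 1.0 / k))
            counts = _unimodal_arrangement(counts, rng)
            labels = [lab for lab, c in zip(scale.labels, counts) for _ in range(c)]
            rng.shuffle(labels)
            pool = _POOL_NARROW if country_effect else _POOL_BASE
        for r, lab in enumerate(labels):
            records.append(AnnotationRecord(
                item_id=item_id,
                rater_id=f"{item_id}.r{r}",
                label=lab,
                country=str(rng.choice(pool)),
            ))
    return records
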