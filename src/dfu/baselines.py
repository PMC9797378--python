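"""Dispersion-style polarization baselines for ordinal histograms.

These are the conventional measures DFU is compared against: standard
deviation of the encoded ratings, Leik's ordinal consensus D, the d^2
dispersion index, and kurtosis as a peakedness proxy.  All operate on a
:class:`~dfu.core.Histogram` with categories encoded as the integer
positions 1..K and treat the histogram as the full population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .core import Histogram, as_histogram, dfu

__all__ = [
    "CumulativeHistogram",
    "cumulative",
    "stdev_dispersion",
    "leik_ordinal_dispersion",
    "d2_dispersion",
    "kurtosis_peakedness",
    "MEASURES",
    "compute_measures",
]


@dataclass(frozen=True)
class CumulativeHistogram:
    """Cumulative relative frequencies F_1 <= ... <= F_K = 1."""

    cum: tuple[float, ...]

    def __post_init__(self) -> None:
        c = self.cum
        if any(c[i] > c[i + 1] + 1e-12 for i in range(len(c) - 1)):
            raise ValueError("cumulative frequencies must be non-decreasing")
        if abs(c[-1] - 1.0) > 1e-9:
            raise ValueError(f"F_K = {c[-1]!r}, expected 1")


def cumulative(h: Histogram | Sequence[float]) -> CumulativeHistogram:
    h = as_histogram(h)
    return CumulativeHistogram(tuple(np.cumsum(h.freqs).tolist()))


def _positions_mean_var(h: Histogram) -> tuple[np.ndarray, float, float]:
    x = np.arange(1, h.k + 1, dtype=float)
    w = np.asarray(h.freqs)
    mu = float(x @ w)
    var = float(((x - mu) ** 2) @ w)
    return x, mu, var


def stdev_dispersion(h: Histogram | Sequence[float]) -> float:
    """Population standard deviation of the ratings encoded as 1..K."""
    h = as_histogram(h)
    _, _, var = _positions_mean_var(h)
    return float(np.sqrt(var))


def leik_ordinal_dispersion(h: Histogram | Sequence[float]) -> float:
    """Leik's ordinal consensus D.

    D = 2 * sum_i(d_i) / (K - 1) with d_i = F_i when F_i < 0.5 and
    1 - F_i otherwise.  0 means full consensus (all mass in one
    category); 1 means a 50/50 split between the two extreme categories.
    """
    h = as_histogram(h)
    if h.k < 2:
        raise ValueError("Leik's D is undefined for a single-category scale")
    F = np.cumsum(h.freqs)
    d = np.where(F < 0.5, F, 1.0 - F)
    return float(2.0 * d.sum() / (h.k - 1))


def d2_dispersion(h: Histogram | Sequence[float], *, absolute: bool = False) -> float:
    """The d^2 dispersion index: sum_{i=1}^{K-1} (F_i - 0.5).

    Implemented literally, so the value may be negative.  ``absolute``
    switches to sum_{i} |F_i - 0.5| for users who suspect the plain form
    drops an absolute value; it is never used by default.
    """
    h = as_histogram(h)
    F = np.cumsum(h.freqs)[:-1]
    dev = np.abs(F - 0.5) if absolute else (F - 0.5)
    return float(dev.sum())


def kurtosis_peakedness(h: Histogram | Sequence[float], *, fisher: bool = False) -> float:
    """Kurtosis of the ratings encoded as 1..K, weighted by frequency.

    Pearson convention by default (normal = 3); ``fisher=True``
    subtracts 3.  Only the correlation of peakedness with judgments is
    of interest, so the convention does not change any conclusion.

    Raises
    ------
    ValueError
        For a degenerate (single-category) histogram, whose variance is
        zero.
    """
    h = as_histogram(h)
    x, mu, var = _positions_mean_var(h)
    if var <= 0:
        raise ValueError(
            "kurtosis undefined for a degenerate (single-category) histogram"
        )
    w = np.asarray(h.freqs)
    m4 = float(((x - mu) ** 4) @ w)
    k = m4 / var**2
    return k - 3.0 if fisher else k


#: name -> callable registry used by the comparison table and the CLI
MEASURES: dict[str, Callable[[Histogram], float]] = {
    "dfu": lambda h: float(dfu(h)),
    "std": stdev_dispersion,
    "leik": leik_ordinal_dispersion,
    "d2": d2_dispersion,
    "kurtosis": kurtosis_peakedness,
}


def compute_measures(h: Histogram | Sequence[float],
                     measures: Iterable[str] = ("dfu", "std", "leik", "d2", "kurtosis"),
                     ) -> dict[str, float]:
    """Evaluate a set of named measures on one histogram."""
    h = as_histogram(h)
    out: dict[str, float] = {}
    for name in measures:
        if name not in MEASURES:
            raise KeyError(f"unknown measure {name!r}; choose from {sorted(MEASURES)}")
        out[name] = MEASURES[name](h)
    return out
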