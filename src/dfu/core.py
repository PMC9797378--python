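"""Distance from unimodality (DFU) for discrete ordinal histograms.

A histogram ``f = (f_1, ..., f_K)`` over an ordered rating scale is
*unimodal* when there is a mode position ``m`` such that frequencies are
non-decreasing up to ``m`` and non-increasing after it.  DFU measures the
largest adjacent-bin violation of that monotonicity rule: for the mode
``m`` the difference values are

    d_i = f_i - f_{i-1}   for i > m   (should be <= 0)
    d_i = f_i - f_{i+1}   for i < m   (should be <= 0)
    d_m = 0

and ``DFU = max(d)``.  Unimodal histograms — including the uniform one —
score exactly 0; any positive score flags a second cluster of opinions,
i.e. polarization.

When the maximum frequency is attained at several positions, each tied
position is evaluated as the mode and the smallest of the resulting
maxima is reported.  This is the most charitable reading towards
unimodality and guarantees that plateau-topped unimodal histograms score
0; on histograms without ties it coincides with the leftmost-argmax
convention.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "OrdinalScale",
    "Histogram",
    "DifferenceVector",
    "DfuScore",
    "build_histogram",
    "difference_vector",
    "dfu",
    "is_unimodal",
]

#: tolerance for the frequencies-sum-to-one invariant
FREQ_SUM_TOL = 1e-9


@dataclass(frozen=True)
class OrdinalScale:
    """A finite, totally ordered set of rating categories.

    Parameters
    ----------
    labels
        Category names in increasing order, e.g.
        ``("negative", "neutral", "positive")``.
    """

    labels: tuple[str, ...]

    def __init__(self, labels: Iterable[str]) -> None:
        object.__setattr__(self, "labels", tuple(labels))
        if len(self.labels) < 2:
            raise ValueError("an ordinal scale needs at least 2 categories")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"duplicate category names in scale: {self.labels}")

    @property
    def k(self) -> int:
        """Number of categories K."""
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(
                f"label {label!r} is not on the scale {list(self.labels)}"
            ) from None

    def __len__(self) -> int:
        return self.k

    def __iter__(self):
        return iter(self.labels)


@dataclass(frozen=True)
class Histogram:
    """Relative frequencies of the K ratings of an ordinal scale.

    ``freqs`` must be non-negative and sum to 1 (within 1e-9); its length
    must equal the number of categories of ``scale``.
    """

    freqs: tuple[float, ...]
    scale: OrdinalScale

    def __init__(self, freqs: Iterable[float], scale: OrdinalScale) -> None:
        f = tuple(float(x) for x in freqs)
        if len(f) != scale.k:
            raise ValueError(
                f"histogram has {len(f)} frequencies but the scale has "
                f"{scale.k} categories"
            )
        if any(x < 0 for x in f):
            raise ValueError(f"negative frequency in {f}")
        total = sum(f)
        if abs(total - 1.0) > FREQ_SUM_TOL:
            raise ValueError(f"frequencies sum to {total!r}, expected 1")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "scale", scale)

    @classmethod
    def from_counts(cls, counts: Iterable[float], scale: OrdinalScale) -> "Histogram":
        """Build a histogram from raw (non-negative) counts."""
        c = np.asarray(list(counts), dtype=float)
        if c.ndim != 1 or len(c) != scale.k:
            raise ValueError(f"expected {scale.k} counts, got {c.tolist()}")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        total = c.sum()
        if total <= 0:
            raise ValueError("counts sum to zero; cannot normalise")
        return cls(c / total, scale)

    @property
    def k(self) -> int:
        return self.scale.k

    def reversed(self) -> "Histogram":
        """The histogram read on the reversed scale (for symmetry checks)."""
        return Histogram(self.freqs[::-1], OrdinalScale(self.scale.labels[::-1]))


def _generic_scale(k: int) -> OrdinalScale:
    return OrdinalScale(tuple(f"O{i}" for i in range(1, k + 1)))


def as_histogram(freqs: Sequence[float] | Histogram,
                 scale: OrdinalScale | None = None) -> Histogram:
    """Coerce a bare frequency sequence into a Histogram.

    Convenience for callers that work with plain vectors; a generic
    scale ``O1 < ... < OK`` is attached when none is given.
    """
    if isinstance(freqs, Histogram):
        return freqs
    seq = list(freqs)
    return Histogram(seq, scale or _generic_scale(len(seq)))


def _weights(h: "Histogram | Sequence[float]") -> tuple[float, ...]:
    """Frequencies of a Histogram, or a bare non-negative weight vector.

    The unimodality rule and the d-vector only compare adjacent bins, so
    the functional API also accepts unnormalised weights; the strict
    sum-to-one invariant is enforced only when a Histogram is built.
    """
    if isinstance(h, Histogram):
        return h.freqs
    w = tuple(float(x) for x in h)
    if len(w) < 2:
        raise ValueError("need at least 2 bins")
    if any(x < 0 for x in w):
        raise ValueError(f"negative weight in {w}")
    return w


@dataclass(frozen=True)
class DifferenceVector:
    """Adjacent-bin differences around a chosen mode position.

    ``mode_index`` is 0-based; ``diffs`` has one entry per category, the
    entry at the mode being exactly 0 and every entry lying in [-1, 1].
    """

    mode_index: int
    diffs: tuple[float, ...]

    def max(self) -> float:
        return max(self.diffs)


@dataclass(frozen=True)
class DfuScore:
    """A DFU value: a real in [0, 1], 0 iff the histogram is unimodal."""

    value: float
    mode_index: int = field(default=0, compare=False)

    def __float__(self) -> float:
        return self.value

    def __round__(self, ndigits: int | None = None):
        return round(self.value, ndigits)


def build_histogram(labels: Iterable[str], scale: OrdinalScale) -> Histogram:
    """Count ordinal labels into relative frequencies along the scale.

    Raises
    ------
    ValueError
        If ``labels`` is empty or contains a label not on the scale
        (the offending label is named).
    """
    labels = list(labels)
    if not labels:
        raise ValueError("cannot build a histogram from zero labels")
    counts = Counter(labels)
    unknown = set(counts) - set(scale.labels)
    if unknown:
        raise ValueError(
            f"unknown label(s) {sorted(unknown)} for scale {list(scale.labels)}"
        )
    n = len(labels)
    return Histogram((counts.get(lab, 0) / n for lab in scale.labels), scale)


def _diffs_for_mode(f: Sequence[float], m: int) -> tuple[float, ...]:
    """d_i for mode position m (0-based), over every position."""
    k = len(f)
    d = [0.0] * k
    for i in range(m + 1, k):  # right of the mode: f_i - f_{i-1}
        d[i] = f[i] - f[i - 1]
    for i in range(m):  # left of the mode: f_i - f_{i+1}
        d[i] = f[i] - f[i + 1]
    return tuple(d)


def _tied_modes(f: Sequence[float]) -> list[int]:
    fmax = max(f)
    return [i for i, x in enumerate(f) if x == fmax]


def difference_vector(h: Histogram | Sequence[float],
                      mode_index: int | None = None) -> DifferenceVector:
    """The d-vector of the histogram for a given (default: leftmost) mode.

    Every position other than the mode carries a difference; a positive
    entry marks a violation of the monotone-around-the-mode rule.
    """
    f = _weights(h)
    m = _tied_modes(f)[0] if mode_index is None else mode_index
    if not 0 <= m < len(f):
        raise ValueError(f"mode_index {m} out of range for K={len(f)}")
    return DifferenceVector(mode_index=m, diffs=_diffs_for_mode(f, m))


def dfu(h: Histogram | Sequence[float]) -> DfuScore:
    """Distance from unimodality of an ordinal histogram.

    Returns the largest positive adjacent-bin deviation from the
    unimodality rule (0 for unimodal and uniform histograms).  Tied
    maxima are resolved by taking, over all tied mode positions, the
    minimum of the maximal deviation.
    """
    f = _weights(h)
    best_m = -1
    best = np.inf
    for m in _tied_modes(f):
        dev = max(_diffs_for_mode(f, m))
        if dev < best:
            best, best_m = dev, m
    # d_m = 0 is always present so max(d) >= 0 analytically; the clamp
    # only guards against float residue like -1e-17
    return DfuScore(value=max(0.0, best), mode_index=best_m)


def is_unimodal(h: Histogram | Sequence[float]) -> bool:
    """Exact unimodality check by brute force over every mode position.

    True iff some position m has frequencies non-decreasing up to m and
    non-increasing after it.  Uniform histograms are unimodal.
    """
    f = _weights(h)
    k = len(f)
    for m in range(k):
        if all(f[i] <= f[i + 1] for i in range(m)) and all(
            f[i + 1] <= f[i] for i in range(m, k - 1)
        ):
            return True
    return False
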