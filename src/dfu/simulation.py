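"""Gaussian-mixture simulation of opinion score distributions.

Draws samples from a (possibly multi-component) normal mixture and bins
them into an ordinal histogram, emulating the classic demonstration that
a unimodal score distribution yields DFU = 0 while well-separated
mixtures yield positive DFU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import Histogram, OrdinalScale

__all__ = ["MixtureComponent", "MixtureSpec", "sample_mixture",
           "mixture_histogram", "preset", "PRESETS"]


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    mean: float
    std: float


@dataclass(frozen=True)
class MixtureSpec:
    """A normal mixture plus sampling/binning parameters.

    Component weights must sum to 1 (within 1e-9), stds must be
    positive, ``n >= 1`` draws, ``bins >= 2`` equal-width ordinal bins.
    """

    components: tuple[MixtureComponent, ...]
    n: int = 10_000
    bins: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        comps = tuple(
            c if isinstance(c, MixtureComponent) else MixtureComponent(*c)
            for c in self.components
        )
        object.__setattr__(self, "components", comps)
        if not comps:
            raise ValueError("components: need at least one mixture component")
        wsum = sum(c.weight for c in comps)
        if abs(wsum - 1.0) > 1e-9:
            raise ValueError(f"components: weights sum to {wsum!r}, expected 1")
        if any(c.weight < 0 for c in comps):
            raise ValueError("components: negative weight")
        if any(c.std <= 0 for c in comps):
            raise ValueError("components: every std must be > 0")
        if self.n < 1:
            raise ValueError(f"n: must be >= 1, got {self.n}")
        if self.bins < 2:
            raise ValueError(f"bins: must be >= 2, got {self.bins}")


def sample_mixture(spec: MixtureSpec) -> np.ndarray:
    """Draw ``spec.n`` values: component by weight, then a normal draw.

    Fully reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    weights = np.array([c.weight for c in spec.components])
    means = np.array([c.mean for c in spec.components])
    stds = np.array([c.std for c in spec.components])
    which = rng.choice(len(weights), size=spec.n, p=weights)
    return rng.normal(means[which], stds[which])


def mixture_histogram(spec: MixtureSpec,
                      range_: tuple[float, float] | None = None) -> Histogram:
    """Equal-width ordinal histogram of a mixture sample.

    Bins span the sample range by default (right-open bins, last bin
    closed — numpy's histogram semantics); pass ``range_`` for a fixed
    span when cross-run comparability matters.

    Raises
    ------
    ValueError
        If all samples are identical (zero-width range).
    """
    x = sample_mixture(spec)
    lo, hi = range_ if range_ is not None else (x.min(), x.max())
    if hi <= lo:
        raise ValueError("zero-width range: all samples identical")
    counts, _ = np.histogram(x, bins=spec.bins, range=(lo, hi))
    scale = OrdinalScale(tuple(f"bin{i}" for i in range(1, spec.bins + 1)))
    return Histogram.from_counts(counts, scale)


def _c(w: float, mean: float, std: float) -> MixtureComponent:
    return MixtureComponent(w, mean, std)


#: Named mixture presets.  `fig1a` is the unimodal unit normal; `fig1b`
#: mixes two normals with stds 3 and 10; `fig1c` mixes three normals
#: with stds 5, 5 and 10.  Component means and weights are this
#: package's own choices (picked to separate the modes clearly), not
#: fixed by any external reference.
PRESETS: dict[str, tuple[MixtureComponent, ...]] = {
    "fig1a": (_c(1.0, 0.0, 1.0),),
    "fig1b": (_c(0.5, -20.0, 3.0), _c(0.5, 20.0, 10.0)),
    "fig1c": (_c(1 / 3, -40.0, 5.0), _c(1 / 3, 0.0, 5.0), _c(1 / 3, 45.0, 10.0)),
}


def preset(name: str, n: int = 10_000, bins: int = 10, seed: int = 0) -> MixtureSpec:
    """Build a MixtureSpec from a named preset."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return MixtureSpec(components=PRESETS[name], n=n, bins=bins, seed=seed)
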