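"""Core DFU statistic: examples, exact oracle, and invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dfu.core import (
    Histogram,
    OrdinalScale,
    as_histogram,
    build_histogram,
    difference_vector,
    dfu,
    is_unimodal,
)

SENT3 = OrdinalScale(("neg", "neu", "pos"))
TOX4 = OrdinalScale(("not toxic", "hard to say", "toxic", "very toxic"))


def simplex(draw_k=st.integers(2, 8)):
    """Random relative-frequency vectors (normalised, any K in 2..8)."""
    return draw_k.flatmap(
        lambda k: st.lists(st.floats(0.0, 1.0), min_size=k, max_size=k)
    ).map(lambda w: (np.asarray(w) / s if (s := sum(w)) > 0 else
                     np.full(len(w), 1 / len(w))).tolist())


class TestOrdinalScale:
    def test_requires_two_unique_ordered_labels(self):
        with pytest.raises(ValueError):
            OrdinalScale(("only",))
        with pytest.raises(ValueError):
            OrdinalScale(("a", "a"))
        assert SENT3.k == 3
        assert SENT3.index("neu") == 1
        with pytest.raises(KeyError):
            SENT3.index("meh")


class TestHistogram:
    def test_rejects_wrong_length_negative_or_unnormalised(self):
        with pytest.raises(ValueError):
            Histogram([0.5, 0.5], SENT3)
        with pytest.raises(ValueError):
            Histogram([-0.1, 0.6, 0.5], SENT3)
        with pytest.raises(ValueError):
            Histogram([0.2, 0.2, 0.2], SENT3)

    def test_from_counts_normalises(self):
        h = Histogram.from_counts([2, 0, 2], SENT3)
        assert h.freqs == (0.5, 0.0, 0.5)
        with pytest.raises(ValueError):
            Histogram.from_counts([0, 0, 0], SENT3)


class TestBuildHistogram:
    @pytest.mark.parametrize(
        "labels, scale, expected",
        [
            (["neg", "neg", "pos", "pos"], SENT3, (0.5, 0.0, 0.5)),
            (["neu"], SENT3, (0.0, 1.0, 0.0)),
            (
                ["not toxic"] * 4 + ["toxic"] * 4,
                TOX4,
                (0.5, 0.0, 0.5, 0.0),
            ),
        ],
    )
    def test_counts_along_the_scale(self, labels, scale, expected):
        assert build_histogram(labels, scale).freqs == expected

    def test_unknown_label_named_in_error(self):
        with pytest.raises(ValueError, match="meh"):
            build_histogram(["neg", "meh"], SENT3)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_histogram([], SENT3)


class TestDifferenceVector:
    def test_unimodal_all_diffs_nonpositive(self):
        dv = difference_vector([0.2, 0.5, 0.3])
        assert dv.mode_index == 1
        assert dv.diffs == (-0.3, 0.0, -0.2)

    def test_leftmost_tie_default_mode(self):
        dv = difference_vector([0.5, 0.0, 0.5])
        assert dv.mode_index == 0
        assert dv.diffs[2] == pytest.approx(0.5)

    def test_uniform_all_zero(self):
        for k in range(2, 9):
            assert all(d == 0 for d in difference_vector([1 / k] * k).diffs)

    def test_mode_entry_is_zero_and_bounded(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            f = rng.dirichlet(np.ones(rng.integers(2, 9))).tolist()
            dv = difference_vector(f)
            assert dv.diffs[dv.mode_index] == 0.0
            assert all(-1.0 <= d <= 1.0 for d in dv.diffs)


class TestDfuExamples:
    @pytest.mark.parametrize(
        "freqs, expected",
        [
            ((0.1, 0.2, 0.4, 0.2, 0.1), 0.0),  # strictly unimodal
            ((0.25, 0.25, 0.25, 0.25), 0.0),  # uniform
            ((0.5, 0.0, 0.5), 0.5),  # extreme two-cluster split
            ((0.4, 0.1, 0.4, 0.35), 0.3),  # raw weights, tied maxima
            ((0.2, 0.5, 0.3), 0.0),
        ],
    )
    def test_hand_derived_values(self, freqs, expected):
        assert float(dfu(freqs)) == pytest.approx(expected, abs=1e-12)

    def test_accepts_histogram_objects(self):
        h = Histogram((0.5, 0.0, 0.5), SENT3)
        assert float(dfu(h)) == 0.5
        assert round(dfu(h), 2) == 0.5


class TestIsUnimodal:
    @pytest.mark.parametrize(
        "freqs, expected",
        [
            ((0.1, 0.3, 0.3, 0.2), True),  # plateau at the mode
            ((0.4, 0.1, 0.5), False),  # interior valley
            ((0.25, 0.25, 0.25, 0.25), True),  # uniform is unimodal
            ((1.0, 0.0), True),
        ],
    )
    def test_examples(self, freqs, expected):
        assert is_unimodal(freqs) is expected


def _count_grids(step_parts: int, k: int):
    """All integer compositions of `step_parts` into k non-negative bins."""
    for cuts in itertools.combinations_with_replacement(range(step_parts + 1), k - 1):
        parts = []
        prev = 0
        for c in cuts:
            parts.append(c - prev)
            prev = c
        parts.append(step_parts - prev)
        yield tuple(parts)


class TestOracleEquivalence:
    """dfu(h) = 0 exactly when the brute-force unimodality oracle says so."""

    @pytest.mark.parametrize("k", range(2, 9))
    def test_exhaustive_grid(self, k):
        # 0.05-frequency grid == integer counts summing to 20; DFU's sign
        # is invariant under rescaling, so counts are checked directly
        mismatches = [
            f
            for f in _count_grids(20, k)
            if (float(dfu(f)) == 0.0) is not is_unimodal(f)
        ]
        assert mismatches == []


class TestDfuProperties:
    @given(simplex())
    @settings(max_examples=200, deadline=None)
    def test_reversal_symmetry(self, f):
        assert float(dfu(f[::-1])) == pytest.approx(float(dfu(f)), abs=1e-12)

    @given(simplex())
    @settings(max_examples=200, deadline=None)
    def test_bounded_by_max_frequency(self, f):
        v = float(dfu(f))
        assert 0.0 <= v <= max(f) + 1e-12 <= 1.0 + 1e-12

    def test_tie_rule_min_over_tied_modes(self):
        # independent brute force over tied argmax positions
        rng = np.random.default_rng(11)
        for _ in range(300):
            k = int(rng.integers(3, 8))
            base = rng.integers(0, 5, size=k)
            base[rng.choice(k, size=2, replace=False)] = 6  # force a tie
            f = base.tolist()
            fmax = max(f)
            expected = min(
                max(
                    [f[i] - f[i - 1] for i in range(m + 1, k)]
                    + [f[i] - f[i + 1] for i in range(m)]
                    + [0]
                )
                for m in range(k)
                if f[m] == fmax
            )
            assert float(dfu(f)) == pytest.approx(max(0, expected))

    def test_tie_rule_agrees_with_leftmost_argmax_on_random_input(self):
        rng = np.random.default_rng(3)
        disagreements = 0
        for _ in range(500):
            f = rng.dirichlet(np.ones(rng.integers(2, 9))).tolist()
            m = int(np.argmax(f))
            leftmost = max(difference_vector(f, mode_index=m).diffs)
            if abs(max(0.0, leftmost) - float(dfu(f))) > 1e-12:
                disagreements += 1
        # continuous draws almost surely have a unique argmax
        assert disagreements == 0

    @given(simplex(), st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_moving_mass_onto_mode_never_increases_dfu(self, f, pick):
        # holds provided the donor bin stays >= its outer neighbour,
        # otherwise the transfer itself can open a new valley at the donor
        score = dfu(f)
        before = float(score)
        m = score.mode_index  # the tie-resolved mode, not a bare argmax
        neighbours = [i for i in (m - 1, m + 1) if 0 <= i < len(f) and f[i] > 0]
        if not neighbours:
            return
        j = neighbours[pick % len(neighbours)]
        outer = j + (j - m)
        cap = f[j] if not 0 <= outer < len(f) else f[j] - f[outer]
        eps = min(f[j] * 0.5, cap)
        if eps <= 0:
            return
        g = list(f)
        g[j] -= eps
        g[m] += eps
        assert float(dfu(g)) <= before + 1e-9
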