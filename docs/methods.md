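# Methods

## The statistic

DFU operates on a histogram `f = (f_1, ..., f_K)` of relative frequencies
over a totally ordered set of K rating categories. Unimodality for
discrete data means frequencies rise (weakly) to a single mode `m` and
fall (weakly) after it. DFU is the largest adjacent-bin violation of that
rule: for the mode `m`, `d_i = f_i - f_{i-1}` to the right of the mode,
`d_i = f_i - f_{i+1}` to the left, `d_m = 0`, and `DFU = max(d)`. The
difference vector covers *every* position other than the mode, including
the edge bins — excluding them would make a spike in the first or last
bin invisible and break the equivalence with the unimodality definition
itself (which constrains every adjacent pair).

Properties the test suite verifies:

- `DFU(f) = 0` if and only if `f` is unimodal (checked exhaustively
  against a brute-force oracle on the 0.05-frequency grid for all
  K ≤ 8), and the uniform histogram is unimodal.
- `0 <= DFU(f) <= max(f) <= 1`.
- Reversal symmetry: reading the scale backwards leaves DFU unchanged.

**Tied maxima.** When several bins share the maximum frequency, each
tied position is evaluated as the mode and the minimum of the resulting
maxima is reported. This is the most charitable rule toward unimodality:
a plateau-topped unimodal histogram scores 0 under it, which a bare
leftmost-argmax convention also delivers, and the two conventions agree
whenever the argmax is unique (a property test confirms this on random
continuous histograms). The tie rule preserves the exact
`DFU = 0 ⟺ unimodal` equivalence.

**Numerical details.** `d_m = 0` is always a member of `d`, so
`max(d) >= 0` analytically; the implementation still clamps at 0 to
absorb float residue. Histogram construction enforces non-negative
frequencies summing to 1 within 1e-9; the functional API additionally
accepts raw non-negative weight vectors, since the statistic only
compares adjacent bins and rescaling by the total changes the score only
by that constant factor (and not its sign). Empty bins are legal and
participate in the difference vector; no smoothing is applied. Scores
are kept at full precision internally; the CLI rounds report views to 2
decimals by default.

A subtlety worth recording: "moving mass onto the mode never increases
DFU" is *not* true unconditionally. Draining a neighbour of the mode can
push it below its own outer neighbour and open a new valley
((0.2, 0.25, 0.3, 0.25) → (0.2, 0.125, 0.425, 0.25) raises DFU from 0 to
0.075), and with tied maxima, feeding the wrong tied position can raise
the reported score. The property that holds — and is tested — moves mass
onto the tie-resolved reported mode with the transfer capped so the
donor stays at or above its outer neighbour.

## Baselines

The comparison measures are the conventional dispersion/consensus
proxies for polarization, all computed with categories encoded as the
integer positions 1..K and the histogram treated as the full population:

- **Standard deviation** — population normalisation, weighted by `f`.
- **Leik's ordinal consensus D** — `D = 2 Σ d_i / (K - 1)` with
  `d_i = F_i` when the cumulative frequency `F_i < 0.5` and `1 - F_i`
  otherwise. `D = 0` at full consensus and `D = 1` for a 50/50 split
  between the extreme categories (both covered by worked-value tests).
  `m` in the defining formula is the category count K, not a mode.
- **d² dispersion index** — `Σ_{i=1}^{K-1} (F_i - 0.5)`, implemented
  literally even though the plain sum can go negative and is
  antisymmetric under scale reversal (reversing the scale negates every
  centred term); an `absolute=True` variant sums `|F_i - 0.5|` for users
  who want a sign-free index, and is never used by default. Because only
  the correlation with human judgment matters downstream, the signed
  literal form is harmless.
- **Kurtosis** — fourth standardised moment of the encoded positions,
  Pearson convention (normal ≈ 3; verified on a finely binned large
  normal sample) with a `fisher=True` flag for excess kurtosis.
  Undefined for a single-category histogram (zero variance, rejected
  explicitly).

## Gaussian-mixture simulation

`MixtureSpec` draws `n` points by first choosing a component by weight
and then sampling its normal. The sample is binned into `bins`
equal-width ordinal bins spanning the sample range (right-open bins,
last bin closed — numpy histogram semantics); a fixed range can be
supplied when cross-run comparability of bin edges matters. Defaults are
`n = 10,000` and `bins = 10`, the regime in which a unit normal yields a
10-bin histogram that is unimodal (DFU rounding to 0.00) in at least 49
of 50 seeds — binning noise very occasionally produces a hairline
violation, which is why the guarantee is stated over seeds rather than
per draw.

Three presets ship: `fig1a`, a unit normal (unimodal); `fig1b`, an equal
mixture of normals with standard deviations 3 and 10; `fig1c`, an equal
mixture of three normals with standard deviations 5, 5 and 10. The
component *means and weights* are this package's own choices, picked so
the multimodal presets separate cleanly (means −20/+20, and −40/0/+45);
only the qualitative contract — `fig1a` scores 0, `fig1b` and `fig1c`
score strictly positive — is guaranteed, and the preset DFU values
themselves depend on these choices.

## Annotation aggregation and the country-diversity resampling

Raw records `(item_id, rater_id, label, country?)` are grouped per item
into a histogram on a configurable ordinal scale; the default 4-level
toxicity scale orders *not toxic < hard to say < toxic < very toxic*,
placing the "hard to say" judgment between the poles. That placement is
a modelling choice (an unsure rater is treated as intermediate); any
other ordering can be supplied as a YAML scale file. Raters without a
country are excluded from the distinct-country count, not imputed.

The resampling analysis splits items at a DFU quantile (default the 3rd
quartile; items exactly at the quantile go to the low side), then per
repetition draws `sample_size` items without replacement from each side
and compares mean distinct-country counts, counting a success when the
high-DFU side's mean is strictly larger. Defaults: 1,000 items per side
and 100 repetitions. A one-sided sign-test p-value over repetitions is
reported alongside the success count. One master seed spawns independent
per-repetition streams (`numpy.random.SeedSequence.spawn`), so
repetitions are independent and the whole analysis is reproducible. If a
side holds fewer than `sample_size` items the sample size is clamped to
the smaller side and a warning logged.

**Synthetic corpus.** The generator emulates a crowd-annotated toxicity
corpus. A `polarized_fraction` share of items gets labels split between
the two extreme categories, with one rater forced to each extreme, so
their histograms are bimodal and DFU > 0 *by construction*; the rest get
multinomially drawn counts rearranged center-out into a unimodal shape,
so DFU = 0 by construction. With the country effect on, raters of
polarized items come from a 12-country pool and raters of unpolarized
items from a 3-country pool; off, everyone shares one 6-country pool.
What the generator does **not** emulate: item-specific rater counts,
label noise that straddles the polarized/unpolarized boundary,
correlation between a rater's country and their label, or realistic
country marginals. Consequently, tests passing on this corpus show that
the pipeline detects a diversity effect when one exists and stays
calibrated (success rate near 50%) when none does — not that real
crowd-annotation corpora behave this way. Calibration tests keep the
corpus large relative to the per-repetition sample, because with a small
corpus the chance difference between the two sides' population means
dominates the per-repetition sampling noise and the null success rate
drifts from 1/2.

## Sentiment time series

Continuous valence scores in [0, 1] are discretized with strict
thresholds — positive above 0.61, negative below 0.43, neutral otherwise
(boundary scores are neutral because both inequalities are strict) — and
grouped by a cluster key, usually (date, region). Each cluster's 3-bin
histogram gets a DFU score; a cluster is flagged as a polarization
*peak* when DFU is strictly positive (an optional `peak_threshold`
raises the bar for noisy data). Dates are opaque strings (ISO 8601
recommended); no timezone arithmetic is performed. Invariants tested:
per-cluster counts sum to the input size; peak flags equal `dfu > 0`
exactly; lowering the positive threshold can move items only from
neutral to positive.

## Correlation with gold judgments

Perceived-polarization gold scores are treated as opaque monotone values
in [0, 100]; Spearman (average ranks for ties — frequent with K-bin
histograms) and Pearson coefficients are computed per measure over the
id intersection of scores and gold. Negative coefficients are meaningful
output (dispersion baselines genuinely anti-correlate with perceived
polarization on some fixtures) and are reported signed. The shipped
15-histogram gold table (`tests/data/synthetic_opgt.csv`) is *synthetic*:
its gold column is `5 + 90·DFU`, monotone in DFU by construction, so it
demonstrates the ranking machinery rather than any empirical human
finding. Real expert-judgment data can be supplied in the same CSV
format (`histogram_id, f1..fK, gold`).

## Problem sizes

The default test and acceptance runs use 10,000-draw simulations over 50
seeds, an exhaustive ~1.2M-histogram grid for the K ≤ 8 oracle check,
and synthetic annotation corpora of 4,000–8,000 items with 8 raters
each; the full suite completes in well under a minute on one CPU.

## Known limitations

- DFU is defined for discrete ordinal histograms only; it is not a
  continuous-distribution unimodality test (no dip-statistic analogue).
- The statistic reports only the *largest* violation; two small
  secondary modes score no higher than one of the same height.
- With very few raters per item, DFU is quantised to multiples of 1/n
  and small-sample noise can flip a histogram across the
  unimodal/non-unimodal boundary.
- The d² index is implemented exactly as its plain-sum definition, whose
  sign conventions are debatable; use the absolute variant if a
  magnitude is wanted.
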