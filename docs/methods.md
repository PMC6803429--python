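# Methods

## Model and assumptions

A CyTOF experiment is a set of batches (barcode sets), each a set of FCS
files of nonnegative per-event ion counts over shared channels. One file
per batch is an *anchor*: an aliquot of a single donor sample processed
identically everywhere, so anchors are technical replicates and inter-batch
differences among them are technical, not biological. The method assumes:

1. the anchor is representative of the batch — the per-channel distortion
   measured on the anchor applies to every sample acquired with it;
2. batch effects are well-approximated per channel, either by a single
   multiplicative factor (scaling methods) or by a monotone distributional
   shift (quantile normalization);
3. the anchor's signal range roughly covers the range of the study samples
   (hence stimulated anchors when stimulation is part of the design), so
   the calibration is not extrapolating.

For scaling methods, channel `c` of batch `b` is corrected by
`f(b,c) = s(ref anchor) / s(batch anchor)` where `s` is the chosen
statistic over **all** events, zeros included. Scaling is purely
multiplicative about zero — including for the SD method — because a
location shift could produce negative ion counts, which are physically
meaningless. Consequences relied on throughout: adjusted data are
nonnegative, event rank order within a channel is preserved, zeros map to
zeros, and since mean, median, SD and percentiles are all homogeneous of
degree one (`s(αx) = αs(x)` for α > 0), the adjusted batch anchor's
statistic equals the reference's *exactly* (to float tolerance), and
recomputing factors on adjusted anchors gives 1 (idempotence).

In arcsinh space the statistic is taken on `asinh(x/cofactor)` and the
corrected value is `cofactor·sinh(f·asinh(x/cofactor))` — non-linear in x,
but still monotone, nonnegative and zero-preserving. The closure property
then holds for the statistic computed in the transformed space.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `method` | `percentile` | summary statistic, or `quantile_norm` |
| `percentile_p` | 95 | targets the high end of the signal range while avoiding outliers; 80 is the robust low-end choice when many events are zero (real panels show channels with up to ~79% zeros) |
| `space` | `raw` | raw ion counts give a linear adjustment; `arcsinh` gives a non-linear one |
| `cofactor` | 5 | the community-standard arcsinh divisor for CyTOF counts |
| `skip_on_zero_stat` | true | a zero anchor statistic (e.g. median with >50% zeros) makes the ratio undefined; the channel is left unadjusted and the reason logged — silent division by zero would be worse than no adjustment |
| `qn_n_knots` | 10 001 | quantile-map resolution, clamped to the smaller anchor's event count; 10 001 knots keep the interpolation error of the map well below sampling noise at typical anchor sizes |
| `qn_zero_handling` | `pooled` | see below |

The reference batch is always user-designated; the tool refuses to pick
one, because a sensible choice (not an outlier batch) requires inspecting
the distributions — which the diagnostic output supports.

## Quantile normalization and the zero mass

The quantile map is piecewise linear through `(batch quantile, reference
quantile)` knots on an even probability grid, with the same interpolation
convention as the percentile statistic (rank `1 + (n−1)p/100`). Inputs
outside the knot range clamp to the end knots. Because the map must be a
*function* of the value, all events tied at one value — in practice the
zero point mass — must share one output; tied source knots are collapsed
to a single knot whose target is the **median** of the tied targets. When
both anchors carry comparable zero mass this maps zeros back to zero; when
the batch anchor has distinctly more zeros than the reference, the median
of the tied target range is positive and zeros are inflated to a positive
value, and in the opposite direction the lowest positive events are
squashed to zero. This inflation/squashing behaviour is an inherent
artifact of single-channel QN on zero-inflated data, reproduced here by
construction; `qn_zero_handling='conditional'` avoids it by mapping zeros
to zeros and quantile-mapping only the positive parts, at the cost of not
matching the zero fractions.

## Validation statistics

*KS consistency* is the mean two-sample KS statistic `D = sup|F₁ − F₂|`
over all unordered anchor pairs in a channel. `D` is invariant under
strictly monotone transforms, so raw vs arcsinh is immaterial for the
exact value; it matters only under subsampling, which is why subsampling
is optional, seeded and off by default.

*Total variance* of a replicates × features matrix is the sum over
features of the sample variance (divisor n−1) — the trace, equivalently
the eigenvalue sum, of the feature covariance matrix.

*Permutation test*: under the null that adjustment changes nothing,
pre/post labels are exchangeable within each replicate. For every subset
of replicates the two rows are swapped and the change in total variance
recomputed; all 2^n assignments are enumerated for n ≤ 20 (the default
`max_exact_n`, ~10⁶ evaluations), beyond which a seeded Monte-Carlo
sample of 10 000 assignments is used, always including the identity. The
test is one-sided in the reduction direction, and the identity assignment
is counted in the null, so p ∈ (0, 1] and the smallest attainable exact p
is 2^−n. Note that a replicate identical pre and post contributes a
duplicate of the observed delta for each subset that differs only in it,
so degenerate rows raise the attainable p floor accordingly.

## Rolling basis and determinism

Each batch's output depends only on (its anchor, the reference anchor,
the config): batches are calibrated and written independently, so adding
a new batch later and re-running reproduces all previously written FCS
outputs byte-identically. To make that hold, the FCS writer emits no
timestamps and uses fixed-width offsets; provenance (method, space,
reference, skipped channels) is written under the `BATCHADJ` keyword
prefix, which standard readers ignore.

## Synthetic data: what it emulates, and what it does not

Each sample is a mixture of cell populations; each population's channel
intensity is a zero point mass (matching the zero-valued-event phenomenon
of real ion counts) plus a log-normal positive part — right-skewed and
nonnegative, qualitatively like CyTOF marginals, but explicitly a
stand-in: no generative model is claimed for real data. Batch effects are
injected as per-batch per-channel multipliers on the positive part and
additive shifts of the zero probability. Anchors share the base mixture
across batches (technical replicates); study samples get Dirichlet-
perturbed mixture weights (biological variability); an optional
unstimulated-analog replicate set attenuates designated "cytokine"
channels' log-means, and is adjusted with factors calibrated on the
designated anchors — mirroring the stimulated/unstimulated validation
design. Everything is reproducible from a seed.

What passing tests on this generator shows: the estimator recovers known
multiplicative distortions, the closure/passthrough/rolling contracts
hold, and the validation statistics detect the injected effects and their
removal. What it does not show: performance on real data with correlated
channels, acquisition drift within a run, doublets, barcode or bead
events, or batch effects that change distribution *shape* rather than
scale — multiplicative correction cannot repair shape changes, and
channels with wildly varying zero fractions may admit no satisfactory
scalar adjustment at all (those channels surface as skips or as large
factors in the diagnostics, and per-batch testing with meta-analytic
combination is the fallback).

Because adjustment rescales intensities and never reassigns events, the
generator's *true* population fractions are identical pre and post by
construction. The end-to-end variance-reduction checks therefore measure
fractions the way a fixed gating scheme would: per-channel threshold
gates (percent-positivity above the reference anchor's 70th percentile)
drawn once on the reference anchor and applied unchanged to every
replicate pre and post. Misclassification under the fixed gates varies
with the injected multipliers before adjustment and collapses after —
the mechanism by which fixed manual gates see batch effects.

## Problem sizes and numerical choices

The test suite and the acceptance script run the end-to-end experiment at
8 batches × 20 channels × 20 000 events per sample (effects on half the
channels, log-uniform multipliers in [0.5, 2]), and parameter-recovery
checks at 100 000 events over 10 seeds — sizes chosen so the sampling
error of a 95th percentile at n = 100k (≈0.5% relative) sits comfortably
inside the 2% recovery tolerance while the whole run stays in seconds.
One round-trip test exercises a full-scale 500k × 38 file. FCS data are
stored as little-endian float32 ($DATATYPE/F), matching contemporary
CyTOF exports and avoiding integer truncation of adjusted values; values
round-trip to float32 precision (~1e−7 relative). Factor tables are CSV
with a JSON sidecar for quantile-map knots — open formats chosen over an
ecosystem-specific binary container for the saved-factors artifact.
Degenerate inputs: constant vectors give SD 0 (skip path), single-event
vectors give SD 0, quantile maps with fewer knots than requested clamp to
the event count, and tie-collapse uses a running maximum to remove ~1 ulp
non-monotonicity introduced by interpolation.

## Known limitations

- Per-channel, single-factor correction: joint multi-channel structure is
  untouched, and shape-changing batch effects are out of reach.
- Single-channel QN is provided but its biaxial artifacts make it
  unsuitable for downstream gating; it is retained for distributional
  comparisons.
- Only the first dataset of a multi-dataset FCS file is read.
- Gating itself is out of scope; gated fraction matrices are accepted as
  CSV input to the evaluation statistics.
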