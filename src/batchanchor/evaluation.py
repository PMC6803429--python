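"""Validation statistics for replicate consistency across batches.

Anchor samples are technical replicates, so any spread among them is
technical. Three measures quantify it:

* per-channel consistency as the mean two-sample Kolmogorov-Smirnov
  statistic over all replicate pairs;
* total variance of a replicates x features summary matrix (channel means
  or gated subpopulation fractions), i.e. the trace — equivalently the
  eigenvalue sum — of the feature covariance matrix;
* an exact permutation test for the reduction in total variance after
  adjustment, swapping pre/post labels per replicate.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fcs_io import EventTable

__all__ = [
    "ReplicateFeatureMatrix",
    "ks_channel_consistency",
    "total_variance",
    "permutation_test_variance_change",
    "channel_mean_matrix",
]


@dataclass
class ReplicateFeatureMatrix:
    """n replicates x k features matrix of per-replicate summaries.

    Features are per-channel mean signal intensities, or gated
    subpopulation fractions in [0, 1]. Needs at least two replicates and
    no missing values.
    """

    replicate_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    fractions: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n, k = self.values.shape
        if n < 2:
            raise ValueError("at least two replicates required")
        if len(self.replicate_ids) != n or len(self.feature_ids) != k:
            raise ValueError("id lists must match the matrix shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains missing or non-finite values")
        if self.fractions and (np.any(self.values < 0) or np.any(self.values > 1)):
            raise ValueError("fraction features must lie in [0, 1]")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.replicate_ids,
                            columns=self.feature_ids)

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index_label="replicate")

    @classmethod
    def from_csv(cls, path: str, fractions: bool = False) -> "ReplicateFeatureMatrix":
        """Load a replicates-in-rows CSV (e.g. externally gated population
        fractions; the gating itself happens elsewhere)."""
        frame = pd.read_csv(path, index_col=0)
        return cls(
            replicate_ids=[str(i) for i in frame.index],
            feature_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=np.float64),
            fractions=fractions,
        )


def ks_channel_consistency(
    replicate_values: list[np.ndarray],
    subsample: int | None = None,
    seed: int | None = None,
) -> float:
    """Mean pairwise two-sample KS statistic among replicates, in [0, 1].

    Averages D = sup|F1 - F2| over all n(n-1)/2 unordered replicate pairs:
    0 for identical empirical distributions, 1 for disjoint supports. With
    ``subsample`` set, each replicate is first downsampled without
    replacement (seeded), which bounds the cost on full-size anchors. D
    itself is invariant under strictly monotone transforms, so raw vs.
    arcsinh intensities give the same exact value.
    """
    vectors = [np.asarray(v, dtype=np.float64) for v in replicate_values]
    if len(vectors) < 2:
        raise ValueError("at least two replicates required")
    if any(v.size == 0 for v in vectors):
        raise ValueError("replicate vectors must be non-empty")
    if subsample is not None:
        rng = np.random.default_rng(seed)
        vectors = [
            rng.choice(v, size=min(subsample, v.size), replace=False) for v in vectors
        ]
    distances = [
        stats.ks_2samp(a, b, method="asymp").statistic
        for a, b in itertools.combinations(vectors, 2)
    ]
    return float(np.mean(distances))


def total_variance(matrix: ReplicateFeatureMatrix) -> float:
    """Sum over features of the sample variance (divisor n-1) across
    replicates — the trace, and eigenvalue sum, of the k x k feature
    covariance matrix."""
    return float(np.var(matrix.values, axis=0, ddof=1).sum())


def permutation_test_variance_change(
    pre: ReplicateFeatureMatrix,
    post: ReplicateFeatureMatrix,
    max_exact_n: int = 20,
    n_monte_carlo: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float, int]:
    """Exact permutation test for the change in total variance.

    The observed statistic is ``total_variance(post) - total_variance(pre)``.
    Under the null that adjustment does nothing, pre/post labels are
    exchangeable per replicate: for every subset S of replicates, rows in S
    are swapped between the two matrices and the change recomputed. All
    2^n sign assignments are enumerated when n <= ``max_exact_n``; larger n
    fall back to ``n_monte_carlo`` seeded random assignments that always
    include the identity. The one-sided p-value is the fraction of null
    changes as small as or smaller than the observed one (reductions as or
    more extreme); including the identity guarantees p in (0, 1].

    Returns ``(observed_delta, p_value, n_permutations)``.
    """
    if pre.replicate_ids != post.replicate_ids or pre.feature_ids != post.feature_ids:
        raise ValueError("pre and post matrices must share replicate and feature ids")
    if pre.values.shape != post.values.shape:
        raise ValueError("pre and post matrices must have equal shape")

    a, b = pre.values, post.values
    n = a.shape[0]

    def delta_for(mask: np.ndarray) -> float:
        swapped_pre = np.where(mask[:, None], b, a)
        swapped_post = np.where(mask[:, None], a, b)
        return float(
            np.var(swapped_post, axis=0, ddof=1).sum()
            - np.var(swapped_pre, axis=0, ddof=1).sum()
        )

    observed = delta_for(np.zeros(n, dtype=bool))

    if n <= max_exact_n:
        masks = (
            np.array(bits, dtype=bool)
            for bits in itertools.product((False, True), repeat=n)
        )
        null = np.fromiter((delta_for(m) for m in masks), dtype=np.float64,
                           count=2 ** n)
    else:
        rng = np.random.default_rng(seed)
        draws = rng.integers(0, 2, size=(n_monte_carlo - 1, n)).astype(bool)
        null = np.empty(n_monte_carlo)
        null[0] = observed  # identity assignment always included
        for i, mask in enumerate(draws, start=1):
            null[i] = delta_for(mask)

    n_perm = null.size
    p_value = float(np.count_nonzero(null <= observed) / n_perm)
    return observed, p_value, int(n_perm)


def channel_mean_matrix(
    tables: list[EventTable], channels: list[str]
) -> ReplicateFeatureMatrix:
    """Per-replicate, per-channel mean signal intensity over all events."""
    values = np.array(
        [[float(np.mean(t.channel_values(c))) for c in channels] for t in tables]
    )
    return ReplicateFeatureMatrix(
        replicate_ids=[t.sample_id for t in tables],
        feature_ids=list(channels),
        values=values,
    )


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Pre/post consistency summary for one replicate set."""

    per_channel_ks_pre: dict[str, float]
    per_channel_ks_post: dict[str, float]
    total_variance_pre: float
    total_variance_post: float
    observed_delta: float
    p_value: float
    n_permutations: int
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)

    def ks_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ks_pre": self.per_channel_ks_pre, "ks_post": self.per_channel_ks_post}
        ).rename_axis("channel")


def evaluate_replicates(
    pre_tables: list[EventTable],
    post_tables: list[EventTable],
    channels: list[str],
    subsample: int | None = None,
    seed: int | None = None,
    max_exact_n: int = 20,
    n_monte_carlo: int = 10_000,
) -> EvaluationReport:
    """Full pre/post evaluation of one replicate (anchor) set: per-channel
    KS consistency, total variance of channel means, and the permutation
    test on the change."""
    ks_pre = {
        c: ks_channel_consistency([t.channel_values(c) for t in pre_tables],
                                  subsample=subsample, seed=seed)
        for c in channels
    }
    ks_post = {
        c: ks_channel_consistency([t.channel_values(c) for t in post_tables],
                                  subsample=subsample, seed=seed)
        for c in channels
    }
    pre_matrix = channel_mean_matrix(pre_tables, channels)
    post_matrix = channel_mean_matrix(post_tables, channels)
    delta, p_value, n_perm = permutation_test_variance_change(
        pre_matrix, post_matrix, max_exact_n=max_exact_n,
        n_monte_carlo=n_monte_carlo, seed=seed,
    )
    return EvaluationReport(
        per_channel_ks_pre=ks_pre,
        per_channel_ks_post=ks_post,
        total_variance_pre=total_variance(pre_matrix),
        total_variance_post=total_variance(post_matrix),
        observed_delta=delta,
        p_value=p_value,
        n_permutations=n_perm,
        seed=seed,
    )
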