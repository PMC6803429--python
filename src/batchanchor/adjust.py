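"""Per-channel batch adjustment calibrated on anchor technical replicates.

Every batch (barcode set) carries an anchor: an aliquot of one donor sample,
biologically identical across batches, so any difference between a batch
anchor and the reference batch's anchor is technical. For each channel an
adjustment factor is the ratio of a summary statistic (percentile, mean,
median, or SD of per-event ion counts) of the reference anchor to the same
statistic of the batch anchor; multiplying the batch's events by that factor
aligns the statistic exactly. Quantile normalization instead maps the batch
anchor's empirical distribution onto the reference anchor's through a
monotone piecewise-linear quantile-to-quantile map.

Factors may be computed and applied in raw ion-count space (linear
adjustment) or in arcsinh-transformed space, which becomes non-linear once
inverted back to ion counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fcs_io import CUSTOM_KEYWORD_PREFIX, EventTable

__all__ = [
    "AdjustmentConfig",
    "ScaleFactorRecord",
    "QuantileMap",
    "SkipChannel",
    "channel_statistic",
    "compute_scale_factor",
    "apply_scale",
    "build_quantile_map",
    "apply_quantile_map",
    "adjust_sample",
]

SCALE_METHODS = ("percentile", "mean", "median", "sd")
METHODS = SCALE_METHODS + ("quantile_norm",)


@dataclass
class AdjustmentConfig:
    """Settings for one batch-adjustment run.

    Parameters
    ----------
    method : {'percentile', 'mean', 'median', 'sd', 'quantile_norm'}
        Summary statistic used for scaling, or quantile normalization.
    percentile_p : float
        Percentile in (0, 100) when ``method='percentile'``. 95 targets the
        high end of the signal range while avoiding outliers; 80 suits
        channels where most events are zero-valued.
    space : {'raw', 'arcsinh'}
        Data space in which factors are computed and applied.
    cofactor : float
        arcsinh divisor (x -> asinh(x / cofactor)); 5 is the CyTOF
        community convention.
    reference_batch : str
        Batch whose anchor defines the adjustment target; its samples are
        never modified.
    channels_to_adjust : list of str
        Channel short names to adjust; all other channels pass through
        untouched.
    skip_on_zero_stat : bool
        If the anchor statistic is zero (e.g. median with >50% zero-valued
        events) leave the channel unadjusted and record the reason, instead
        of raising.
    qn_n_knots : int
        Quantile grid size for ``quantile_norm`` (clamped to the smaller
        anchor's event count).
    qn_zero_handling : {'pooled', 'conditional'}
        'pooled' quantile-maps all events including zeros (the plain ECDF
        map, which can inflate zeros or squash low positives when zero
        masses differ); 'conditional' maps zeros to zeros and
        quantile-maps only the positive parts.
    """

    method: str = "percentile"
    percentile_p: float = 95.0
    space: str = "raw"
    cofactor: float = 5.0
    reference_batch: str = ""
    channels_to_adjust: list[str] = field(default_factory=list)
    skip_on_zero_stat: bool = True
    qn_n_knots: int = 10_001
    qn_zero_handling: str = "pooled"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if not 0.0 < self.percentile_p < 100.0:
            raise ValueError("percentile_p must lie in (0, 100)")
        if self.space not in ("raw", "arcsinh"):
            raise ValueError("space must be 'raw' or 'arcsinh'")
        if self.cofactor <= 0:
            raise ValueError("cofactor must be positive")
        if self.qn_n_knots < 2:
            raise ValueError("qn_n_knots must be >= 2")
        if self.qn_zero_handling not in ("pooled", "conditional"):
            raise ValueError("qn_zero_handling must be 'pooled' or 'conditional'")


@dataclass
class SkipChannel:
    """Signal that a channel was left unadjusted, with the reason why."""

    reason: str


@dataclass
class QuantileMap:
    """Monotone piecewise-linear value -> value map between two distributions.

    ``source_knots`` are quantiles of the batch anchor and ``target_knots``
    the reference anchor's quantiles at the same probabilities. Inputs
    outside the knot range clamp to the end knots. Applying the map
    preserves rank order and maps nonnegative inputs to nonnegative outputs.
    """

    source_knots: np.ndarray
    target_knots: np.ndarray
    #: built on positive events only; zeros pass through unchanged on apply
    zero_preserving: bool = False

    def __post_init__(self) -> None:
        self.source_knots = np.asarray(self.source_knots, dtype=np.float64)
        self.target_knots = np.asarray(self.target_knots, dtype=np.float64)
        if self.source_knots.shape != self.target_knots.shape:
            raise ValueError("source and target knots must have equal length")
        if self.source_knots.ndim != 1 or self.source_knots.size < 1:
            raise ValueError("knot vectors must be non-empty and 1-D")
        if np.any(np.diff(self.source_knots) < 0) or np.any(np.diff(self.target_knots) < 0):
            raise ValueError("knot vectors must be nondecreasing")

    @property
    def is_identity(self) -> bool:
        return bool(np.array_equal(self.source_knots, self.target_knots))


@dataclass
class ScaleFactorRecord:
    """Per-batch adjustment: one factor, quantile map, or skip per channel.

    This is the persisted "diagnostic" artifact of a run: inspecting the
    factors reveals outlier batches, channel labeling errors, or other
    input problems before they propagate downstream.
    """

    batch_id: str
    method: str
    space: str
    entries: dict[str, float | QuantileMap | SkipChannel] = field(default_factory=dict)

    def validate(self) -> None:
        for channel, entry in self.entries.items():
            if isinstance(entry, (int, float)):
                if not np.isfinite(entry) or entry <= 0:
                    raise ValueError(
                        f"batch {self.batch_id!r} channel {channel!r}: "
                        f"factor must be finite and positive, got {entry}"
                    )

    def skipped_channels(self) -> dict[str, str]:
        return {
            ch: e.reason for ch, e in self.entries.items() if isinstance(e, SkipChannel)
        }


# ---------------------------------------------------------------------------
# Summary statistics and scale factors
# ---------------------------------------------------------------------------

def channel_statistic(
    values: np.ndarray, method: str, percentile_p: float = 95.0
) -> float:
    """Summary statistic of one channel over all events, zeros included.

    Percentiles interpolate linearly between order statistics at rank
    ``1 + (n - 1) * p / 100``; ``sd`` is the sample standard deviation
    (divisor ``n - 1``), zero for a constant or single-event vector.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("values must be a non-empty 1-D vector")
    if method == "mean":
        return float(np.mean(values))
    if method == "median":
        return float(np.median(values))
    if method == "percentile":
        if not 0.0 < percentile_p < 100.0:
            raise ValueError("percentile_p must lie in (0, 100)")
        return float(np.percentile(values, percentile_p))
    if method == "sd":
        if values.size < 2:
            return 0.0
        return float(np.std(values, ddof=1))
    raise ValueError(f"unknown statistic {method!r}; expected one of {SCALE_METHODS}")


def _maybe_transform(values: np.ndarray, config: AdjustmentConfig) -> np.ndarray:
    if config.space == "arcsinh":
        return np.arcsinh(np.asarray(values, dtype=np.float64) / config.cofactor)
    return np.asarray(values, dtype=np.float64)


def compute_scale_factor(
    ref_anchor_values: np.ndarray,
    batch_anchor_values: np.ndarray,
    config: AdjustmentConfig,
) -> float | SkipChannel:
    """Adjustment factor stat(reference anchor) / stat(batch anchor).

    With ``space='arcsinh'`` both vectors are transformed before the
    statistic. A zero statistic in either anchor (the degenerate case of
    e.g. a median over >50% zero-valued events) yields a
    :class:`SkipChannel` when ``skip_on_zero_stat`` is set, else raises.
    """
    if config.method not in SCALE_METHODS:
        raise ValueError(f"scale factor undefined for method {config.method!r}")
    stat_ref = channel_statistic(
        _maybe_transform(ref_anchor_values, config), config.method, config.percentile_p
    )
    stat_batch = channel_statistic(
        _maybe_transform(batch_anchor_values, config), config.method, config.percentile_p
    )
    if stat_ref == 0.0 or stat_batch == 0.0:
        which = "reference" if stat_ref == 0.0 else "batch"
        reason = (
            f"{config.method} statistic of the {which} anchor is zero; "
            "scaling factor undefined"
        )
        if config.skip_on_zero_stat:
            return SkipChannel(reason)
        raise ValueError(reason)
    factor = stat_ref / stat_batch
    if not np.isfinite(factor) or factor <= 0:
        raise ValueError(f"non-finite or non-positive scale factor {factor}")
    return factor


def apply_scale(
    values: np.ndarray, factor: float, space: str = "raw", cofactor: float = 5.0
) -> np.ndarray:
    """Scale event intensities by ``factor`` in the requested data space.

    raw:      v -> v * factor                          (linear)
    arcsinh:  v -> c * sinh(factor * asinh(v / c))     (non-linear in v)

    Both preserve rank order, nonnegativity, and map zeros to zeros.
    """
    values = np.asarray(values, dtype=np.float64)
    if not np.isfinite(factor) or factor <= 0:
        raise ValueError("factor must be finite and positive")
    if space == "raw":
        return values * factor
    if space == "arcsinh":
        return cofactor * np.sinh(factor * np.arcsinh(values / cofactor))
    raise ValueError("space must be 'raw' or 'arcsinh'")


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------

def build_quantile_map(
    ref_anchor_values: np.ndarray,
    batch_anchor_values: np.ndarray,
    n_knots: int = 10_001,
    zero_handling: str = "pooled",
) -> QuantileMap:
    """Quantile-to-quantile map from a batch anchor onto the reference anchor.

    Knots are the two anchors' quantiles on a common evenly spaced
    probability grid (linear interpolation between order statistics, same
    convention as :func:`channel_statistic`). Tied source knots — the zero
    point mass of ion-count data — are collapsed to a single knot whose
    target is the median of the tied targets, keeping the map a monotone
    function of the input value: when both anchors carry comparable zero
    mass the zeros map back to zero, while genuinely unequal zero masses
    still produce the inflation/squashing artifact below.

    With ``zero_handling='pooled'`` (default) the map is built over all
    events including zeros: when zero masses differ between anchors this
    either inflates zeros to positive values or squashes the lowest
    positive events to zero — the known single-channel QN artifact.
    ``'conditional'`` instead maps zeros to zeros and builds the map on the
    positive parts only.
    """
    ref = np.asarray(ref_anchor_values, dtype=np.float64)
    batch = np.asarray(batch_anchor_values, dtype=np.float64)
    if ref.size == 0 or batch.size == 0:
        raise ValueError("anchor vectors must be non-empty")
    if n_knots < 2:
        raise ValueError("n_knots must be >= 2")
    if zero_handling == "conditional":
        ref = ref[ref > 0]
        batch = batch[batch > 0]
        if ref.size == 0 or batch.size == 0:
            raise ValueError(
                "conditional quantile map undefined: an anchor has no positive events"
            )
    elif zero_handling != "pooled":
        raise ValueError("zero_handling must be 'pooled' or 'conditional'")

    n_knots = min(n_knots, ref.size, batch.size)
    n_knots = max(n_knots, 2)
    grid = np.linspace(0.0, 1.0, n_knots)
    source = np.quantile(batch, grid)
    target = np.quantile(ref, grid)
    # collapse ties in the source so the map is a function of the value
    uniq, start = np.unique(source, return_index=True)
    if uniq.size < source.size:
        bounds = np.append(start, source.size)
        target = np.array(
            [np.median(target[a:b]) for a, b in zip(bounds[:-1], bounds[1:])]
        )
        # interpolation can introduce ~1 ulp of non-monotonicity; clamp it
        target = np.maximum.accumulate(target)
        source = uniq
    return QuantileMap(
        source_knots=source,
        target_knots=target,
        zero_preserving=(zero_handling == "conditional"),
    )


def apply_quantile_map(values: np.ndarray, qmap: QuantileMap) -> np.ndarray:
    """Apply a quantile map by piecewise-linear interpolation.

    Inputs below/above the knot range clamp to the first/last target knot;
    zeros stay zero when both end knots are zero (the conditional-mode
    contract) but may move under the pooled map.
    """
    values = np.asarray(values, dtype=np.float64)
    out = np.interp(values, qmap.source_knots, qmap.target_knots)
    if qmap.zero_preserving:
        out = np.where(values == 0, 0.0, out)
    return out


# ---------------------------------------------------------------------------
# Applying a record to a sample
# ---------------------------------------------------------------------------

def adjust_sample(
    table: EventTable, record: ScaleFactorRecord, config: AdjustmentConfig
) -> EventTable:
    """Apply a batch's per-channel adjustments to one sample.

    Channels outside ``channels_to_adjust`` are untouched; samples from the
    reference batch are returned value-identical; skipped channels stay
    unchanged and are flagged in the provenance keywords.
    """
    if record.batch_id != table.batch_id:
        raise ValueError(
            f"record for batch {record.batch_id!r} applied to sample "
            f"{table.sample_id!r} from batch {table.batch_id!r}"
        )
    missing = [c for c in config.channels_to_adjust if c not in table.channel_names]
    if missing:
        raise ValueError(
            f"sample {table.sample_id!r}: channels {missing} not present"
        )
    provenance = {
        f"{CUSTOM_KEYWORD_PREFIX}_METHOD": config.method,
        f"{CUSTOM_KEYWORD_PREFIX}_SPACE": config.space,
        f"{CUSTOM_KEYWORD_PREFIX}_REFERENCE": config.reference_batch,
    }
    if table.batch_id == config.reference_batch:
        return table.with_data(
            table.data, **provenance, **{f"{CUSTOM_KEYWORD_PREFIX}_REFBATCH": "1"}
        )

    data = table.data.copy()
    names = table.channel_names
    skipped = []
    for channel in config.channels_to_adjust:
        entry = record.entries.get(channel)
        if entry is None or isinstance(entry, SkipChannel):
            skipped.append(channel)
            continue
        idx = names.index(channel)
        if isinstance(entry, QuantileMap):
            data[:, idx] = apply_quantile_map(data[:, idx], entry)
        else:
            data[:, idx] = apply_scale(
                data[:, idx], float(entry), config.space, config.cofactor
            )
    if skipped:
        provenance[f"{CUSTOM_KEYWORD_PREFIX}_SKIPPED"] = ",".join(skipped)
    return table.with_data(data, **provenance)


# ---------------------------------------------------------------------------
# Record (de)serialization: CSV table + JSON sidecar for quantile-map knots
# ---------------------------------------------------------------------------

def records_to_frame(records: list[ScaleFactorRecord]) -> pd.DataFrame:
    """Flatten records into a (batch_id, channel, method, space, factor,
    skipped, reason) table; quantile maps show ``factor='QN'``."""
    rows = []
    for record in records:
        for channel, entry in sorted(record.entries.items()):
            if isinstance(entry, SkipChannel):
                rows.append(
                    (record.batch_id, channel, record.method, record.space,
                     "", True, entry.reason)
                )
            elif isinstance(entry, QuantileMap):
                rows.append(
                    (record.batch_id, channel, record.method, record.space,
                     "QN", False, "")
                )
            else:
                rows.append(
                    (record.batch_id, channel, record.method, record.space,
                     repr(float(entry)), False, "")
                )
    return pd.DataFrame(
        rows,
        columns=["batch_id", "channel", "method", "space", "factor", "skipped", "reason"],
    )


def save_records(records: list[ScaleFactorRecord], csv_path: str,
                 knots_path: str | None = None) -> None:
    """Persist records as a CSV table, plus a JSON sidecar of quantile-map
    knots when any record carries maps."""
    records_to_frame(records).to_csv(csv_path, index=False)
    maps = {
        record.batch_id: {
            ch: {"source": e.source_knots.tolist(), "target": e.target_knots.tolist(),
                 "zero_preserving": e.zero_preserving}
            for ch, e in record.entries.items()
            if isinstance(e, QuantileMap)
        }
        for record in records
    }
    maps = {b: m for b, m in maps.items() if m}
    if maps and knots_path:
        with open(knots_path, "w") as fh:
            json.dump(maps, fh)


def load_records(csv_path: str, knots_path: str | None = None
                 ) -> list[ScaleFactorRecord]:
    """Inverse of :func:`save_records`."""
    frame = pd.read_csv(csv_path, keep_default_na=False)
    maps: dict = {}
    if knots_path:
        try:
            with open(knots_path) as fh:
                maps = json.load(fh)
        except FileNotFoundError:
            maps = {}
    records: dict[str, ScaleFactorRecord] = {}
    for row in frame.itertuples(index=False):
        batch = str(row.batch_id)
        record = records.setdefault(
            batch, ScaleFactorRecord(batch_id=batch, method=row.method, space=row.space)
        )
        if row.skipped in (True, "True"):
            record.entries[row.channel] = SkipChannel(str(row.reason))
        elif row.factor == "QN":
            knots = maps[batch][row.channel]
            record.entries[row.channel] = QuantileMap(
                np.asarray(knots["source"]),
                np.asarray(knots["target"]),
                zero_preserving=bool(knots.get("zero_preserving", False)),
            )
        else:
            record.entries[row.channel] = float(row.factor)
    return list(records.values())
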