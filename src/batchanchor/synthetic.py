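"""Synthetic multi-batch CyTOF-like data with known injected batch effects.

Real mass-cytometry channels are zero-inflated and right-skewed: a point
mass of zero-valued events (no ions detected) plus a positive part that is
roughly log-normal in ion-count units. Samples are mixtures of cell
populations that differ in both mixture weight and per-channel intensity.
Batch effects enter as per-batch per-channel multiplicative distortions of
the positive part and shifts of the zero-event fraction.

The generator emits one anchor (technical replicate of a fixed mixture) and
any number of study samples per batch, optionally with an unstimulated-analog
second replicate set, and records the ground truth (specs, seed, realized
population fractions) so parameter recovery is assertable. Everything is
reproducible from the seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from .evaluation import ReplicateFeatureMatrix
from .fcs_io import EventTable, write_fcs

__all__ = [
    "PopulationSpec",
    "BatchEffectSpec",
    "SyntheticTruth",
    "generate_experiment",
    "true_fraction_matrix",
    "default_populations",
    "default_batch_effects",
    "write_experiment",
]


@dataclass
class PopulationSpec:
    """One cell population's mixture weight and per-channel intensity model.

    Each channel is modeled as a zero point mass (probability
    ``zero_probability[j]``) plus a log-normal positive part with location
    ``log_mean[j]`` and scale ``log_sd[j]`` on the natural-log scale, in
    ion-count units.
    """

    name: str
    mixture_weight: float
    zero_probability: np.ndarray
    log_mean: np.ndarray
    log_sd: np.ndarray

    def __post_init__(self) -> None:
        self.zero_probability = np.asarray(self.zero_probability, dtype=np.float64)
        self.log_mean = np.asarray(self.log_mean, dtype=np.float64)
        self.log_sd = np.asarray(self.log_sd, dtype=np.float64)
        if not 0.0 < self.mixture_weight <= 1.0:
            raise ValueError(f"population {self.name!r}: weight must be in (0, 1]")
        if np.any(self.zero_probability < 0) or np.any(self.zero_probability >= 1):
            raise ValueError(f"population {self.name!r}: zero_probability must be in [0, 1)")
        if np.any(self.log_sd <= 0):
            raise ValueError(f"population {self.name!r}: log_sd must be positive")
        if not self.zero_probability.shape == self.log_mean.shape == self.log_sd.shape:
            raise ValueError(f"population {self.name!r}: per-channel arrays differ in length")

    @property
    def n_channels(self) -> int:
        return self.zero_probability.size


@dataclass
class BatchEffectSpec:
    """Per-batch per-channel distortions applied to every sample of a batch.

    ``multipliers[batch][channel]`` scales the positive part;
    ``zero_shift[batch][channel]`` is added to each population's zero
    probability (clipped to [0, 1)). The reference batch must be the
    identity: multiplier 1, shift 0.
    """

    multipliers: dict[str, np.ndarray]
    zero_shift: dict[str, np.ndarray] = field(default_factory=dict)
    reference_batch: str = ""

    def __post_init__(self) -> None:
        self.multipliers = {
            b: np.asarray(m, dtype=np.float64) for b, m in self.multipliers.items()
        }
        self.zero_shift = {
            b: np.asarray(s, dtype=np.float64) for b, s in self.zero_shift.items()
        }
        for batch, m in self.multipliers.items():
            if np.any(m <= 0):
                raise ValueError(f"batch {batch!r}: multipliers must be positive")
        if self.reference_batch:
            ref_m = self.multipliers.get(self.reference_batch)
            if ref_m is None or not np.allclose(ref_m, 1.0):
                raise ValueError("reference batch must have identity multipliers")
            ref_s = self.zero_shift.get(self.reference_batch)
            if ref_s is not None and not np.allclose(ref_s, 0.0):
                raise ValueError("reference batch must have zero zero-shift")

    def batches(self) -> list[str]:
        return sorted(self.multipliers)


@dataclass
class SyntheticTruth:
    """Everything needed to reconstruct or check a generated experiment."""

    populations: list[PopulationSpec]
    effects: BatchEffectSpec
    seed: int
    events_per_sample: dict[str, int]
    fractions: dict[str, np.ndarray]        # sample_id -> realized fractions
    roles: dict[str, str] = field(default_factory=dict)
    conditions: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        payload = {
            "seed": self.seed,
            "populations": [
                {
                    "name": p.name,
                    "mixture_weight": p.mixture_weight,
                    "zero_probability": p.zero_probability.tolist(),
                    "log_mean": p.log_mean.tolist(),
                    "log_sd": p.log_sd.tolist(),
                }
                for p in self.populations
            ],
            "effects": {
                "reference_batch": self.effects.reference_batch,
                "multipliers": {b: m.tolist() for b, m in self.effects.multipliers.items()},
                "zero_shift": {b: s.tolist() for b, s in self.effects.zero_shift.items()},
            },
            "events_per_sample": self.events_per_sample,
            "fractions": {s: f.tolist() for s, f in self.fractions.items()},
            "roles": self.roles,
            "conditions": self.conditions,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def default_populations(n_channels: int = 38, n_populations: int = 3
                        ) -> list[PopulationSpec]:
    """A realistic default panel: a few populations of unequal abundance
    with channel-dependent zero fractions (up to ~half the events zero in
    the worst channels) and median ion counts in the tens-to-hundreds."""
    rng = np.random.default_rng(20191015)  # fixed panel, independent of data seed
    weights = np.array([0.5, 0.3, 0.2, 0.15, 0.1][:n_populations], dtype=float)
    weights = weights / weights.sum()
    populations = []
    for i in range(n_populations):
        populations.append(
            PopulationSpec(
                name=f"pop{i + 1}",
                mixture_weight=float(weights[i]),
                zero_probability=rng.uniform(0.05, 0.5, size=n_channels),
                log_mean=rng.uniform(2.0, 5.0, size=n_channels),
                log_sd=rng.uniform(0.4, 0.9, size=n_channels),
            )
        )
    return populations


def default_batch_effects(
    n_batches: int,
    n_channels: int,
    affected_channels: list[int] | None = None,
    multiplier_range: tuple[float, float] = (0.5, 2.0),
    zero_shift_range: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    reference_batch: str = "batch1",
) -> BatchEffectSpec:
    """Random per-batch per-channel effects on a subset of channels.

    Multipliers are drawn log-uniformly in ``multiplier_range`` (so up- and
    down-scaling are equally likely); unaffected channels and the reference
    batch stay at identity.
    """
    rng = np.random.default_rng(seed)
    if affected_channels is None:
        affected_channels = list(range(n_channels))
    multipliers: dict[str, np.ndarray] = {}
    zero_shift: dict[str, np.ndarray] = {}
    lo, hi = np.log(multiplier_range[0]), np.log(multiplier_range[1])
    for b in range(1, n_batches + 1):
        batch = f"batch{b}"
        m = np.ones(n_channels)
        s = np.zeros(n_channels)
        if batch != reference_batch:
            m[affected_channels] = np.exp(
                rng.uniform(lo, hi, size=len(affected_channels))
            )
            if zero_shift_range != (0.0, 0.0):
                s[affected_channels] = rng.uniform(
                    zero_shift_range[0], zero_shift_range[1],
                    size=len(affected_channels),
                )
        multipliers[batch] = m
        zero_shift[batch] = s
    return BatchEffectSpec(
        multipliers=multipliers, zero_shift=zero_shift,
        reference_batch=reference_batch,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _sample_events(
    rng: np.random.Generator,
    populations: list[PopulationSpec],
    weights: np.ndarray,
    n_events: int,
    multiplier: np.ndarray,
    zero_shift: np.ndarray,
    log_mean_shift: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one sample's event matrix; returns (data, realized fractions)."""
    n_channels = populations[0].n_channels
    counts = rng.multinomial(n_events, weights)
    blocks = []
    for pop, count in zip(populations, counts):
        if count == 0:
            blocks.append(np.empty((0, n_channels)))
            continue
        mu = pop.log_mean if log_mean_shift is None else pop.log_mean + log_mean_shift
        positive = rng.lognormal(mean=mu, sigma=pop.log_sd, size=(count, n_channels))
        zero_p = np.clip(pop.zero_probability + zero_shift, 0.0, 0.999)
        zeros = rng.random((count, n_channels)) < zero_p
        block = np.where(zeros, 0.0, positive * multiplier)
        blocks.append(block)
    data = np.vstack(blocks)
    rng.shuffle(data, axis=0)
    return data, counts / n_events


def generate_experiment(
    populations: list[PopulationSpec],
    effects: BatchEffectSpec,
    n_batches: int,
    events_per_sample: int,
    samples_per_batch: int = 1,
    seed: int = 0,
    include_validation_anchor: bool = False,
    stim_channels: list[int] | None = None,
    unstim_log_mean_shift: float = -1.5,
    study_weight_concentration: float = 200.0,
    channel_prefix: str = "Ch",
) -> tuple[list[EventTable], SyntheticTruth]:
    """Generate a multi-batch experiment with replicate anchors.

    Per batch: one anchor drawn from the shared base mixture (condition
    ``"stim"``), optionally one validation replicate (condition
    ``"unstim"``, role ``"study"``) in which ``stim_channels`` have their
    log-mean shifted by ``unstim_log_mean_shift`` — emulating cytokine
    channels that only light up under stimulation — plus
    ``samples_per_batch`` study samples whose mixture weights are Dirichlet
    perturbations of the base weights (biological variability). All samples
    of a batch receive that batch's multiplicative and zero-shift
    distortion. Fully reproducible from ``seed``.
    """
    if n_batches < 2:
        raise ValueError("n_batches must be >= 2")
    if events_per_sample < 100:
        raise ValueError("events_per_sample must be >= 100")
    if samples_per_batch < 0:
        raise ValueError("samples_per_batch must be >= 0")
    weights = np.array([p.mixture_weight for p in populations])
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("population mixture weights must sum to 1")
    n_channels = populations[0].n_channels
    if any(p.n_channels != n_channels for p in populations):
        raise ValueError("all populations must share the channel count")
    batch_ids = [f"batch{b}" for b in range(1, n_batches + 1)]
    for batch in batch_ids:
        if batch not in effects.multipliers:
            raise ValueError(f"effects missing batch {batch!r}")
        if effects.multipliers[batch].size != n_channels:
            raise ValueError(f"effects for {batch!r} have wrong channel count")

    rng = np.random.default_rng(seed)
    channels = [(f"{channel_prefix}{j + 1}", f"marker{j + 1}") for j in range(n_channels)]
    unstim_shift = None
    if include_validation_anchor:
        unstim_shift = np.zeros(n_channels)
        if stim_channels is None:
            stim_channels = list(range(3 * n_channels // 4, n_channels))
        unstim_shift[stim_channels] = unstim_log_mean_shift

    tables: list[EventTable] = []
    truth = SyntheticTruth(
        populations=populations, effects=effects, seed=seed,
        events_per_sample={}, fractions={},
    )

    def add(sample_id: str, batch: str, role: str, condition: str | None,
            data: np.ndarray, fractions: np.ndarray) -> None:
        tables.append(
            EventTable(sample_id=sample_id, batch_id=batch, role=role,
                       channels=list(channels), data=data, condition=condition)
        )
        truth.events_per_sample[sample_id] = data.shape[0]
        truth.fractions[sample_id] = fractions
        truth.roles[sample_id] = role
        if condition:
            truth.conditions[sample_id] = condition

    for batch in batch_ids:
        multiplier = effects.multipliers[batch]
        zero_shift = effects.zero_shift.get(batch, np.zeros(n_channels))
        data, fractions = _sample_events(
            rng, populations, weights, events_per_sample, multiplier, zero_shift
        )
        add(f"{batch}_anchor", batch, "anchor", "stim", data, fractions)
        if include_validation_anchor:
            data, fractions = _sample_events(
                rng, populations, weights, events_per_sample, multiplier,
                zero_shift, log_mean_shift=unstim_shift,
            )
            add(f"{batch}_anchor_unstim", batch, "study", "unstim", data, fractions)
        for s in range(1, samples_per_batch + 1):
            sample_weights = rng.dirichlet(weights * study_weight_concentration)
            data, fractions = _sample_events(
                rng, populations, sample_weights, events_per_sample, multiplier,
                zero_shift,
            )
            add(f"{batch}_s{s:02d}", batch, "study", None, data, fractions)

    return tables, truth


def true_fraction_matrix(truth: SyntheticTruth, role_filter: str = "anchor",
                         condition: str | None = None) -> ReplicateFeatureMatrix:
    """Realized (sampled) population-fraction matrix for one role, the
    ground-truth analog of a gated subpopulation fraction table."""
    ids = [
        s for s, r in truth.roles.items()
        if r == role_filter and (condition is None or truth.conditions.get(s) == condition)
    ]
    if not ids:
        raise ValueError(f"no samples with role {role_filter!r}")
    values = np.array([truth.fractions[s] for s in ids])
    return ReplicateFeatureMatrix(
        replicate_ids=ids,
        feature_ids=[p.name for p in truth.populations],
        values=values,
        fractions=True,
    )


# ---------------------------------------------------------------------------
# Spec files and on-disk experiments
# ---------------------------------------------------------------------------

def load_spec(path: str) -> tuple[list[PopulationSpec], BatchEffectSpec]:
    """Load populations and batch effects from a YAML or JSON spec file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    populations = [
        PopulationSpec(
            name=p["name"],
            mixture_weight=p["mixture_weight"],
            zero_probability=np.asarray(p["zero_probability"]),
            log_mean=np.asarray(p["log_mean"]),
            log_sd=np.asarray(p["log_sd"]),
        )
        for p in raw["populations"]
    ]
    eff = raw["effects"]
    effects = BatchEffectSpec(
        multipliers={b: np.asarray(m) for b, m in eff["multipliers"].items()},
        zero_shift={b: np.asarray(s) for b, s in eff.get("zero_shift", {}).items()},
        reference_batch=eff.get("reference_batch", ""),
    )
    return populations, effects


def write_experiment(tables: list[EventTable], truth: SyntheticTruth,
                     out_dir: str) -> list[str]:
    """Write an experiment as FCS files plus a truth JSON and manifest CSV."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    rows = []
    for table in tables:
        path = os.path.join(out_dir, f"{table.sample_id}.fcs")
        write_fcs(table, path)
        paths.append(path)
        rows.append((path, table.batch_id, table.role, table.condition or ""))
    truth.to_json(os.path.join(out_dir, "truth.json"))
    import csv

    with open(os.path.join(out_dir, "manifest.csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["file_path", "batch_id", "role", "condition"])
        writer.writerows(rows)
    return paths
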