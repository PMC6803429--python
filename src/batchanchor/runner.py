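"""Batch discovery and rolling per-batch adjustment orchestration.

A run takes a manifest of FCS files (explicit CSV, or discovered from
filename conventions), computes each batch's per-channel factors from its
anchor against the reference batch's anchor, applies them to every sample
of the batch, and writes adjusted FCS files plus the factor table, a plain
text log and a JSON summary. Batches are processed independently of each
other, so the run can proceed on a rolling basis: re-running on a superset
of batches reproduces the previously written outputs bit-identically as
long as the reference batch and config are unchanged.
"""

from __future__ import annotations

import json
import os
import re
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import adjust as _adj
from .adjust import (
    AdjustmentConfig,
    ScaleFactorRecord,
    SkipChannel,
    QuantileMap,
    adjust_sample,
    build_quantile_map,
    compute_scale_factor,
    save_records,
)
from .fcs_io import EventTable, read_fcs, write_fcs

__all__ = [
    "BatchManifest",
    "ManifestRow",
    "discover_batches",
    "run_adjustment",
    "emit_diagnostics",
    "RunResult",
]


@dataclass
class ManifestRow:
    file_path: str
    batch_id: str
    role: str  # 'anchor' | 'study'
    condition: str = ""


@dataclass
class BatchManifest:
    """Files grouped into batches, with exactly one calibration anchor each."""

    rows: list[ManifestRow]
    reference_batch: str

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.rows:
            raise ValueError("manifest is empty")
        paths = [r.file_path for r in self.rows]
        if len(set(paths)) != len(paths):
            raise ValueError("manifest contains duplicate file paths")
        missing = [p for p in paths if not os.path.exists(p)]
        if missing:
            raise FileNotFoundError(f"manifest files not found: {missing[:5]}")
        batches = self.batch_ids()
        if self.reference_batch not in batches:
            raise ValueError(
                f"reference batch {self.reference_batch!r} not among {batches}"
            )
        for batch in batches:
            anchors = [
                r for r in self.rows if r.batch_id == batch and r.role == "anchor"
            ]
            if len(anchors) != 1:
                names = [os.path.basename(r.file_path) for r in anchors]
                raise ValueError(
                    f"batch {batch!r} must have exactly one anchor, found "
                    f"{len(anchors)}: {names}"
                )

    def batch_ids(self) -> list[str]:
        return sorted({r.batch_id for r in self.rows})

    def anchor_row(self, batch_id: str) -> ManifestRow:
        return next(
            r for r in self.rows if r.batch_id == batch_id and r.role == "anchor"
        )

    def batch_rows(self, batch_id: str) -> list[ManifestRow]:
        return sorted(
            (r for r in self.rows if r.batch_id == batch_id),
            key=lambda r: r.file_path,
        )

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            [(r.file_path, r.batch_id, r.role, r.condition) for r in self.rows],
            columns=["file_path", "batch_id", "role", "condition"],
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str, reference_batch: str) -> "BatchManifest":
        frame = pd.read_csv(path, keep_default_na=False)
        rows = [
            ManifestRow(
                file_path=str(r.file_path),
                batch_id=str(r.batch_id),
                role=str(r.role),
                condition=str(getattr(r, "condition", "")),
            )
            for r in frame.itertuples(index=False)
        ]
        return cls(rows=rows, reference_batch=reference_batch)


def discover_batches(
    directory: str,
    anchor_token: str,
    batch_pattern: str,
    reference_batch: str,
) -> BatchManifest:
    """Build a manifest from filename conventions.

    ``batch_pattern`` is a regex with one capture group yielding the batch
    id; files whose basename contains ``anchor_token`` (case-insensitive)
    are anchors. Files not matching the pattern are excluded with a
    warning. Ordering is lexicographic, hence deterministic.
    """
    if not os.path.isdir(directory):
        raise FileNotFoundError(f"directory {directory!r} does not exist")
    pattern = re.compile(batch_pattern)
    if pattern.groups != 1:
        raise ValueError("batch_pattern must have exactly one capture group")
    rows = []
    for name in sorted(os.listdir(directory)):
        if not name.lower().endswith(".fcs"):
            continue
        match = pattern.search(name)
        if match is None:
            import warnings

            warnings.warn(f"file {name!r} does not match batch pattern; excluded")
            continue
        role = "anchor" if anchor_token.lower() in name.lower() else "study"
        rows.append(
            ManifestRow(
                file_path=os.path.join(directory, name),
                batch_id=match.group(1),
                role=role,
            )
        )
    if not rows:
        raise ValueError(f"no batches found in {directory!r}")
    return BatchManifest(rows=rows, reference_batch=reference_batch)


# ---------------------------------------------------------------------------
# Run
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    records: list[ScaleFactorRecord]
    log_path: str
    out_paths: list[str]
    failures: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


class _Log:
    def __init__(self, path: str):
        self.path = path
        self.lines: list[str] = []

    def write(self, message: str) -> None:
        stamp = time.strftime("%Y-%m-%d %H:%M:%S")
        self.lines.append(f"{stamp}  {message}")

    def flush(self) -> None:
        with open(self.path, "w") as fh:
            fh.write("\n".join(self.lines) + "\n")


def compute_batch_record(
    ref_anchor: EventTable, batch_anchor: EventTable, config: AdjustmentConfig
) -> ScaleFactorRecord:
    """Calibrate one batch's per-channel entries from its anchor pair.

    The reference batch gets factor 1 (or an identity contract via the
    passthrough in :func:`~batchanchor.adjust.adjust_sample`); factors are
    computed once per (batch, channel) from anchors only, never from study
    samples.
    """
    record = ScaleFactorRecord(
        batch_id=batch_anchor.batch_id, method=config.method, space=config.space
    )
    is_reference = batch_anchor.batch_id == config.reference_batch
    for channel in config.channels_to_adjust:
        ref_values = ref_anchor.channel_values(channel)
        if is_reference:
            record.entries[channel] = 1.0
            continue
        batch_values = batch_anchor.channel_values(channel)
        if config.method == "quantile_norm":
            record.entries[channel] = build_quantile_map(
                ref_values, batch_values, n_knots=config.qn_n_knots,
                zero_handling=config.qn_zero_handling,
            )
        else:
            record.entries[channel] = compute_scale_factor(
                ref_values, batch_values, config
            )
    record.validate()
    return record


def run_adjustment(
    manifest: BatchManifest, config: AdjustmentConfig, out_dir: str
) -> RunResult:
    """Adjust every file in the manifest, batch by batch.

    Writes one adjusted FCS per input into ``out_dir`` (reference-batch
    files pass through value-identically), persists the factor table
    (``scale_factors.csv`` + quantile-map sidecar), and logs every batch
    found, every sample processed with its wall time, and every skipped
    channel with its reason. A channel mismatch in one file is recorded as
    a failure and the run continues.
    """
    if config.reference_batch != manifest.reference_batch:
        raise ValueError("config and manifest disagree on the reference batch")
    os.makedirs(out_dir, exist_ok=True)
    log = _Log(os.path.join(out_dir, "adjustment.log"))
    log.write(
        f"run start: method={config.method} p={config.percentile_p} "
        f"space={config.space} reference={config.reference_batch}"
    )

    ref_anchor = read_fcs(manifest.anchor_row(manifest.reference_batch).file_path)
    ref_anchor.batch_id = manifest.reference_batch

    records: list[ScaleFactorRecord] = []
    out_paths: list[str] = []
    failures: list[tuple[str, str]] = []
    for batch in manifest.batch_ids():
        log.write(f"batch found: {batch} ({len(manifest.batch_rows(batch))} files)")
        anchor_row = manifest.anchor_row(batch)
        try:
            anchor = read_fcs(anchor_row.file_path)
            anchor.batch_id = batch
            anchor.role = "anchor"
            record = compute_batch_record(ref_anchor, anchor, config)
        except Exception as exc:  # noqa: BLE001 - per-batch isolation
            failures.append((anchor_row.file_path, str(exc)))
            log.write(f"batch {batch} FAILED during calibration: {exc}")
            continue
        records.append(record)
        for channel, reason in sorted(record.skipped_channels().items()):
            log.write(f"batch {batch} channel {channel} skipped: {reason}")
        for row in manifest.batch_rows(batch):
            started = time.perf_counter()
            out_path = os.path.join(out_dir, os.path.basename(row.file_path))
            try:
                table = read_fcs(row.file_path)
                table.batch_id = batch
                table.role = row.role
                if row.condition:
                    table.condition = row.condition
                adjusted = adjust_sample(table, record, config)
                write_fcs(adjusted, out_path)
            except Exception as exc:  # noqa: BLE001 - per-file isolation
                failures.append((row.file_path, str(exc)))
                log.write(f"sample {os.path.basename(row.file_path)} FAILED: {exc}")
                continue
            out_paths.append(out_path)
            elapsed = time.perf_counter() - started
            log.write(
                f"sample processed: {os.path.basename(row.file_path)} "
                f"({table.n_events} events, {elapsed:.3f}s)"
            )

    save_records(
        records,
        os.path.join(out_dir, "scale_factors.csv"),
        os.path.join(out_dir, "quantile_maps.json"),
    )
    log.write(f"run end: {len(out_paths)} files written, {len(failures)} failures")
    log.flush()
    summary = {
        "batches": manifest.batch_ids(),
        "reference_batch": manifest.reference_batch,
        "method": config.method,
        "space": config.space,
        "files_written": len(out_paths),
        "failures": [{"file": f, "error": e} for f, e in failures],
    }
    with open(os.path.join(out_dir, "adjustment_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    return RunResult(
        records=records, log_path=log.path, out_paths=out_paths, failures=failures
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def emit_diagnostics(
    records: list[ScaleFactorRecord],
    anchors_pre: list[EventTable],
    anchors_post: list[EventTable],
    out_dir: str,
) -> list[str]:
    """Graphical diagnostics for a finished run.

    Emits (a) one scaling-factor overview figure (channels x batches) for
    spotting outlier batches or mislabeled channels, (b) one density
    figure per adjusted channel overlaying all batch anchors pre and post,
    and (c) the factor table CSV. Skipped channels are annotated, not
    omitted. Output is deterministic given the inputs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out_dir, exist_ok=True)
    paths: list[str] = []

    channels = sorted({ch for r in records for ch in r.entries})
    batches = [r.batch_id for r in records]
    grid = np.full((len(channels), len(batches)), np.nan)
    skipped_cells = []
    for j, record in enumerate(records):
        for i, channel in enumerate(channels):
            entry = record.entries.get(channel)
            if isinstance(entry, SkipChannel):
                skipped_cells.append((i, j))
            elif isinstance(entry, QuantileMap):
                grid[i, j] = np.nan
            elif entry is not None:
                grid[i, j] = float(entry)

    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.6 * len(batches) + 2), max(3.0, 0.3 * len(channels) + 1))
    )
    image = ax.imshow(grid, aspect="auto", cmap="coolwarm")
    ax.set_xticks(range(len(batches)), batches, rotation=90, fontsize=7)
    ax.set_yticks(range(len(channels)), channels, fontsize=7)
    for i, j in skipped_cells:
        ax.text(j, i, "skipped", ha="center", va="center", fontsize=6)
    fig.colorbar(image, ax=ax, label="scale factor")
    ax.set_title("Per-channel scale factors by batch")
    fig.tight_layout()
    overview = os.path.join(out_dir, "scale_factor_overview.png")
    fig.savefig(overview, dpi=110)
    plt.close(fig)
    paths.append(overview)

    pre_by_batch = {t.batch_id: t for t in anchors_pre}
    post_by_batch = {t.batch_id: t for t in anchors_post}
    skipped_by_channel = {
        ch: r.batch_id
        for r in records
        for ch in r.skipped_channels()
    }
    for channel in channels:
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.2), sharex=True, sharey=True)
        for title, axis, tables in (
            ("pre-adjustment", axes[0], pre_by_batch),
            ("post-adjustment", axes[1], post_by_batch),
        ):
            for batch in batches:
                table = tables.get(batch)
                if table is None or channel not in table.channel_names:
                    continue
                values = np.arcsinh(table.channel_values(channel) / 5.0)
                hist, edges = np.histogram(values, bins=60, density=True)
                centers = 0.5 * (edges[:-1] + edges[1:])
                axis.plot(centers, hist, lw=0.8, label=batch)
            axis.set_title(f"{channel} {title}", fontsize=9)
            axis.set_xlabel("arcsinh(x/5)")
        if channel in skipped_by_channel:
            axes[1].annotate(
                "skipped in some batches", xy=(0.5, 0.9),
                xycoords="axes fraction", ha="center", fontsize=8, color="red",
            )
        axes[0].set_ylabel("density")
        fig.tight_layout()
        path = os.path.join(out_dir, f"channel_{channel}_density.png")
        fig.savefig(path, dpi=110)
        plt.close(fig)
        paths.append(path)

    table_path = os.path.join(out_dir, "scale_factors.csv")
    _adj.records_to_frame(records).to_csv(table_path, index=False)
    paths.append(table_path)
    return paths
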