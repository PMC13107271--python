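"""Detection-table ingestion and result serialization.

Detection CSVs are comma-separated UTF-8 with a header and three columns:
``timestamp`` (ISO-8601 datetime or decimal hour-of-day), ``verified``
(true/false) and ``label`` (true/false, present exactly when verified).
Dates are discarded after extracting local clock time — the models describe
time-of-day only; any time-zone or solar-time conversion is the caller's
responsibility.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ActivityHistogram, TimeGrid, assign_bin
from .model import (
    STATUS_UNVERIFIED,
    STATUS_VERIFIED_FALSE,
    STATUS_VERIFIED_TRUE,
    DetectionDataset,
    PosteriorFit,
    posterior_activity,
)
from .simulate import SimulatedDataset

__all__ = [
    "read_detections",
    "write_detections",
    "write_truth",
    "read_histogram",
    "write_histogram",
    "write_fit",
]

logger = logging.getLogger(__name__)

_TRUE_STRINGS = {"true", "t", "1", "yes", "y"}
_FALSE_STRINGS = {"false", "f", "0", "no", "n"}


def _parse_bool(value, column: str, row: int) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS:
        return False
    raise ValueError(f"cannot parse {column}={value!r} as boolean on row {row}")


def _parse_hour(value, row: int) -> float:
    """Decimal hour-of-day, or clock time extracted from an ISO datetime."""
    try:
        hour = float(value)
    except (TypeError, ValueError):
        ts = pd.to_datetime(str(value), errors="coerce")
        if pd.isna(ts):
            raise ValueError(
                f"cannot parse timestamp {value!r} on row {row}"
            ) from None
        return (
            ts.hour + ts.minute / 60.0 + ts.second / 3600.0
            + ts.microsecond / 3.6e9
        )
    if not np.isfinite(hour) or hour < 0.0 or hour > 24.0:
        raise ValueError(f"decimal hour {value!r} out of [0, 24] on row {row}")
    return hour


def read_detections(path, grid: TimeGrid | None = None) -> DetectionDataset:
    """Read a detection CSV into a :class:`DetectionDataset`.

    Rows are preserved in input order. Raises on missing columns, unparseable
    values (citing the 1-based data row) and verified rows without a label.
    """
    if grid is None:
        grid = TimeGrid()
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for column in ("timestamp", "verified", "label"):
        if column not in frame.columns:
            raise ValueError(f"detection file {path} is missing column {column!r}")

    bins = np.empty(len(frame), dtype=np.int64)
    status = np.empty(len(frame), dtype=np.int64)
    for i, record in enumerate(frame.itertuples(index=False)):
        row = i + 1
        hour = _parse_hour(record.timestamp, row)
        bins[i] = assign_bin(hour, grid)
        verified = _parse_bool(record.verified, "verified", row)
        label_text = str(record.label).strip()
        if verified:
            if not label_text:
                raise ValueError(f"verified row {row} has no label")
            label = _parse_bool(record.label, "label", row)
            status[i] = STATUS_VERIFIED_TRUE if label else STATUS_VERIFIED_FALSE
        else:
            status[i] = STATUS_UNVERIFIED

    dataset = DetectionDataset(bins=bins, status=status, grid=grid)
    logger.info(
        "read %d detections from %s: %d verified true, %d verified false, "
        "%d unverified",
        len(frame),
        path,
        int((status == STATUS_VERIFIED_TRUE).sum()),
        int((status == STATUS_VERIFIED_FALSE).sum()),
        int((status == STATUS_UNVERIFIED).sum()),
    )
    return dataset


def write_detections(path, sim: SimulatedDataset) -> None:
    """Write a simulated dataset as a detection CSV (ground truth withheld:
    labels appear only for verified records)."""
    label = np.where(
        sim.verified, np.where(sim.is_true, "true", "false"), ""
    )
    frame = pd.DataFrame(
        {
            "timestamp": [format(t, ".6f") for t in sim.times],
            "verified": np.where(sim.verified, "true", "false"),
            "label": label,
        }
    )
    frame.to_csv(path, index=False)


def write_truth(path, sim: SimulatedDataset) -> None:
    """Write the simulator's ground truth (per-record flags) alongside a
    detection CSV."""
    frame = pd.DataFrame(
        {
            "timestamp": [format(t, ".6f") for t in sim.times],
            "bin": sim.bins,
            "is_true": np.where(sim.is_true, "true", "false"),
            "verified": np.where(sim.verified, "true", "false"),
        }
    )
    frame.to_csv(path, index=False)


def read_histogram(path) -> ActivityHistogram:
    """Read a histogram CSV (columns ``bin`` and ``proportion``)."""
    frame = pd.read_csv(path)
    for column in ("bin", "proportion"):
        if column not in frame.columns:
            raise ValueError(f"histogram file {path} is missing column {column!r}")
    frame = frame.sort_values("bin")
    return ActivityHistogram(frame["proportion"].to_numpy(dtype=float))


def write_histogram(path, hist: ActivityHistogram, lower=None, upper=None) -> None:
    """Write a histogram CSV, optionally with 95% interval columns."""
    data = {"bin": np.arange(len(hist)), "proportion": hist.probs}
    if lower is not None and upper is not None:
        data["lower95"] = np.asarray(lower, dtype=float)
        data["upper95"] = np.asarray(upper, dtype=float)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")


def write_fit(path, fitted: PosteriorFit) -> tuple[Path, Path]:
    """Serialize a converged fit: a JSON summary plus a per-bin histogram CSV.

    Returns the two paths written. Output is deterministic for a fixed fit.
    """
    if fitted.report is None or not fitted.report.passed:
        raise ValueError("write_fit requires a fit that passed diagnostics")
    path = Path(path)
    json_path = path if path.suffix == ".json" else path.with_suffix(".json")
    csv_path = json_path.with_name(json_path.stem + "_histogram.csv")

    mean_hist, lower, upper = posterior_activity(fitted)
    lo, hi = fitted.theta_interval()
    summary = {
        "model": fitted.spec.error_structure,
        "n_bins": fitted.grid.n_bins,
        "theta": {
            "mean": fitted.theta_mean,
            "lower95": lo,
            "upper95": hi,
        },
        "sampler": {
            "chains": fitted.settings.chains,
            "iterations": fitted.settings.iterations,
            "warmup": fitted.settings.warmup,
            "seed": fitted.settings.seed,
        },
        "diagnostics": {
            "passed": fitted.report.passed,
            "max_rhat": fitted.report.max_rhat,
            "min_ess": fitted.report.min_ess,
            "rhat": fitted.report.rhat,
            "ess": fitted.report.ess,
        },
        "prior": {
            "beta": list(fitted.spec.beta_prior),
            "dirichlet_concentration": np.broadcast_to(
                np.asarray(fitted.spec.dirichlet_concentration, dtype=float),
                (fitted.grid.n_bins,),
            ).tolist(),
        },
    }
    with open(json_path, "w", encoding="utf-8") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
    write_histogram(csv_path, mean_hist, lower, upper)
    return json_path, csv_path
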