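"""Readers and writers for heart-rate tables and result artefacts.

Input is a delimiter-separated text table with a header row and three named
columns — ``participant_id``, ``minute_index``, ``heart_rate_bpm`` — one row
per participant-minute.  ``minute_index`` is either a 1-based integer or an
ISO-8601 timestamp (floored to the minute).  All outputs are plain
delimiter-separated text or YAML, written deterministically: rerunning on
identical inputs produces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ar_core import HeartRateSeries
from .cohort import ClusterAssignment, CohortTable, participant_sort_key
from .config import RunConfig
from .exceptions import GapError, TableParseError
from .rolling import RollingFitResult
from .synthetic import SyntheticSpec

__all__ = [
    "read_hr_table",
    "write_outputs",
    "write_fixture",
    "REQUIRED_COLUMNS",
]

logger = logging.getLogger("hrtwin")

REQUIRED_COLUMNS = ("participant_id", "minute_index", "heart_rate_bpm")


def _minutes_from_index(raw: pd.Series, pid: str) -> np.ndarray:
    """Integer minute indices from an integer or ISO-8601 timestamp column."""
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.notna().all():
        idx = numeric.to_numpy()
        if not np.allclose(idx, np.round(idx)):
            raise TableParseError(
                f"participant {pid!r}: minute_index must be integral"
            )
        idx = np.round(idx).astype(np.int64)
        if np.any(idx < 1):
            raise TableParseError(
                f"participant {pid!r}: minute_index must be >= 1 (1-based)"
            )
        return idx
    try:
        ts = pd.to_datetime(raw, format="ISO8601").dt.floor("min")
    except (ValueError, TypeError) as exc:
        raise TableParseError(
            f"participant {pid!r}: minute_index is neither integer nor "
            f"ISO-8601 timestamp ({exc})"
        ) from exc
    idx = ((ts - ts.iloc[0]).dt.total_seconds() / 60.0).astype(np.int64) + 1
    if idx.duplicated().any():
        dup = ts[idx.duplicated()].iloc[0]
        raise TableParseError(
            f"participant {pid!r}: duplicate minute after flooring timestamps "
            f"({dup})"
        )
    return idx.to_numpy()


def _apply_gap_policy(
    minutes: np.ndarray, bpm: np.ndarray, pid: str, config: RunConfig
) -> np.ndarray:
    """Contiguous bpm values starting at the participant's first minute."""
    gaps = np.diff(minutes) - 1
    if not np.any(gaps > 0):
        return bpm
    if config.gap_policy == "error":
        at = minutes[np.argmax(gaps > 0)] + 1
        raise GapError(
            f"participant {pid!r}: missing minute {at} under strict gap policy"
        )
    too_long = gaps > config.max_gap_fill
    if np.any(too_long):
        j = int(np.argmax(too_long))
        raise GapError(
            f"participant {pid!r}: gap of {int(gaps[j])} min after minute "
            f"{int(minutes[j])} exceeds max_gap_fill={config.max_gap_fill}"
        )
    n_total = int(minutes[-1] - minutes[0] + 1)
    filled = np.empty(n_total)
    pos = minutes - minutes[0]
    filled[:] = np.nan
    filled[pos] = bpm
    filled = pd.Series(filled).ffill().to_numpy()
    for j in np.flatnonzero(gaps > 0):
        logger.warning(
            "participant %r: forward-filled %d missing minute(s) after minute %d",
            pid,
            int(gaps[j]),
            int(minutes[j]),
        )
    return filled


def read_hr_table(path: str | Path, config: RunConfig) -> list[HeartRateSeries]:
    """Read a heart-rate table into one series per participant.

    Rows with out-of-bounds bpm are dropped (logged); gaps are then handled
    per ``config.gap_policy``; finally each participant is truncated to the
    first ``config.window`` minutes.  Participants are returned in natural
    id order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype={"participant_id": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TableParseError(f"{path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TableParseError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise TableParseError(f"{path}: no data rows")

    out: list[HeartRateSeries] = []
    for pid, grp in df.groupby("participant_id", sort=False):
        bpm = pd.to_numeric(grp["heart_rate_bpm"], errors="coerce")
        if bpm.isna().any():
            line = int(grp.index[bpm.isna()][0]) + 2  # +1 header, +1 one-based
            raise TableParseError(
                f"{path}, line {line}: non-numeric heart_rate_bpm for "
                f"participant {pid!r}"
            )
        minutes = _minutes_from_index(grp["minute_index"], str(pid))
        if np.any(np.diff(minutes) <= 0):
            j = int(np.argmax(np.diff(minutes) <= 0))
            raise TableParseError(
                f"participant {pid!r}: minute_index not strictly increasing "
                f"at minute {int(minutes[j + 1])}"
            )
        in_bounds = (bpm >= config.bpm_low) & (bpm <= config.bpm_high)
        n_dropped = int((~in_bounds).sum())
        if n_dropped:
            logger.warning(
                "participant %r: dropped %d row(s) with bpm outside [%g, %g]",
                pid,
                n_dropped,
                config.bpm_low,
                config.bpm_high,
            )
        bpm_arr = bpm.to_numpy()[in_bounds.to_numpy()]
        minutes = minutes[in_bounds.to_numpy()]
        if bpm_arr.size == 0:
            raise TableParseError(
                f"participant {pid!r}: no in-bounds heart-rate rows remain"
            )
        values = _apply_gap_policy(minutes, bpm_arr, str(pid), config)
        if values.size > config.window:
            values = values[: config.window]
        out.append(HeartRateSeries(participant_id=str(pid), values=values))
    out.sort(key=lambda s: participant_sort_key(s.participant_id))
    return out


def _safe_name(pid: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in pid)


def write_outputs(
    table: CohortTable,
    clusters: ClusterAssignment,
    fits: dict[str, RollingFitResult],
    series: dict[str, HeartRateSeries],
    config: RunConfig,
    out_dir: str | Path,
) -> list[Path]:
    """Write all result artefacts for a cohort run.

    Produces, under ``out_dir``: the cohort summary table, the cluster
    assignment, one parameter-trajectory table and one predicted-vs-actual
    table per participant, and a YAML run manifest echoing every
    configuration value that affects the results.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = out_dir / "cohort_summary.csv"
    table.to_frame().to_csv(p, index=False)
    written.append(p)

    p = out_dir / "clusters.csv"
    clusters.to_frame().to_csv(p, index=False)
    written.append(p)

    for pid in sorted(fits, key=participant_sort_key):
        fit = fits[pid]
        tag = _safe_name(pid)
        traj = pd.DataFrame(
            fit.trajectory, columns=[f"a{i}" for i in range(fit.order + 1)]
        )
        traj.insert(0, "window_end_k", fit.fit_indices)
        p = out_dir / f"trajectory_{tag}.csv"
        traj.to_csv(p, index=False)
        written.append(p)

        actual = series[pid].values[fit.fit_indices]
        pred = pd.DataFrame(
            {
                "minute": fit.predicted_minutes,
                "actual_bpm": actual,
                "predicted_bpm": fit.predictions,
            }
        )
        p = out_dir / f"predictions_{tag}.csv"
        pred.to_csv(p, index=False)
        written.append(p)

    manifest = {
        "hrtwin_version": __version__,
        "config": config.to_dict(),
        "n_participants": len(table),
        "participants": table.participant_ids,
        "cluster_counts": {int(m): n for m, n in clusters.counts.items()},
    }
    p = out_dir / "manifest.yaml"
    p.write_text(yaml.safe_dump(manifest, sort_keys=True))
    written.append(p)
    return written


def write_fixture(
    fixture: list[tuple[HeartRateSeries, SyntheticSpec]], out_dir: str | Path
) -> tuple[Path, Path]:
    """Write a synthetic cohort as a heart-rate table plus a truth sidecar.

    ``heart_rate.csv`` is readable by :func:`read_hr_table`;
    ``truth.yaml`` records each participant's generating spec for
    recovery testing.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    truth: dict[str, dict] = {}
    for s, spec in fixture:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": s.participant_id,
                    "minute_index": np.arange(1, len(s) + 1),
                    "heart_rate_bpm": s.values,
                }
            )
        )
        d = dataclasses.asdict(spec)
        d["coefficients"] = [float(c) for c in d["coefficients"]]
        truth[s.participant_id] = d
    table_path = out_dir / "heart_rate.csv"
    pd.concat(frames, ignore_index=True).to_csv(table_path, index=False)
    truth_path = out_dir / "truth.yaml"
    truth_path.write_text(yaml.safe_dump(truth, sort_keys=True))
    return table_path, truth_path
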