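"""Cohort-level artefacts: the per-participant summary table and the
clustering of participants by best-fitting model complexity.

The "clustering" is deliberately an exact group-by on the integer order m —
no distance metric, no algorithmic clustering.  Grouping people whose heart
rate is best described by the same model complexity is an indicative,
preliminary way of exposing diversity in a cohort; it carries no clinical
interpretation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DuplicateParticipantError
from .rolling import ModelSummary, RollingFitResult, select_best_order

__all__ = [
    "CohortTable",
    "ClusterAssignment",
    "build_cohort_table",
    "cluster_by_complexity",
    "run_cohort",
    "participant_sort_key",
]


def participant_sort_key(pid: str):
    """Natural sort key: numeric runs compare as integers ('P 2' < 'P 10')."""
    return tuple(
        int(tok) if tok.isdigit() else tok
        for tok in re.split(r"(\d+)", pid)
        if tok != ""
    )


@dataclass(frozen=True)
class CohortTable:
    """Ordered per-participant model summaries with fixed-width parameter columns.

    Each row's parameter mean/SD columns run a_0..a_{m_max}; entries beyond
    the row's own order m are exact zeros (the fixed-width convention).
    """

    summaries: tuple[ModelSummary, ...] = field(repr=False)
    m_max: int

    def __len__(self) -> int:
        return len(self.summaries)

    @property
    def participant_ids(self) -> list[str]:
        return [s.participant_id for s in self.summaries]

    def to_frame(self) -> pd.DataFrame:
        """Render the table as a DataFrame (full-precision values)."""
        rows = []
        for s in self.summaries:
            row: dict[str, object] = {
                "participant_id": s.participant_id,
                "best_order": s.order,
                "err_bpm": s.err,
            }
            means = np.zeros(self.m_max + 1)
            sds = np.zeros(self.m_max + 1)
            means[: s.order + 1] = s.stability.means
            sds[: s.order + 1] = s.stability.sds
            for i in range(self.m_max + 1):
                row[f"a{i}_mean"] = means[i]
                row[f"a{i}_sd"] = sds[i]
            pv = np.full(self.m_max + 1, np.nan)
            pv[: s.order + 1] = s.pvalues
            for i in range(self.m_max + 1):
                row[f"a{i}_pvalue"] = pv[i]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_display_frame(self) -> pd.DataFrame:
        """Human-facing rendering: mean (+/- SD) at 3 significant figures."""

        def sig3(x: float) -> str:
            return "0" if x == 0 else f"{x:.3g}"

        rows = []
        for s in self.summaries:
            row = {
                "participant_id": s.participant_id,
                "best_order": s.order,
                "err_bpm": sig3(s.err),
            }
            for i in range(self.m_max + 1):
                if i <= s.order:
                    row[f"a{i}"] = (
                        f"{sig3(float(s.stability.means[i]))} "
                        f"(+/-{sig3(float(s.stability.sds[i]))})"
                    )
                else:
                    row[f"a{i}"] = "0"
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ClusterAssignment:
    """Participants grouped by the complexity m of their best-fitting model."""

    members: dict[int, tuple[str, ...]]  # m -> ids, each list in natural id order

    @property
    def counts(self) -> dict[int, int]:
        return {m: len(ids) for m, ids in self.members.items()}

    @property
    def n_participants(self) -> int:
        return sum(len(ids) for ids in self.members.values())

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per participant (complexity, id)."""
        rows = [
            {"complexity": m, "participant_id": pid}
            for m in sorted(self.members)
            for pid in self.members[m]
        ]
        return pd.DataFrame(rows, columns=["complexity", "participant_id"])


def build_cohort_table(summaries, m_max: int = 5) -> CohortTable:
    """Assemble per-participant summaries into a cohort table.

    Rows are sorted by participant id (natural order); ids must be unique.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("cohort table needs at least one participant summary")
    ids = [s.participant_id for s in summaries]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DuplicateParticipantError(f"duplicate participant ids: {dupes}")
    if any(s.order > m_max for s in summaries):
        raise ValueError("a summary's order exceeds m_max")
    ordered = sorted(summaries, key=lambda s: participant_sort_key(s.participant_id))
    return CohortTable(summaries=tuple(ordered), m_max=m_max)


def cluster_by_complexity(table: CohortTable) -> ClusterAssignment:
    """Group participants by their best-fitting model order m.

    Every participant lands in exactly one cluster; within a cluster the
    membership list follows natural participant-id order.
    """
    groups: dict[int, list[str]] = {}
    for s in table.summaries:
        groups.setdefault(s.order, []).append(s.participant_id)
    members = {
        m: tuple(sorted(ids, key=participant_sort_key))
        for m, ids in sorted(groups.items())
    }
    return ClusterAssignment(members=members)


def run_cohort(
    series_list,
    *,
    m_max: int = 5,
    eval_fraction: float = 0.2,
    stability_fraction: float = 0.2,
    window: int | None = 1440,
) -> tuple[CohortTable, ClusterAssignment, dict[str, RollingFitResult]]:
    """Full cohort pipeline: select the best order per participant, then group.

    Returns the cohort table, the complexity clustering, and each
    participant's best-order rolling fit (for trajectory/prediction export).
    """
    summaries = []
    fits: dict[str, RollingFitResult] = {}
    for series in series_list:
        summary = select_best_order(
            series,
            m_max,
            eval_fraction=eval_fraction,
            stability_fraction=stability_fraction,
            window=window,
        )
        assert summary.best_fit is not None
        fits[series.participant_id] = summary.best_fit
        summaries.append(summary)
    table = build_cohort_table(summaries, m_max=m_max)
    return table, cluster_by_complexity(table), fits
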