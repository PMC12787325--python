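"""Published reference values from a 23-person heart-failure pilot cohort.

A pilot study of at-home wearable monitoring fit per-minute AR models to the
first 24 h (1440 minutes) of smartwatch heart rate from 23 people with heart
failure and reported, per participant, the best-fitting model complexity m,
its tail mean-absolute error (Err, bpm) and the parameter means.  The raw
heart-rate streams themselves are not publicly available, so these printed
summary numbers are the only real-data anchor this package ships: they seed
the synthetic generator's presets and let the cohort clustering be checked
against the published grouping.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ReportedModel", "REPORTED_COHORT", "reported_best_orders"]


@dataclass(frozen=True)
class ReportedModel:
    """One participant's published best model: order, Err and parameter means."""

    participant_id: str
    best_order: int
    err_bpm: float
    intercept: float  # a_0 mean, bpm
    coefficients: tuple[float, ...]  # a_1..a_m means


REPORTED_COHORT: tuple[ReportedModel, ...] = (
    ReportedModel("Participant 1", 5, 6.84, 5.97, (0.0543, 0.0272, 0.121, -0.0997, 0.824)),
    ReportedModel("Participant 2", 1, 3.18, 6.55, (0.916,)),
    ReportedModel("Participant 3", 5, 6.32, 12.1, (0.0588, 0.0591, 0.0453, -0.0606, 0.744)),
    ReportedModel("Participant 4", 5, 4.49, 7.9, (0.0492, -0.0058, 0.119, -0.115, 0.85)),
    ReportedModel("Participant 5", 5, 7.07, 22.2, (0.0588, -0.0311, 0.0853, -0.141, 0.791)),
    ReportedModel("Participant 6", 3, 2.66, 6.16, (0.119, -0.0215, 0.82)),
    ReportedModel("Participant 7", 2, 6.57, 12.2, (-0.0176, 0.863)),
    ReportedModel("Participant 8", 3, 5.67, 17.2, (0.1, -0.00173, 0.664)),
    ReportedModel("Participant 9", 2, 5.36, 13.6, (0.0823, 0.726)),
    ReportedModel("Participant 10", 3, 2.56, 26.8, (0.144, -0.0494, 0.574)),
    ReportedModel("Participant 11", 5, 7.12, 39.7, (0.018, 0.067, 0.116, -0.026, 0.393)),
    ReportedModel("Participant 12", 3, 7.03, 16.1, (0.0699, -0.0265, 0.765)),
    ReportedModel("Participant 13", 5, 6.68, 10.7, (0.0499, -0.00481, 0.0387, 0.0275, 0.753)),
    ReportedModel("Participant 14", 5, 2.69, 34.8, (0.0981, -0.00785, 0.132, -0.00806, 0.406)),
    ReportedModel("Participant 15", 3, 3.42, 18.2, (0.0974, 0.0106, 0.657)),
    ReportedModel("Participant 16", 5, 6.55, 15.3, (0.0208, -0.0334, 0.094, 0.202, 0.526)),
    ReportedModel("Participant 17", 5, 3.98, 15.1, (0.0729, -0.031, 0.156, 0.0346, 0.577)),
    ReportedModel("Participant 18", 2, 4.09, 21.9, (0.0283, 0.699)),
    ReportedModel("Participant 19", 4, 7.22, 10.6, (0.0413, 0.101, -0.0816, 0.808)),
    ReportedModel("Participant 20", 2, 10.1, 24.6, (0.155, 0.542)),
    ReportedModel("Participant 21", 1, 8.44, 17.2, (0.785,)),
    ReportedModel("Participant 22", 5, 4.12, 17.0, (0.0855, -0.0608, 0.104, 0.159, 0.492)),
    ReportedModel("Participant 23", 1, 5.14, 90.3, (-0.00243,)),
)


def reported_best_orders() -> dict[str, int]:
    """Participant id -> published best-fitting model complexity m."""
    return {r.participant_id: r.best_order for r in REPORTED_COHORT}
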