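import dataclasses

import numpy as np
import pytest

import hrtwin as ht
from hrtwin.rolling import EvaluationResult, ModelSummary, ParameterStability


@pytest.fixture
def constant_series():
    return ht.HeartRateSeries("const", np.full(60, 70.0))


@pytest.fixture
def participant2_series():
    """One realization of the strongly persistent AR(1) preset."""
    spec = dataclasses.replace(ht.PRESETS["participant2"], seed=42)
    return ht.generate_ar_series(spec, participant_id="p2")


def make_summary(pid: str, m: int, err: float = 3.0) -> ModelSummary:
    """A minimal, hand-built per-participant summary for cohort-level tests."""
    means = np.linspace(1.0, 0.1, m + 1)
    return ModelSummary(
        participant_id=pid,
        order=m,
        evaluation=EvaluationResult(err=err, eval_count=10, eval_fraction=0.2),
        stability=ParameterStability(
            means=means, sds=np.zeros(m + 1), slice_fraction=0.2, n_used=10
        ),
        pvalues=np.full(m + 1, 0.001),
    )
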