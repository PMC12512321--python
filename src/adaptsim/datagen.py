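"""Complete simulated trial datasets (building block 3).

Composes the randomisation list, the accrual times and Bernoulli outcome
draws into one table with a row per participant:

====  ============================================================
obs_no        participant id, 1..n in accrual order
trt           arm indicator (0 control, 1 treatment)
accrual_time  recruitment time in days
event         binary outcome, available immediately at recruitment
====  ============================================================

The three random components are consumed from a single stream in a fixed
order — allocation permutations, then accrual times, then outcomes — so a
per-trial seed fully determines the dataset.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .accrual import simulate_accrual
from .allocation import simulate_randomisation
from .design import DesignParameters, Scenario, validate_scenario

__all__ = ["simulate_trial_data", "write_trial_data", "read_trial_data"]

BASE_COLUMNS = ["obs_no", "trt", "accrual_time", "event"]
INTERIM_COLUMNS = ["cum_events", "interim_flag", "event_interim"]


def simulate_trial_data(
    params: DesignParameters, scenario: Scenario, rng: np.random.Generator
) -> pd.DataFrame:
    """Simulate one trial's data under ``scenario``.

    Each participant's outcome is an independent Bernoulli draw with
    probability ``p0`` (control) or ``p1`` (treatment); outcomes are
    independent of accrual time (zero outcome lag).  Rows are ordered by
    accrual time, with the randomisation list applied to participants in
    that order.
    """
    validate_scenario(scenario)
    trt = simulate_randomisation(params, rng)
    accrual_time = simulate_accrual(params, rng)
    p = np.where(trt == 1, scenario.p1, scenario.p0)
    event = (rng.random(params.n) < p).astype(np.int64)
    return pd.DataFrame(
        {
            "obs_no": np.arange(1, params.n + 1),
            "trt": trt,
            "accrual_time": accrual_time,
            "event": event,
        }
    )


def write_trial_data(data: pd.DataFrame, path: str | Path) -> None:
    """Export a (possibly interim-annotated) trial dataset as CSV."""
    data.to_csv(path, index=False)


def read_trial_data(path: str | Path) -> pd.DataFrame:
    """Read a trial dataset written by :func:`write_trial_data`."""
    data = pd.read_csv(path)
    missing = set(BASE_COLUMNS) - set(data.columns)
    if missing:
        raise ValueError(f"trial data missing columns: {sorted(missing)}")
    return data
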