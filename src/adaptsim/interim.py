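"""Event-triggered interim selection (building block 4).

The interim analysis happens when a pre-specified cumulative number of
outcome events has occurred.  Because outcomes are available immediately
and rows are ordered by accrual time, the interim dataset is simply the
prefix of participants up to and including the one whose event is the
trigger-th event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["InterimSelection", "select_interim"]


@dataclass(frozen=True)
class InterimSelection:
    """Where (and whether) the interim trigger fell in one dataset."""

    reached: bool
    interim_ind: int | None = None  # obs_no of the trigger-th event
    interim_time: float | None = None  # accrual time of that participant (days)


def select_interim(
    data: pd.DataFrame, events_at_interim: int
) -> tuple[pd.DataFrame, InterimSelection]:
    """Annotate ``data`` with the interim dataset membership.

    Adds three columns: ``cum_events`` (running event total),
    ``interim_flag`` (1 for rows in the interim dataset) and
    ``event_interim`` (the outcome for interim rows, NaN afterwards —
    equal to ``event`` because there is no outcome lag).  The triggering
    participant is included in the interim dataset.

    If fewer than ``events_at_interim`` events ever occur the interim is
    never reached: no rows are flagged and the selection records
    ``reached=False``.

    Parameters
    ----------
    data
        Trial dataset ordered by accrual time.
    events_at_interim
        Cumulative event count that triggers the interim.

    Returns
    -------
    (annotated data copy, InterimSelection)
    """
    if len(data) == 0:
        raise ValueError("cannot select an interim dataset from an empty trial")
    if events_at_interim < 1:
        raise ValueError("events_at_interim must be >= 1")

    data = data.copy()
    cum = data["event"].to_numpy().cumsum()
    data["cum_events"] = cum

    hits = np.flatnonzero(cum >= events_at_interim)
    if hits.size == 0:
        data["interim_flag"] = 0
        data["event_interim"] = np.nan
        return data, InterimSelection(reached=False)

    idx = int(hits[0])  # positional index of the trigger-th event
    flag = np.zeros(len(data), dtype=np.int64)
    flag[: idx + 1] = 1
    data["interim_flag"] = flag
    data["event_interim"] = np.where(flag == 1, data["event"], np.nan)
    return data, InterimSelection(
        reached=True,
        interim_ind=int(data["obs_no"].iloc[idx]),
        interim_time=float(data["accrual_time"].iloc[idx]),
    )
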