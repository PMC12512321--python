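"""Participant recruitment times under constant accrual (building block 2).

Accrual is modelled as uniform over a fixed recruitment window: the n
recruitment times are the order statistics of n independent
Uniform(0, recruit_period) draws.  Ramp-up/ramp-down phases seen in real
multi-site trials can be supplied through the ``sampler`` hook; only the
uniform model is provided here.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .design import DesignParameters

__all__ = ["simulate_accrual"]

AccrualSampler = Callable[[int, float, np.random.Generator], np.ndarray]


def _uniform_sampler(n: int, period: float, rng: np.random.Generator) -> np.ndarray:
    return rng.random(n) * period


def simulate_accrual(
    params: DesignParameters,
    rng: np.random.Generator,
    sampler: AccrualSampler = _uniform_sampler,
) -> np.ndarray:
    """Draw and sort the ``n`` accrual times (days since trial start).

    ``sampler(n, recruit_period, rng)`` must return ``n`` unsorted times in
    ``[0, recruit_period]``; the default draws them uniformly.  Ties are
    kept in draw order by the stable sort (probability zero under
    continuous sampling).
    """
    times = np.asarray(sampler(params.n, params.recruit_period, rng), dtype=float)
    return np.sort(times, kind="stable")
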