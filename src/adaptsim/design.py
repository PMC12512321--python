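"""Trial design parameters and scenario definitions.

A design is fully specified by :class:`DesignParameters` (maximum sample
size, recruitment period, permuted-block structure, the event count that
triggers the interim analysis, and the efficacy thresholds spent at the
interim and final analyses).  A :class:`Scenario` is a named pair of true
event probabilities for the control and treatment arms; operating
characteristics are always estimated scenario by scenario.

The defaults reproduce the design of a two-arm paediatric intravenous
maintenance-fluid trial (binary hyponatraemia outcome) modified to include
a single interim analysis after 20 events: n = 584 recruited uniformly
over 928 days, 1:1 allocation in blocks of 4, efficacy declared at
p < 0.005 (interim) or p < 0.045 (final).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "DesignParameters",
    "Scenario",
    "DesignError",
    "pims_defaults",
    "pims_scenarios",
    "validate",
    "read_scenarios",
    "write_scenarios",
]


class DesignError(ValueError):
    """A design parameter or scenario violates an invariant."""


@dataclass(frozen=True)
class DesignParameters:
    """Fixed inputs of a two-arm design with one event-triggered interim.

    Parameters
    ----------
    n
        Maximum trial sample size (participants).
    recruit_period
        Recruitment duration in days; accrual is uniform over this window.
    events_at_interim
        Cumulative event count that triggers the interim analysis.
    alpha_interim, alpha_final
        Two-sided efficacy thresholds for the interim and final analyses.
        Both comparisons are strict (p < threshold).
    block_size
        Length of each permuted randomisation block.
    allocation
        Per-block participant counts ``(control, treatment)``; must sum to
        ``block_size``.  ``(2, 2)`` gives 1:1 allocation in blocks of 4.
    ci_level
        Confidence level for interval estimates.
    """

    n: int = 584
    recruit_period: float = 928.0
    events_at_interim: int = 20
    alpha_interim: float = 0.005
    alpha_final: float = 0.045
    block_size: int = 4
    allocation: tuple[int, int] = (2, 2)
    ci_level: float = 0.95

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["allocation"] = list(self.allocation)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DesignParameters":
        d = dict(d)
        if "allocation" in d:
            d["allocation"] = tuple(d["allocation"])
        return cls(**d)


@dataclass(frozen=True)
class Scenario:
    """True per-arm event probabilities under one hypothetical world."""

    name: str
    p0: float  # control-arm event probability
    p1: float  # treatment-arm event probability


def validate(params: DesignParameters) -> DesignParameters:
    """Return ``params`` unchanged if every invariant holds.

    Raises
    ------
    DesignError
        Naming the first violated invariant.
    """
    if not isinstance(params.n, int) or params.n < 1:
        raise DesignError("n must be a positive integer")
    if params.recruit_period <= 0:
        raise DesignError("recruit_period must be positive")
    if not isinstance(params.events_at_interim, int) or params.events_at_interim < 1:
        raise DesignError("events_at_interim must be a positive integer")
    if params.events_at_interim >= params.n:
        raise DesignError("interim trigger must be < n")
    if not 0.0 < params.alpha_interim < 1.0:
        raise DesignError("alpha_interim must lie in the open interval (0, 1)")
    if not 0.0 < params.alpha_final < 1.0:
        raise DesignError("alpha_final must lie in the open interval (0, 1)")
    if params.block_size < 2 or params.block_size % 2 != 0:
        raise DesignError("block_size must be a positive even integer")
    if len(params.allocation) != 2 or any(
        (not isinstance(a, int)) or a < 0 for a in params.allocation
    ):
        raise DesignError("allocation must be a pair of non-negative integers")
    if sum(params.allocation) != params.block_size:
        raise DesignError("allocation counts must sum to block_size")
    if not 0.0 < params.ci_level < 1.0:
        raise DesignError("ci_level must lie in the open interval (0, 1)")
    return params


def validate_scenario(scenario: Scenario) -> Scenario:
    """Return ``scenario`` unchanged if its probabilities and name are valid."""
    if not scenario.name:
        raise DesignError("scenario name must be non-empty")
    for label, p in (("p0", scenario.p0), ("p1", scenario.p1)):
        if not 0.0 <= p <= 1.0:
            raise DesignError(f"scenario {scenario.name!r}: {label} must lie in [0, 1]")
    return scenario


def pims_defaults() -> DesignParameters:
    """The modified PIMS design: n=584 over 928 days, interim at 20 events."""
    return validate(DesignParameters())


def pims_scenarios() -> list[Scenario]:
    """The four PIMS planning scenarios.

    A null scenario (no treatment effect, 10% event rate in both arms),
    the as-powered effect the sample size was computed for (10% vs 4%),
    and two extremes bracketing it (10% vs 6% and 10% vs 3%).
    """
    return [
        Scenario("Null", 0.10, 0.10),
        Scenario("As powered", 0.10, 0.04),
        Scenario("Smaller difference", 0.10, 0.06),
        Scenario("Larger difference", 0.10, 0.03),
    ]


def write_scenarios(scenarios: list[Scenario], path: str | Path) -> None:
    """Write a scenario set as delimited text with header ``name,p0,p1``."""
    _check_unique_names(scenarios)
    pd.DataFrame(
        [{"name": s.name, "p0": s.p0, "p1": s.p1} for s in scenarios]
    ).to_csv(path, index=False)


def read_scenarios(path: str | Path) -> list[Scenario]:
    """Read a ``name,p0,p1`` scenario file, validating every row."""
    # keep_default_na: a scenario legitimately named "null" must stay a string
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    missing = {"name", "p0", "p1"} - set(df.columns)
    if missing:
        raise DesignError(f"scenario file missing columns: {sorted(missing)}")
    scenarios = [
        validate_scenario(Scenario(str(r.name), float(r.p0), float(r.p1)))
        for r in df.itertuples(index=False)
    ]
    _check_unique_names(scenarios)
    return scenarios


def _check_unique_names(scenarios: list[Scenario]) -> None:
    names = [s.name for s in scenarios]
    if len(set(names)) != len(names):
        raise DesignError("scenario names must be unique")
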