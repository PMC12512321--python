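"""Summaries and operating characteristics of a Monte-Carlo run.

Two views of the same simulation output:

* :func:`summarise_run` — the six-number summary (minimum, Q1, median,
  mean, Q3, maximum) of every per-trial result variable, the table a
  design report prints for each scenario;
* :func:`extract_oc` — the scalar operating characteristics a designer
  steers by: probability of a conclusive trial (type I error under a
  null scenario, power otherwise), probability of stopping at the
  interim, expected sample size, flip-flop probability and mean final
  effect estimates.

:func:`scenario_grid` repeats a run over a scenario set with independent
seed derivations and tabulates one row of operating characteristics per
scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .design import DesignParameters, Scenario
from .engine import SimulationRun, derive_seeds, run_multiple_trials

__all__ = [
    "OperatingCharacteristics",
    "summarise_run",
    "extract_oc",
    "scenario_grid",
]

SUMMARY_STATS = ["minimum", "q1", "median", "mean", "q3", "maximum"]


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Scalar design metrics aggregated over simulated trials.

    ``p_success`` is the mean of the ``stop`` indicator: the type I error
    under a null scenario, the power otherwise.  Odds-ratio means are
    taken over trials with a non-degenerate final fit; ``n_excluded``
    counts the trials dropped from those means.
    """

    scenario: str
    n_sims: int
    p_success: float
    p_interim_stop: float
    mean_sample_size: float
    p_flipflop: float
    mean_final_or: float
    mean_final_lci: float
    mean_final_uci: float
    mean_final_p: float
    n_excluded: int

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def summarise_run(run: SimulationRun) -> pd.DataFrame:
    """Six-number summary of every result variable across simulated trials.

    Quartiles use linear interpolation of order statistics (the "type 7"
    convention shared by numpy, pandas and R's default).  Missing values
    (e.g. interim statistics of trials whose trigger was never reached,
    or degenerate odds ratios) are excluded and counted in ``n_missing``
    rather than silently dropped.

    Returns
    -------
    pandas.DataFrame
        One row per result variable, columns ``minimum, q1, median,
        mean, q3, maximum, n_missing``.
    """
    if len(run.results) == 0:
        raise ValueError("cannot summarise an empty run")
    variables = [c for c in run.results.columns if c not in ("simno", "seed")]
    rows = {}
    for var in variables:
        col = run.results[var].astype(float)
        valid = col.dropna()
        n_missing = int(col.isna().sum())
        if len(valid) == 0:
            stats = [np.nan] * 6
        else:
            stats = [
                valid.min(),
                valid.quantile(0.25),
                valid.quantile(0.50),
                valid.mean(),
                valid.quantile(0.75),
                valid.max(),
            ]
        rows[var] = dict(zip(SUMMARY_STATS, stats)) | {"n_missing": n_missing}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "variable"
    return out


def extract_oc(run: SimulationRun) -> OperatingCharacteristics:
    """Operating characteristics of one scenario's Monte-Carlo run."""
    res = run.results
    if len(res) == 0:
        raise ValueError("cannot extract operating characteristics from an empty run")
    finite_or = res["final_or"].notna()
    n_excluded = int((~finite_or).sum())
    kept = res[finite_or]
    nan = float("nan")
    return OperatingCharacteristics(
        scenario=run.scenario.name,
        n_sims=run.n_sims,
        p_success=float(res["stop"].mean()),
        p_interim_stop=float(res["interim_stop"].mean()),
        mean_sample_size=float(res["sample_size"].mean()),
        p_flipflop=float(res["flipflop"].mean()),
        mean_final_or=float(kept["final_or"].mean()) if len(kept) else nan,
        mean_final_lci=float(kept["final_lci"].mean()) if len(kept) else nan,
        mean_final_uci=float(kept["final_uci"].mean()) if len(kept) else nan,
        mean_final_p=float(res["final_p"].mean()),
        n_excluded=n_excluded,
    )


def scenario_grid(
    params: DesignParameters,
    scenarios: list[Scenario],
    n_sims: int,
    master_seed: int,
    log_every: int = 500,
) -> tuple[pd.DataFrame, dict[str, SimulationRun]]:
    """Run every scenario and tabulate operating characteristics.

    Each scenario gets an independently derived master seed, so adding or
    reordering scenarios never perturbs another scenario's results.

    Returns
    -------
    (oc_table, runs)
        ``oc_table`` has one row per scenario in input order;``runs``
        maps scenario name to its full :class:`SimulationRun`.
    """
    if not scenarios:
        raise ValueError("at least one scenario is required")
    names = [s.name for s in scenarios]
    if len(set(names)) != len(names):
        raise ValueError("scenario names must be unique")

    scenario_seeds = derive_seeds(master_seed, len(scenarios))
    runs: dict[str, SimulationRun] = {}
    oc_rows = []
    for scenario, seed in zip(scenarios, scenario_seeds):
        run = run_multiple_trials(
            params, scenario, n_sims, int(seed), log_every=log_every
        )
        runs[scenario.name] = run
        oc_rows.append(extract_oc(run).as_dict())
    return pd.DataFrame(oc_rows), runs
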