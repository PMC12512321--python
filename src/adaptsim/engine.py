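"""Single-trial and Monte-Carlo orchestration.

``run_trial`` chains data generation, interim selection and analysis into
a deterministic function of (design, scenario, seed).  ``run_multiple_trials``
derives one seed per trial from a master seed, so any simulated trial can
be replayed in isolation and results are invariant to execution order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import RESULT_COLUMNS, TrialResult, analyse_trial
from .datagen import simulate_trial_data, write_trial_data
from .design import DesignParameters, Scenario, validate, validate_scenario
from .interim import select_interim

__all__ = ["SimulationRun", "run_trial", "run_multiple_trials", "derive_seeds"]

logger = logging.getLogger(__name__)

_SEED_BOUND = 2**31


@dataclass(frozen=True)
class SimulationRun:
    """Results of a Monte-Carlo replication of one scenario.

    ``results`` has one row per simulated trial with columns ``simno``,
    ``seed`` and the 18 per-trial result variables; replaying any
    recorded seed through :func:`run_trial` reproduces that row exactly.
    """

    results: pd.DataFrame
    seeds: np.ndarray
    n_sims: int
    params: DesignParameters
    scenario: Scenario


def derive_seeds(master_seed: int, n: int) -> np.ndarray:
    """Derive ``n`` per-trial seeds deterministically from a master seed.

    A dedicated generator seeded with ``master_seed`` draws the per-trial
    seeds in one vectorised call, so the mapping (master_seed, i) -> seed_i
    does not depend on how trials are chunked or ordered at execution time.
    """
    return np.random.default_rng(master_seed).integers(0, _SEED_BOUND, size=n)


def run_trial(
    params: DesignParameters, scenario: Scenario, seed: int
) -> tuple[pd.DataFrame, TrialResult]:
    """Simulate and analyse a single trial.

    Deterministic in (params, scenario, seed): a fresh generator is seeded
    per trial and consumed in a fixed order (allocation, accrual, outcomes).

    Returns
    -------
    (annotated trial dataset, TrialResult)
    """
    validate(params)
    validate_scenario(scenario)
    rng = np.random.default_rng(seed)
    data = simulate_trial_data(params, scenario, rng)
    data, selection = select_interim(data, params.events_at_interim)
    result = analyse_trial(data, selection, params)
    return data, result


def run_multiple_trials(
    params: DesignParameters,
    scenario: Scenario,
    n_sims: int,
    master_seed: int,
    persist: str | Path | None = None,
    persist_datasets: bool = False,
    log_every: int = 500,
) -> SimulationRun:
    """Replicate ``run_trial`` ``n_sims`` times with derived per-trial seeds.

    Parameters
    ----------
    persist
        Optional directory; when given, the results table and a manifest
        are written there (``results.csv``, ``run_manifest.json``), and —
        only if ``persist_datasets`` — every trial's dataset as
        ``trial_<i>.csv``.  Full datasets can occupy considerable space,
        hence the default persists results rows only.
    log_every
        Progress is logged every this many trials (0 disables).
    """
    validate(params)
    validate_scenario(scenario)
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")

    out_dir: Path | None = None
    if persist is not None:
        out_dir = Path(persist)
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        try:
            probe.touch()
            probe.unlink()
        except OSError as exc:  # fail before burning simulation time
            raise OSError(f"persist path {out_dir} is not writable") from exc

    seeds = derive_seeds(master_seed, n_sims)
    rows = []
    for i, seed in enumerate(seeds, start=1):
        data, result = run_trial(params, scenario, int(seed))
        rows.append({"simno": i, "seed": int(seed), **result.as_dict()})
        if out_dir is not None and persist_datasets:
            write_trial_data(data, out_dir / f"trial_{i}.csv")
        if log_every and i % log_every == 0:
            logger.info("scenario %r: simulated %d/%d trials", scenario.name, i, n_sims)

    results = pd.DataFrame(rows, columns=["simno", "seed", *RESULT_COLUMNS])
    run = SimulationRun(
        results=results,
        seeds=seeds,
        n_sims=n_sims,
        params=params,
        scenario=scenario,
    )
    if out_dir is not None:
        results.to_csv(out_dir / "results.csv", index=False)
        write_manifest(run, master_seed, out_dir / "run_manifest.json")
    return run


def write_manifest(run: SimulationRun, master_seed: int, path: str | Path) -> None:
    """Record everything needed to reproduce a run bit-for-bit."""
    manifest = {
        "version": __version__,
        "params": run.params.as_dict(),
        "scenario": dataclasses.asdict(run.scenario),
        "n_sims": run.n_sims,
        "master_seed": int(master_seed),
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
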