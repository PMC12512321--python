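"""Treatment-effect analysis and stopping decisions (building block 5).

The primary analysis is a logistic regression of the binary outcome on
the treatment indicator.  With a single binary covariate the maximum
likelihood fit has a closed form in the 2x2 table of arm-by-outcome
counts: the log odds ratio is ``ln(ad/bc)`` with Wald standard error
``sqrt(1/a + 1/b + 1/c + 1/d)``, and the Wald z statistic gives the
two-sided p-value and confidence interval.  This is the identical
estimator, standard error, p-value and CI that an iteratively-reweighted
least-squares logistic fit reports, evaluated in closed form because it
runs inside a Monte-Carlo loop of thousands of simulated trials.

A table with any zero cell is separated: the MLE diverges and the Wald
standard error is unbounded, so the fit is flagged ``degenerate`` with
p-value 1 and no finite odds ratio or CI — such a trial can never stop
for efficacy.

Stopping rules are strict comparisons of the Wald p-value against the
interim and final thresholds.  Both analyses are always computed, even
when the interim threshold is met, so that "flip-flop" trials (interim
efficacy not confirmed on the full data) can be counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignParameters
from .interim import InterimSelection

__all__ = [
    "TwoByTwoTable",
    "EffectEstimate",
    "TrialResult",
    "RESULT_COLUMNS",
    "fit_binary_logistic",
    "evaluate_decisions",
    "analyse_trial",
]


@dataclass(frozen=True)
class TwoByTwoTable:
    """Arm-by-outcome counts: the sufficient statistic for the logistic model.

    ``a``/``b`` are treatment events/non-events, ``c``/``d`` control
    events/non-events.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("both arms must contain at least one participant")

    @classmethod
    def from_data(cls, trt: np.ndarray, event: np.ndarray) -> "TwoByTwoTable":
        trt = np.asarray(trt)
        event = np.asarray(event)
        return cls(
            a=int(np.sum((trt == 1) & (event == 1))),
            b=int(np.sum((trt == 1) & (event == 0))),
            c=int(np.sum((trt == 0) & (event == 1))),
            d=int(np.sum((trt == 0) & (event == 0))),
        )

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


@dataclass(frozen=True)
class EffectEstimate:
    """Odds ratio (treatment vs control) with Wald CI and p-value."""

    odds_ratio: float
    lci: float
    uci: float
    p_value: float
    degenerate: bool = False


def fit_binary_logistic(table: TwoByTwoTable, ci_level: float = 0.95) -> EffectEstimate:
    """Wald inference for the treatment effect from a 2x2 table.

    Equivalent to ``glm(event ~ trt, family=binomial)`` on the expanded
    per-participant data.  Zero-cell tables return a degenerate estimate
    (p = 1, NaN odds ratio and CI).
    """
    if table.has_zero_cell:
        return EffectEstimate(
            odds_ratio=math.nan,
            lci=math.nan,
            uci=math.nan,
            p_value=1.0,
            degenerate=True,
        )
    a, b, c, d = table.a, table.b, table.c, table.d
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    p = 2.0 * stats.norm.sf(abs(z))
    zcrit = stats.norm.ppf(0.5 + ci_level / 2.0)
    return EffectEstimate(
        odds_ratio=math.exp(log_or),
        lci=math.exp(log_or - zcrit * se),
        uci=math.exp(log_or + zcrit * se),
        p_value=float(p),
    )


def evaluate_decisions(
    interim: EffectEstimate | None,
    final: EffectEstimate,
    params: DesignParameters,
) -> tuple[int, int, int, int]:
    """Apply the stopping thresholds; returns (interim_stop, final_stop, stop, flipflop).

    Efficacy is declared when the p-value is strictly below the threshold.
    ``stop`` records whether the trial was conclusive at either analysis;
    ``flipflop`` flags trials that met the interim threshold but would not
    have met the final one on the complete data.
    """
    interim_stop = int(interim is not None and interim.p_value < params.alpha_interim)
    final_stop = int(final.p_value < params.alpha_final)
    stop = max(interim_stop, final_stop)
    flipflop = interim_stop * (1 - final_stop)
    return interim_stop, final_stop, stop, flipflop


@dataclass(frozen=True)
class TrialResult:
    """One simulated trial's analysis summary (18 variables).

    Event counts/proportions and ``sample_size`` describe the data the
    trial's conclusion rests on: the interim dataset when the trial
    stopped early, the full dataset otherwise.  Interim fields are NaN
    when the interim trigger was never reached.
    """

    nevents0: float
    nevents1: float
    pevents0: float
    pevents1: float
    sample_size: int
    interim_time: float
    interim_or: float
    interim_lci: float
    interim_uci: float
    interim_p: float
    interim_stop: int
    final_or: float
    final_lci: float
    final_uci: float
    final_p: float
    final_stop: int
    stop: int
    flipflop: int

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


RESULT_COLUMNS = [f.name for f in fields(TrialResult)]


def analyse_trial(
    data: pd.DataFrame,
    selection: InterimSelection,
    params: DesignParameters,
) -> TrialResult:
    """Analyse an interim-annotated trial dataset and assemble its result row.

    Fits the logistic model on the interim dataset (when the trigger was
    reached) and on the full dataset, applies the decision thresholds,
    and fills the event counts, proportions and realised sample size.
    Both analyses are computed unconditionally (post-processing design) so
    flip-flops are observable.
    """
    if "interim_flag" not in data.columns:
        raise ValueError("data must be annotated by select_interim first")

    final_table = TwoByTwoTable.from_data(data["trt"], data["event"])
    final_est = fit_binary_logistic(final_table, params.ci_level)

    interim_est: EffectEstimate | None = None
    if selection.reached:
        sub = data[data["interim_flag"] == 1]
        interim_table = TwoByTwoTable.from_data(sub["trt"], sub["event_interim"])
        interim_est = fit_binary_logistic(interim_table, params.ci_level)

    interim_stop, final_stop, stop, flipflop = evaluate_decisions(
        interim_est, final_est, params
    )

    # counts reflect the dataset the conclusion rests on
    if interim_stop == 1:
        concl = data[data["interim_flag"] == 1]
        sample_size = int(selection.interim_ind)
    else:
        concl = data
        sample_size = int(len(data))
    ctrl = concl[concl["trt"] == 0]
    trtm = concl[concl["trt"] == 1]
    nevents0 = float(ctrl["event"].sum())
    nevents1 = float(trtm["event"].sum())

    nan = float("nan")
    return TrialResult(
        nevents0=nevents0,
        nevents1=nevents1,
        pevents0=nevents0 / len(ctrl) if len(ctrl) else nan,
        pevents1=nevents1 / len(trtm) if len(trtm) else nan,
        sample_size=sample_size,
        interim_time=selection.interim_time if selection.reached else nan,
        interim_or=interim_est.odds_ratio if interim_est else nan,
        interim_lci=interim_est.lci if interim_est else nan,
        interim_uci=interim_est.uci if interim_est else nan,
        interim_p=interim_est.p_value if interim_est else nan,
        interim_stop=interim_stop,
        final_or=final_est.odds_ratio,
        final_lci=final_est.lci,
        final_uci=final_est.uci,
        final_p=final_est.p_value,
        final_stop=final_stop,
        stop=stop,
        flipflop=flipflop,
    )
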