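"""Survival comparisons for lifespan and starvation cohorts.

Kaplan-Meier product-limit estimation and the two-sample log-rank test are
delegated to lifelines; the exposure x genotype interaction is tested either
by Cox proportional-hazards regression (statsmodels PHReg, Breslow tie
handling by default, Efron optional) or, when censoring is absent and the
proportional-hazards assumption is doubtful, by a two-way fixed-effects ANOVA
on age at death.  Which of the two to use is a user decision; a Schoenfeld
residual check is provided as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import (
    DegenerateDataError,
    DesignError,
    FitError,
    InsufficientDataError,
    ParameterError,
)

__all__ = [
    "SurvivalCohort",
    "KMCurve",
    "InteractionResult",
    "km_estimate",
    "logrank_test",
    "cox_interaction",
    "anova_interaction_age_at_death",
    "proportional_hazards_check",
]

EXPOSURE_LEVELS = ("unexposed", "exposed")
GENOTYPE_LEVELS = ("control", "mutant")


@dataclass
class SurvivalCohort:
    """Per-individual event times with censoring flags and factor labels."""

    event_time: np.ndarray
    event_observed: np.ndarray
    exposure: np.ndarray
    genotype: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.event_time = np.asarray(self.event_time, dtype=float)
        self.event_observed = np.asarray(self.event_observed, dtype=bool)
        self.exposure = np.asarray(self.exposure)
        if self.genotype is not None:
            self.genotype = np.asarray(self.genotype)
            if self.genotype.shape != self.event_time.shape:
                raise ParameterError("genotype labels do not match event times")
        if self.event_time.shape != self.event_observed.shape:
            raise ParameterError("event flags do not match event times")
        if self.exposure.shape != self.event_time.shape:
            raise ParameterError("exposure labels do not match event times")
        if (self.event_time <= 0).any():
            raise ParameterError("event times must be strictly positive")

    def __len__(self) -> int:
        return self.event_time.size

    @property
    def n_events(self) -> int:
        return int(self.event_observed.sum())

    def subset(self, mask: np.ndarray) -> "SurvivalCohort":
        return SurvivalCohort(
            event_time=self.event_time[mask],
            event_observed=self.event_observed[mask],
            exposure=self.exposure[mask],
            genotype=self.genotype[mask] if self.genotype is not None else None,
        )

    def to_frame(self) -> pd.DataFrame:
        d = {
            "event_time": self.event_time,
            "event_observed": self.event_observed.astype(int),
            "exposure": self.exposure,
        }
        if self.genotype is not None:
            d["genotype"] = self.genotype
        return pd.DataFrame(d)


@dataclass
class KMCurve:
    """Right-continuous product-limit survival curve."""

    times: np.ndarray
    survival_probabilities: np.ndarray
    at_risk: np.ndarray

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Step-function evaluation S(t) for arbitrary times."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival_probabilities[np.maximum(idx, 0)], 1.0)
        return out


@dataclass
class InteractionResult:
    """Exposure x genotype interaction estimate from cox or ANOVA."""

    method: str
    interaction_estimate: float
    standard_error: float
    p_value: float


def km_estimate(cohort: SurvivalCohort) -> KMCurve:
    """Kaplan-Meier estimate; censored individuals leave the risk set at
    their censoring times."""
    if cohort.n_events == 0:
        raise DegenerateDataError("no observed events: survival curve degenerate")
    kmf = KaplanMeierFitter()
    kmf.fit(cohort.event_time, cohort.event_observed)
    surv = kmf.survival_function_["KM_estimate"]
    times = surv.index.to_numpy(dtype=float)
    at_risk = (
        kmf.event_table["at_risk"].reindex(surv.index).ffill().to_numpy(dtype=int)
    )
    return KMCurve(times=times,
                   survival_probabilities=surv.to_numpy(dtype=float),
                   at_risk=at_risk)


def logrank_test(a: SurvivalCohort, b: SurvivalCohort) -> tuple[float, float]:
    """Two-sample log-rank test: (chi-square statistic on 1 df, two-sided p)."""
    if a.n_events == 0 or b.n_events == 0:
        raise DegenerateDataError("each cohort needs at least one observed event")
    r = _ll_logrank(a.event_time, b.event_time,
                    event_observed_A=a.event_observed,
                    event_observed_B=b.event_observed)
    return float(r.test_statistic), float(r.p_value)


def _design_frame(cohort: SurvivalCohort) -> pd.DataFrame:
    if cohort.genotype is None:
        raise DesignError("interaction tests need both exposure and genotype labels")
    df = cohort.to_frame()
    for col, levels in (("exposure", EXPOSURE_LEVELS), ("genotype", GENOTYPE_LEVELS)):
        found = set(map(str, df[col]))
        if len(found) != 2:
            raise DesignError(f"{col} must have exactly 2 levels; found {sorted(found)}")
    # code the second-sorted level as 1 so conventional levels map to
    # exposed=1 / mutant=1; arbitrary but deterministic for other labels
    for col, ref in (("exposure", "unexposed"), ("genotype", "control")):
        levels = sorted(set(map(str, df[col])))
        baseline = ref if ref in levels else levels[0]
        df[col + "01"] = (df[col].astype(str) != baseline).astype(float)
    df["interaction"] = df["exposure01"] * df["genotype01"]
    for e in (0.0, 1.0):
        for g in (0.0, 1.0):
            cell = (df["exposure01"] == e) & (df["genotype01"] == g)
            if not cell.any():
                raise DesignError("empty cell in the 2x2 design")
            if not df.loc[cell, "event_observed"].any():
                raise DesignError("a design cell has no observed events")
    return df


def cox_interaction(cohort: SurvivalCohort, ties: str = "breslow") -> InteractionResult:
    """Cox proportional-hazards fit with exposure, genotype and their
    interaction; returns the interaction log hazard ratio."""
    from statsmodels.duration.hazard_regression import PHReg

    if ties not in ("breslow", "efron"):
        raise ParameterError("ties must be 'breslow' or 'efron'")
    df = _design_frame(cohort)
    exog = df[["exposure01", "genotype01", "interaction"]].to_numpy()
    try:
        model = PHReg(df["event_time"].to_numpy(), exog,
                      status=df["event_observed"].to_numpy(), ties=ties)
        fit = model.fit(disp=False)
    except Exception as exc:  # noqa: BLE001 - surface fit diagnostics
        raise FitError(f"Cox regression failed: {exc}") from exc
    est = float(fit.params[2])
    se = float(fit.bse[2])
    if not np.isfinite(est) or not np.isfinite(se) or se <= 0:
        raise FitError(
            f"Cox regression did not converge: estimate={est}, se={se}"
        )
    return InteractionResult(method="cox", interaction_estimate=est,
                             standard_error=se, p_value=float(fit.pvalues[2]))


def anova_interaction_age_at_death(cohort: SurvivalCohort) -> InteractionResult:
    """Two-way fixed-effects ANOVA interaction test on age at death.

    Requires fully observed deaths; with censored records present the Cox
    model is the appropriate tool and an error says so.  The estimate is the
    interaction contrast (difference of exposure effects between genotypes)
    with its OLS standard error; for this 1-df term the t test coincides with
    the ANOVA F test.
    """
    import statsmodels.formula.api as smf

    df = _design_frame(cohort)
    if not df["event_observed"].all():
        raise ParameterError(
            "age-at-death ANOVA requires uncensored data; use cox_interaction"
        )
    for e in (0.0, 1.0):
        for g in (0.0, 1.0):
            if ((df["exposure01"] == e) & (df["genotype01"] == g)).sum() < 2:
                raise InsufficientDataError("each design cell needs >= 2 deaths")
    fit = smf.ols("event_time ~ exposure01 * genotype01", data=df).fit()
    term = "exposure01:genotype01"
    return InteractionResult(
        method="anova_age_at_death",
        interaction_estimate=float(fit.params[term]),
        standard_error=float(fit.bse[term]),
        p_value=float(fit.pvalues[term]),
    )


def proportional_hazards_check(cohort: SurvivalCohort) -> pd.DataFrame:
    """Schoenfeld-residual-style diagnostic for the 2x2 Cox model.

    Returns the per-covariate test table from lifelines; small p-values flag
    departures from proportional hazards, suggesting the age-at-death ANOVA.
    """
    from lifelines.statistics import proportional_hazard_test

    df = _design_frame(cohort)[["event_time", "event_observed", "exposure01",
                                "genotype01", "interaction"]]
    cph = CoxPHFitter()
    cph.fit(df, duration_col="event_time", event_col="event_observed")
    res = proportional_hazard_test(cph, df, time_transform="rank")
    return res.summary
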