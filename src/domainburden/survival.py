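"""Survival stratification by mutation status.

Patients are split into carriers (>= 1 eligible mutation in a given
domain family or gene) and non-carriers, then compared with the
Kaplan-Meier product-limit estimate, the log-rank test, and a
single-covariate Cox proportional-hazards fit whose exponentiated
coefficient is the hazard ratio (Wald p-value).  Ties in the partial
likelihood are handled by the Efron approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .burden import DEFAULT_ELIGIBLE_CLASSES

__all__ = [
    "SurvivalGroup",
    "km_curve",
    "logrank_test",
    "HazardRatioResult",
    "hazard_ratio",
    "stratify_by_carrier",
]


@dataclass
class SurvivalGroup:
    """Follow-up for one patient group: times (>= 0) and event flags."""

    label: str
    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.events = np.asarray(self.events, dtype=bool).ravel()
        if self.times.size != self.events.size:
            raise ValueError("times and events must have equal length")
        if self.times.size == 0:
            raise ValueError("group must be non-empty")
        if np.any(self.times < 0):
            raise ValueError("survival times must be non-negative")

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def n_events(self) -> int:
        return int(self.events.sum())


def km_curve(group: SurvivalGroup) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate as step-function points.

    Returns a frame (time, survival) starting at (0, 1); survival is
    non-increasing and, without censoring, equals the empirical survivor
    function.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(group.times, group.events, label=group.label)
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )


def logrank_test(a: SurvivalGroup, b: SurvivalGroup) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic with 1 df, p-value).

    Requires at least one event overall; identical groups give statistic 0
    and p = 1.
    """
    if a.n_events + b.n_events == 0:
        raise ValueError("log-rank test needs at least one event")
    res = _ll_logrank(a.times, b.times, event_observed_A=a.events, event_observed_B=b.events)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class HazardRatioResult:
    hr: float
    ci_low: float
    ci_high: float
    wald_p: float
    log_hr: float
    se: float


def hazard_ratio(a: SurvivalGroup, b: SurvivalGroup) -> HazardRatioResult:
    """Hazard of group ``b`` relative to group ``a`` from a Cox PH fit on
    the binary group indicator (Efron ties; Wald p-value).

    Both groups need at least one event; complete separation or other
    non-convergence raises with lifelines' diagnostics attached.
    """
    if a.n_events == 0 or b.n_events == 0:
        raise ValueError("both groups need at least one observed event")
    df = pd.DataFrame(
        {
            "time": np.concatenate([a.times, b.times]),
            "event": np.concatenate([a.events, b.events]).astype(int),
            "group": np.concatenate([np.zeros(a.n), np.ones(b.n)]),
        }
    )
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # convergence / separation diagnostics
        raise RuntimeError(f"Cox PH fit failed: {exc}") from exc
    coef = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    ci = cph.confidence_intervals_
    return HazardRatioResult(
        hr=float(np.exp(coef)),
        ci_low=float(np.exp(ci.iloc[0, 0])),
        ci_high=float(np.exp(ci.iloc[0, 1])),
        wald_p=float(cph.summary["p"].iloc[0]),
        log_hr=coef,
        se=se,
    )


def stratify_by_carrier(
    clinical: pd.DataFrame,
    mutations: pd.DataFrame,
    *,
    genes: Optional[Iterable[str]] = None,
    domains: Optional[pd.DataFrame] = None,
    family_acc: Optional[str] = None,
    eligible_classes=DEFAULT_ELIGIBLE_CLASSES,
) -> tuple[SurvivalGroup, SurvivalGroup]:
    """Split the cohort into (non-carriers, carriers).

    Carrier status is >= 1 eligible mutation in any of ``genes``, or — when
    ``domains`` and ``family_acc`` are given — >= 1 eligible mutation inside
    that family's domain spans.
    """
    classes = {getattr(c, "value", c) for c in eligible_classes}
    sub = mutations.loc[mutations["variant_class"].isin(classes)]
    if family_acc is not None:
        if domains is None:
            raise ValueError("domains table required with family_acc")
        fam = domains.loc[domains["family_acc"] == family_acc]
        sub = sub.loc[sub["protein_pos"].notna()]
        joined = sub.merge(fam[["gene", "start", "end"]], on="gene", how="inner")
        joined = joined.loc[
            (joined["protein_pos"].astype(int) >= joined["start"])
            & (joined["protein_pos"].astype(int) <= joined["end"])
        ]
        carriers = set(joined["patient_id"].astype(str))
        label = family_acc
    elif genes is not None:
        carriers = set(
            sub.loc[sub["gene"].isin(set(genes)), "patient_id"].astype(str)
        )
        label = ",".join(sorted(set(genes)))
    else:
        raise ValueError("give either genes or (domains, family_acc)")
    is_carrier = clinical["patient_id"].astype(str).isin(carriers).to_numpy()
    times = clinical["survival_time"].to_numpy(dtype=float)
    events = clinical["event"].to_numpy(dtype=bool)
    non = SurvivalGroup("wild-type", times[~is_carrier], events[~is_carrier])
    car = SurvivalGroup(f"{label} mutated", times[is_carrier], events[is_carrier])
    return non, car
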