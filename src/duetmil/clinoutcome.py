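"""Claims-derived endpoints and survival statistics.

Two endpoints are supported. Time-on-treatment (TOT) is the interval
between the first and last drug administrations in the claims trail.
Overall survival (OS) runs from treatment start to death; an explicit death
date takes precedence, otherwise a silence of more than 100 days between
the last claim and the claims-data refresh is read as a presumed death
(imputed at the last claim date — the latest evidence of being alive),
and anything with contact within 100 days of the refresh is censored at the
last claim. Patients with TOT below 21 days are excluded from survival
analyses as poor-quality records.

Kaplan-Meier curves, the log-rank test and Cox proportional-hazards ratios
(Breslow tie handling by default, Wald CI on the log scale, biomarker-
negative group as reference) are provided through lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

from .synthcohort import OutcomeRecord

log = logging.getLogger("duetmil.clinoutcome")

TOT_MIN_DAYS = 21
PRESUMED_DEATH_GAP_DAYS = 100


def derive_tot(outcome: OutcomeRecord) -> int:
    """Time-on-treatment: last minus first administration day."""
    return outcome.last_admin_day - outcome.first_admin_day


def derive_os(outcome: OutcomeRecord) -> tuple[int, int]:
    """(time, event) for overall survival from treatment start.

    Explicit death date wins; otherwise a claims gap of more than 100 days
    before the refresh is a presumed death at the last claim day, and a
    recent claim (gap <= 100 days) censors at the last claim day.
    """
    if outcome.death_day is not None:
        return outcome.death_day - outcome.first_admin_day, 1
    gap = outcome.refresh_day - outcome.last_claim_day
    time = outcome.last_claim_day - outcome.first_admin_day
    return (time, 1) if gap > PRESUMED_DEATH_GAP_DAYS else (time, 0)


@dataclass(frozen=True)
class SurvivalRecord:
    case_id: str
    time: float
    event: int
    group: int  # 1 = biomarker positive (actual or predicted), 0 = negative
    endpoint: str  # "TOT" or "OS"

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be positive")
        if self.event not in (0, 1) or self.group not in (0, 1):
            raise ValueError("event and group must be binary")


def build_survival_records(outcomes: dict, groups: dict, endpoint: str = "OS",
                           min_tot_days: int = TOT_MIN_DAYS) -> list[SurvivalRecord]:
    """Derive endpoint records for cases present in both mappings.

    ``outcomes`` maps case_id -> OutcomeRecord; ``groups`` maps case_id to
    the binary stratification status (actual label or thresholded model
    prediction). Cases failing the minimum-TOT filter are dropped here so
    both endpoints see the same analysis set.
    """
    if endpoint not in ("TOT", "OS"):
        raise ValueError("endpoint must be TOT or OS")
    records = []
    for cid, out in outcomes.items():
        if cid not in groups:
            continue
        if derive_tot(out) < min_tot_days:
            continue
        if endpoint == "TOT":
            time, event = derive_tot(out), 1
        else:
            time, event = derive_os(out)
        if time <= 0:
            continue  # degenerate same-day records carry no information
        records.append(SurvivalRecord(cid, float(time), int(event), int(groups[cid]), endpoint))
    return records


def filter_min_tot(records_with_tot: list[tuple], min_days: int = TOT_MIN_DAYS) -> list:
    """Keep (anything, OutcomeRecord) pairs whose TOT is at least ``min_days``."""
    kept = [r for r in records_with_tot if derive_tot(r[1]) >= min_days]
    removed = len(records_with_tot) - len(kept)
    if removed:
        log.info("excluded %d records with TOT < %d days", removed, min_days)
    return kept


def _frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame([{"time": r.time, "event": r.event, "group": r.group}
                         for r in records])


def km_curve(records: list[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival estimate: (event times, S(t) at those times)."""
    if not records:
        raise ValueError("need at least one record")
    df = _frame(records)
    if (df["time"] <= 0).any():
        raise ValueError("non-positive survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], df["event"])
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = times > 0
    return times[keep], surv[keep]


def logrank(group_a: list[SurvivalRecord], group_b: list[SurvivalRecord]) -> tuple[float, float]:
    """Two-sample log-rank test: (chi-square statistic on 1 df, p value)."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    a, b = _frame(group_a), _frame(group_b)
    if a["event"].sum() + b["event"].sum() == 0:
        raise ValueError("log-rank needs at least one event")
    res = logrank_test(a["time"], b["time"], event_observed_A=a["event"],
                       event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int


def cox_hr(records: list[SurvivalRecord], ties: str = "breslow") -> CoxResult:
    """Hazard ratio of the positive group vs the negative (reference) group.

    Partial-likelihood Cox fit with Breslow (default) or Efron tie handling
    and a Wald confidence interval on the log-hazard scale. Non-convergence
    (e.g. a monotone likelihood when one group has no events) raises rather
    than returning a silent estimate.
    """
    df = _frame(records)
    if df["group"].nunique() != 2:
        raise ValueError("need both groups represented")
    cph = CoxPHFitter()
    try:
        with np.errstate(all="ignore"):
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, Warning) as exc:  # pragma: no cover - rethrown
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    coef = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    if not np.isfinite(coef) or not np.isfinite(se) or se > 50:
        raise RuntimeError("Cox model did not converge to a finite estimate")
    z = 1.959963984540054
    return CoxResult(
        hr=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        p=float(cph.summary.loc["group", "p"]),
        n=len(df),
        n_events=int(df["event"].sum()),
    )


def survival_summary(records: list[SurvivalRecord]) -> dict:
    """KM + log-rank + Cox for one endpoint, positive vs negative group."""
    pos = [r for r in records if r.group == 1]
    neg = [r for r in records if r.group == 0]
    stat, p = logrank(pos, neg)
    cox = cox_hr(records)
    return {
        "endpoint": records[0].endpoint if records else "NA",
        "n_pos": len(pos), "n_neg": len(neg),
        "logrank_stat": stat, "logrank_p": p,
        "hr": cox.hr, "hr_ci_low": cox.ci_low, "hr_ci_high": cox.ci_high,
        "cox_p": cox.p,
    }


def plot_km(records: list[SurvivalRecord], path=None, title: str = ""):
    """KM curves per group with shaded 95% confidence bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for grp, name in ((1, "positive"), (0, "negative")):
        sub = _frame([r for r in records if r.group == grp])
        if len(sub) == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=name)
        kmf.plot_survival_function(ax=ax, ci_show=True)
    ax.set_xlabel("days")
    ax.set_ylabel("survival probability")
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
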