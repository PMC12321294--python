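"""Kaplan–Meier estimation and log-rank comparison for cohort metadata.

The product-limit estimator is computed directly from its definition:

    S(t) = prod_{t_i <= t} (1 - d_i / n_i)

over the distinct observed event times t_i, with d_i events and n_i subjects
at risk just before t_i.  Censored observations reduce future risk sets but
contribute no factor; at tied times, events are processed before censorings
(the standard convention), i.e. a subject censored at t is still at risk at t.

The log-rank test compares k groups by accumulating, at every distinct event
time, the observed minus expected events per group (expectation proportional
to the group's share of the risk set) with the hypergeometric variance; the
statistic is (O-E)' V^{-1} (O-E) over the first k-1 groups and is referred to
a chi-square distribution with k-1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "LogRankResult",
    "km_estimate",
    "logrank_test",
    "build_survival_records",
    "survival_plot",
]

#: default mapping from vital-status text to the event indicator
DEFAULT_STATUS_VOCAB: Mapping[str, bool] = {
    "dead": True,
    "deceased": True,
    "death": True,
    "true": True,
    "1": True,
    "alive": False,
    "living": False,
    "censored": False,
    "false": False,
    "0": False,
}


@dataclass(frozen=True)
class SurvivalRecord:
    individual_id: str
    time: float
    event: bool
    group: str = "all"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"negative follow-up time {self.time} for {self.individual_id}")
        if not self.group:
            raise ValueError("group label must be nonempty")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate for one group.

    ``event_times`` are the distinct times with at least one event; survival,
    at-risk counts and event counts are parallel to it.  Greenwood standard
    errors and log-transformed confidence bounds are carried for plotting.
    """

    group: str
    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray
    n_total: int
    ci_lower: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    ci_upper: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    censor_times: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function, 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )

    def step_coordinates(self) -> pd.DataFrame:
        """(time, survival) pairs duplicated into a drawable step path."""
        times = [0.0]
        surv = [1.0]
        for t, s in zip(self.event_times, self.survival):
            times += [float(t), float(t)]
            surv += [surv[-1], float(s)]
        return pd.DataFrame({"group": self.group, "time": times, "survival": surv})


def km_estimate(
    records: Sequence[SurvivalRecord],
    group: str | None = None,
    conf_level: float = 0.95,
) -> KMCurve:
    """Kaplan–Meier product-limit estimate over one group of records."""
    if not records:
        raise ValueError("at least one record required")
    label = group if group is not None else records[0].group
    times = np.asarray([r.time for r in records], dtype=float)
    events = np.asarray([r.event for r in records], dtype=bool)
    if np.any(times < 0):
        raise ValueError("negative follow-up time")

    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    n = len(times)

    event_times = np.unique(times[events])
    at_risk = np.empty(len(event_times), dtype=int)
    d = np.empty(len(event_times), dtype=int)
    c = np.empty(len(event_times), dtype=int)
    for i, t in enumerate(event_times):
        at_risk[i] = int(np.sum(times >= t))  # censored at t still at risk
        d[i] = int(np.sum((times == t) & events))
        c[i] = int(np.sum((times == t) & ~events))
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 - d / at_risk
        survival = np.cumprod(factors)
        # Greenwood variance on log S, with the log(-log S) transform for CIs
        greenwood = np.cumsum(d / (at_risk * (at_risk - d + 1e-300)))
        se_log = np.sqrt(greenwood)
        z = stats.norm.ppf(0.5 + conf_level / 2.0)
        safe = (survival > 0) & (survival < 1)
        ci_lower = np.where(safe, np.nan, survival)
        ci_upper = np.where(safe, np.nan, survival)
        if np.any(safe):
            loglog = np.log(-np.log(survival[safe]))
            se_loglog = se_log[safe] / np.abs(np.log(survival[safe]))
            ci_lower[safe] = np.exp(-np.exp(loglog + z * se_loglog))
            ci_upper[safe] = np.exp(-np.exp(loglog - z * se_loglog))
    return KMCurve(
        group=label,
        event_times=event_times,
        survival=survival,
        at_risk=at_risk,
        n_events=d,
        n_censored=c,
        n_total=n,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        censor_times=np.sort(times[~events]),
    )


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    groups: tuple[str, ...]
    observed: np.ndarray
    expected: np.ndarray


def logrank_test(records: Sequence[SurvivalRecord]) -> LogRankResult:
    """k-sample log-rank test over grouped records.

    At each distinct event time, the expected number of events in group j is
    d * n_j / n; the variance-covariance of the observed counts is
    hypergeometric.  The chi-square statistic uses the first k-1 groups.
    """
    groups = list(dict.fromkeys(r.group for r in records))
    k = len(groups)
    if k < 2:
        raise ValueError("log-rank test needs at least two groups")
    gidx = {g: j for j, g in enumerate(groups)}
    times = np.asarray([r.time for r in records], dtype=float)
    events = np.asarray([r.event for r in records], dtype=bool)
    glabels = np.asarray([gidx[r.group] for r in records], dtype=int)

    event_times = np.unique(times[events])
    observed = np.zeros(k)
    expected = np.zeros(k)
    var = np.zeros((k, k))
    for t in event_times:
        at_risk_mask = times >= t
        n = int(at_risk_mask.sum())
        nj = np.bincount(glabels[at_risk_mask], minlength=k).astype(float)
        d = int(np.sum((times == t) & events))
        dj = np.bincount(glabels[(times == t) & events], minlength=k).astype(float)
        observed += dj
        expected += d * nj / n
        if n > 1:
            # hypergeometric covariance of event counts at this time
            frac = nj / n
            mult = d * (n - d) / (n - 1)
            var += mult * (np.diag(frac) - np.outer(frac, frac))
    diff = (observed - expected)[: k - 1]
    vmat = var[: k - 1, : k - 1]
    try:
        stat = float(diff @ np.linalg.solve(vmat, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(vmat) @ diff)
    stat = max(stat, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(stat, df))
    return LogRankResult(
        statistic=stat, df=df, p_value=p, groups=tuple(groups),
        observed=observed, expected=expected,
    )


def build_survival_records(
    table: pd.DataFrame,
    time_column: str,
    status_column: str,
    group: str | Callable[[pd.Series], str] | None = None,
    group_threshold: float | None = None,
    status_vocab: Mapping[str, bool] | None = None,
    id_column: str | None = None,
) -> tuple[list[SurvivalRecord], int]:
    """Bridge a flattened individuals table to survival records.

    ``group`` may name a metadata column; with ``group_threshold`` set, that
    column is numeric and records split into ``"<x"`` / ``">=x"`` groups.
    Rows with null time/status, unmappable status text, or negative times are
    dropped; the count of dropped rows is returned alongside the records.
    """
    for col in (time_column, status_column):
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in table (has {list(table.columns)})")
    if isinstance(group, str) and group not in table.columns:
        raise KeyError(f"group column {group!r} not in table")
    vocab = {k.lower(): v for k, v in (status_vocab or DEFAULT_STATUS_VOCAB).items()}
    records: list[SurvivalRecord] = []
    dropped = 0
    for i, row in table.iterrows():
        time_raw, status_raw = row[time_column], row[status_column]
        if time_raw is None or status_raw is None or pd.isna(time_raw) or pd.isna(status_raw):
            dropped += 1
            continue
        try:
            time = float(time_raw)
        except (TypeError, ValueError):
            dropped += 1
            continue
        if time < 0:
            dropped += 1
            continue
        if isinstance(status_raw, (bool, np.bool_)):
            event = bool(status_raw)
        else:
            key = str(status_raw).strip().lower()
            if key not in vocab:
                dropped += 1
                continue
            event = vocab[key]
        if group is None:
            label = "all"
        elif callable(group):
            label = group(row)
        elif group_threshold is not None:
            value = row[group]
            if value is None or pd.isna(value):
                dropped += 1
                continue
            label = (
                f">={group_threshold:g}" if float(value) >= group_threshold
                else f"<{group_threshold:g}"
            )
        else:
            label = str(row[group])
        ident = str(row[id_column]) if id_column and id_column in table.columns else str(i)
        records.append(SurvivalRecord(individual_id=ident, time=time, event=event, group=label))
    if not records:
        raise ValueError("no usable records after filtering")
    return records, dropped


def survival_plot(
    curves: KMCurve | Sequence[KMCurve],
    show_censor_marks: bool = True,
    risk_table: bool = False,
    show_ci: bool = True,
    out: str | None = None,
):
    """Step-function survival plot; returns ``(figure, step table)``."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if isinstance(curves, KMCurve):
        curves = [curves]
    if not curves:
        raise ValueError("at least one curve required")
    nrows = 2 if risk_table else 1
    fig, axes = plt.subplots(
        nrows, 1, figsize=(7, 5 if risk_table else 4), squeeze=False,
        gridspec_kw={"height_ratios": [4, 1]} if risk_table else None,
    )
    ax = axes[0, 0]
    tables = []
    for curve in curves:
        steps = curve.step_coordinates()
        tables.append(steps)
        (line,) = ax.plot(steps["time"], steps["survival"], label=curve.group)
        if show_ci and curve.ci_lower is not None and len(curve.event_times):
            ax.fill_between(
                curve.event_times, curve.ci_lower, curve.ci_upper,
                step="post", alpha=0.15, color=line.get_color(),
            )
        if show_censor_marks and curve.censor_times is not None:
            marks = [(t, curve.survival_at(t)) for t in curve.censor_times]
            if marks:
                xs, ys = zip(*marks)
                ax.plot(xs, ys, "|", color=line.get_color(), markersize=8)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability S(t)")
    ax.set_ylim(0, 1.05)
    ax.legend()
    if risk_table:
        rax = axes[1, 0]
        rax.axis("off")
        for i, curve in enumerate(curves):
            text = "  ".join(f"{int(t):g}:{r}" for t, r in zip(curve.event_times, curve.at_risk))
            rax.text(0, 1 - 0.35 * i, f"{curve.group} at risk  {text}",
                     fontsize=8, transform=rax.transAxes)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out)
    return fig, pd.concat(tables, ignore_index=True)
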