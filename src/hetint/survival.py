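"""Clinical endpoints, Kaplan-Meier curves and two-group Cox comparison.

Endpoints are derived from per-patient event streams:

* **OS** — overall survival, event = death from any cause, otherwise
  censored at last follow-up.
* **DMFP** — distant-metastasis-free probability: event at the first
  distant metastasis or ipsilateral supraclavicular recurrence (the latter
  counting as first clinical evidence of metastatic disease); a preceding
  local recurrence, axillary recurrence, contralateral breast cancer or
  second primary *censors* the patient at that time, because such lesions
  could themselves seed later metastases.
* **BMFS** — same censoring logic with bone metastasis as the event.

Estimation and testing are delegated to lifelines: the product-limit
estimator for curves, and a two-group Cox proportional-hazards fit (Efron
tie handling) plus the log-rank test — which is the score test of that Cox
model — for group comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

__all__ = [
    "EVENT_TYPES",
    "ClinicalRecord",
    "Endpoint",
    "SurvivalCurve",
    "GroupComparison",
    "derive_os",
    "derive_dmfp",
    "derive_bmfs",
    "km_estimate",
    "survival_at",
    "compare_groups",
    "read_clinical_table",
    "write_clinical_table",
]

EVENT_TYPES = (
    "local_recurrence",
    "axillary_recurrence",
    "contralateral",
    "second_primary",
    "supraclavicular_recurrence",
    "distant_metastasis",
    "bone_metastasis",
    "death",
)

_DMFP_EVENTS = frozenset({"distant_metastasis", "supraclavicular_recurrence"})
_BMFS_EVENTS = frozenset({"bone_metastasis"})
_CENSORING_EVENTS = frozenset(
    {"local_recurrence", "axillary_recurrence", "contralateral", "second_primary"}
)


@dataclass
class ClinicalRecord:
    """One patient's time-ordered event stream plus last follow-up (years)."""

    patient_id: str
    events: list[tuple[str, float]] = field(default_factory=list)
    last_followup: float = 0.0

    def __post_init__(self) -> None:
        for etype, t in self.events:
            if etype not in EVENT_TYPES:
                raise ValueError(f"unknown event type {etype!r}")
            if t < 0:
                raise ValueError(f"negative event time {t} for {self.patient_id!r}")
        if self.last_followup < 0:
            raise ValueError("last_followup must be nonnegative")

    def _ordered(self) -> list[tuple[str, float]]:
        times = [t for _, t in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(f"event stream of {self.patient_id!r} is not time-ordered")
        return self.events


class Endpoint(NamedTuple):
    time: float
    event: int


def derive_os(record: ClinicalRecord) -> Endpoint:
    """Overall survival: death from any cause, else censored at last follow-up."""
    for etype, t in record._ordered():
        if etype == "death":
            return Endpoint(t, 1)
    return Endpoint(record.last_followup, 0)


def _first_event_endpoint(
    record: ClinicalRecord, event_set: frozenset[str]
) -> Endpoint:
    for etype, t in record._ordered():
        if etype in event_set:
            return Endpoint(t, 1)
        if etype in _CENSORING_EVENTS:
            return Endpoint(t, 0)
    return Endpoint(record.last_followup, 0)


def derive_dmfp(record: ClinicalRecord) -> Endpoint:
    """Distant-metastasis-free probability endpoint (see module docstring)."""
    return _first_event_endpoint(record, _DMFP_EVENTS)


def derive_bmfs(record: ClinicalRecord) -> Endpoint:
    """Bone-metastasis-free survival with the same censoring rules as DMFP."""
    return _first_event_endpoint(record, _BMFS_EVENTS)


@dataclass
class SurvivalCurve:
    """Right-continuous Kaplan-Meier step function.

    ``event_times`` are the distinct observed event times, ``at_risk`` the
    risk-set size just before each, ``survival`` the post-drop value S(t).
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")


def km_estimate(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Product-limit estimator; censored-at-event-time subjects stay at risk."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) == 0:
        raise ValueError("need at least one subject")
    if np.any(t < 0):
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    observed = table[table["observed"] > 0]
    surv = kmf.survival_function_["KM_estimate"]
    event_times = observed.index.to_numpy(dtype=float)
    return SurvivalCurve(
        event_times=event_times,
        at_risk=observed["at_risk"].to_numpy(dtype=float),
        n_events=observed["observed"].to_numpy(dtype=float),
        survival=surv.loc[observed.index].to_numpy(dtype=float),
    )


def survival_at(curve: SurvivalCurve, t: float) -> float:
    """S(t) of the right-continuous step function (post-drop value at event times)."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    if idx < 0:
        return 1.0
    return float(curve.survival[idx])


@dataclass
class GroupComparison:
    """Two-group survival comparison: Cox hazard ratio plus log-rank test.

    The log-rank test is the score test of the two-group Cox model and is
    always available; the partial-likelihood hazard ratio is flagged
    ``degenerate`` when one group has no events (monotone likelihood).
    """

    hazard_ratio: float
    log_hr: float
    se_log_hr: float
    cox_p: float
    logrank_stat: float
    logrank_p: float
    n_per_group: dict[str, int]
    events_per_group: dict[str, int]
    degenerate: bool = False

    def summary(self) -> str:
        lines = [
            "Two-group survival comparison (Cox PH, Efron ties; log-rank score test)",
            "=" * 72,
            "  ".join(
                f"{g}: n={n}, events={self.events_per_group[g]}"
                for g, n in self.n_per_group.items()
            ),
            f"hazard ratio   {self.hazard_ratio:>10.4f}  "
            f"(log HR {self.log_hr:.4f} +- {self.se_log_hr:.4f}, Wald p {self.cox_p:.4g})",
            f"log-rank       {self.logrank_stat:>10.4f}  (p {self.logrank_p:.4g})",
        ]
        if self.degenerate:
            lines.append("WARNING: monotone likelihood (a group without events); "
                         "hazard ratio unreliable, use the log-rank test")
        return "\n".join(lines)


def compare_groups(
    times: Sequence[float],
    events: Sequence[int],
    group_labels: Sequence,
) -> GroupComparison:
    """Compare exactly two groups with Cox regression and the log-rank test.

    The second group label in sorted order is the "exposed" group: the
    hazard ratio is hazard(group2) / hazard(group1).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(group_labels)
    labels = sorted(pd.unique(g).tolist())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    if e.sum() < 1:
        raise ValueError("need at least one event overall")
    ind = (g == labels[1]).astype(float)
    n_per_group = {str(l): int((g == l).sum()) for l in labels}
    ev_per_group = {str(l): int(e[g == l].sum()) for l in labels}
    if min(n_per_group.values()) == 0:
        raise ValueError("a group has zero subjects")

    lr = logrank_test(t[ind == 0], t[ind == 1], e[ind == 0], e[ind == 1])

    degenerate = min(ev_per_group.values()) == 0
    log_hr = se = hr = cox_p = float("nan")
    if not degenerate:
        df = pd.DataFrame({"time": t, "event": e, "group": ind})
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
            log_hr = float(cph.params_["group"])
            se = float(cph.standard_errors_["group"])
            hr = float(np.exp(log_hr))
            cox_p = float(cph.summary.loc["group", "p"])
        except ConvergenceError:
            degenerate = True
    if degenerate:
        # monotone likelihood: report the diverging direction, keep log-rank
        hr = float("inf") if ev_per_group[str(labels[0])] == 0 else 0.0
        log_hr = float(np.log(hr)) if hr > 0 else float("-inf")
    return GroupComparison(
        hazard_ratio=hr,
        log_hr=log_hr,
        se_log_hr=se,
        cox_p=cox_p,
        logrank_stat=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        n_per_group=n_per_group,
        events_per_group=ev_per_group,
        degenerate=degenerate,
    )


def write_clinical_table(records: Iterable[ClinicalRecord], path) -> None:
    """Long-format clinical TSV: patient_id, event_type, time.

    A ``last_followup`` row per patient closes the stream.
    """
    rows = []
    for r in records:
        for etype, t in r.events:
            rows.append((r.patient_id, etype, t))
        rows.append((r.patient_id, "last_followup", r.last_followup))
    pd.DataFrame(rows, columns=["patient_id", "event_type", "time"]).to_csv(
        path, sep="\t", index=False
    )


def read_clinical_table(path) -> list[ClinicalRecord]:
    """Read the long-format clinical TSV written by :func:`write_clinical_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    records = []
    for pid, sub in df.groupby("patient_id", sort=False):
        fu = sub[sub["event_type"] == "last_followup"]
        last = float(fu["time"].iloc[0]) if len(fu) else float(sub["time"].max())
        events = [
            (str(r.event_type), float(r.time))
            for r in sub.itertuples()
            if r.event_type != "last_followup"
        ]
        events.sort(key=lambda x: x[1])
        records.append(ClinicalRecord(str(pid), events, last))
    return records
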