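"""Birth-aligned accumulation analysis of drug study histories.

Drugs are aligned at their *birth* (first study) and their cumulative
number of studies -- or of adopting diseases -- is averaged across drugs at
each integer age, producing the accumulation curves that empirically follow
a power law ``alpha * t**beta``.  This module also provides yearly
studies-per-drug ratios, within-cohort quintile assignment, the quintile
transition ("momentum") matrix, and windowed study rates.

Age convention: ages are integer years.  A study at fractional age ``u``
counts toward cumulative totals at ages >= ceil(u); age 0 means "by the end
of the birth year".  A drug contributes to the aligned curve at age ``a``
only if its observed span ``t_max - t_birth`` covers ``a``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .events_io import AdoptionRecord, DEFAULT_WINDOW, EventTable, ObservationWindow

logger = logging.getLogger(__name__)

__all__ = [
    "CumulativeCurve",
    "PowerLawFit",
    "QuintileAssignment",
    "TransitionMatrix",
    "studies_per_drug_by_year",
    "aligned_curve",
    "fit_power_law",
    "assign_quintiles",
    "quintile_transitions",
    "rate_in_window",
]


@dataclass(frozen=True)
class CumulativeCurve:
    """Mean (or median) cumulative count at each integer age, with the
    number of drugs contributing at each age."""

    ages: np.ndarray
    values: np.ndarray
    support: np.ndarray
    mode: str = "studies"
    aggregator: str = "mean"

    def __post_init__(self):
        if not (len(self.ages) == len(self.values) == len(self.support)):
            raise ValueError("ages, values and support must be equal length")


@dataclass(frozen=True)
class PowerLawFit:
    """Log-log OLS fit of a cumulative curve to ``alpha * t**beta``."""

    alpha: float
    beta: float
    r_squared: float
    ages_used: tuple[int, ...]


@dataclass(frozen=True)
class QuintileAssignment:
    """Within-cohort quintile membership (5 = most-studied)."""

    assignments: Mapping[str, tuple[int, int, int]]  # drug -> (cohort_year, quintile, count)

    def quintile(self, drug_id: str) -> int:
        return self.assignments[drug_id][1]

    def drugs_in_quintile(self, q: int) -> list[str]:
        return sorted(d for d, (_, qq, _) in self.assignments.items() if qq == q)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-normalized 5x5 quintile transition frequencies between two age
    windows, plus the fraction of window-1 top-quintile drugs with no
    studies in window 2 at all."""

    matrix: np.ndarray
    counts: np.ndarray
    n_drugs: int
    top_quintile_zero_fraction: float


def studies_per_drug_by_year(events: EventTable) -> pd.DataFrame:
    """Per calendar year: number of studies, number of distinct drugs
    mentioned, and the studies-per-drug ratio.

    Years with no drugs are omitted.
    """
    counts: dict[int, int] = {}
    drugs: dict[int, set] = {}
    for r in events:
        y = math.floor(r.time)
        counts[y] = counts.get(y, 0) + 1
        drugs.setdefault(y, set()).add(r.drug_id)
    years = sorted(counts)
    df = pd.DataFrame(
        {
            "year": years,
            "n_studies": [counts[y] for y in years],
            "n_unique_drugs": [len(drugs[y]) for y in years],
        }
    )
    df["studies_per_drug"] = df["n_studies"] / df["n_unique_drugs"]
    return df.set_index("year")


def _event_ages_by_drug(
    source: EventTable | Iterable[AdoptionRecord], mode: Literal["studies", "diseases"]
) -> dict[str, list[float]]:
    """Per drug, sorted event times (study times or adoption times)."""
    times: dict[str, list[float]] = {}
    if mode == "studies":
        if not isinstance(source, EventTable):
            raise TypeError("mode='studies' requires an EventTable")
        for r in source:
            times.setdefault(r.drug_id, []).append(r.time)
    elif mode == "diseases":
        for a in source:
            times.setdefault(a.drug_id, []).append(a.time)
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    for v in times.values():
        v.sort()
    return times


def aligned_curve(
    source: EventTable | Iterable[AdoptionRecord],
    mode: Literal["studies", "diseases"] = "studies",
    aggregator: Literal["mean", "median"] = "mean",
    window: ObservationWindow = DEFAULT_WINDOW,
) -> CumulativeCurve:
    """Birth-aligned average cumulative curve F (studies) or G (diseases).

    Per drug, events are shifted so age 0 is the drug's first event; the
    first event itself is excluded from counts (it would only shift the
    curve up by one) and drugs with a single event are dropped entirely.
    At integer age ``a`` a drug contributes its cumulative count only if
    ``a <= t_max - t_birth``; the aggregator is taken across contributing
    drugs.
    """
    if aggregator not in ("mean", "median"):
        raise ValueError(f"unknown aggregator: {aggregator!r}")
    times = _event_ages_by_drug(source, mode)
    spans: list[float] = []
    per_drug_ages: list[np.ndarray] = []
    for drug, ts in sorted(times.items()):
        if len(ts) < 2:
            continue  # single-event drugs are uninformative for the curve
        t_birth = ts[0]
        ages = np.ceil(np.asarray(ts[1:]) - t_birth)  # first event excluded
        spans.append(window.t_max - t_birth)
        per_drug_ages.append(ages)
    if not spans:
        logger.warning("aligned_curve: no eligible drugs after exclusions")
        return CumulativeCurve(
            ages=np.array([], dtype=int),
            values=np.array([]),
            support=np.array([], dtype=int),
            mode=mode,
            aggregator=aggregator,
        )
    max_age = int(math.floor(max(spans)))
    ages = np.arange(max_age + 1)
    values = np.empty(max_age + 1)
    support = np.empty(max_age + 1, dtype=int)
    spans_arr = np.asarray(spans)
    for a in ages:
        contrib = [np.count_nonzero(ev <= a) for ev, sp in zip(per_drug_ages, spans_arr) if a <= sp]
        support[a] = len(contrib)
        if contrib:
            values[a] = float(np.mean(contrib) if aggregator == "mean" else np.median(contrib))
        else:
            values[a] = np.nan
    keep = support > 0
    return CumulativeCurve(
        ages=ages[keep], values=values[keep], support=support[keep], mode=mode, aggregator=aggregator
    )


def fit_power_law(curve: CumulativeCurve, min_age: int = 1) -> PowerLawFit:
    """Fit ``value = alpha * age**beta`` by OLS of log(value) on log(age).

    Only ages >= ``min_age`` with strictly positive values enter the fit;
    R^2 is computed on the log scale.
    """
    mask = (curve.ages >= min_age) & (curve.values > 0)
    x = np.log(curve.ages[mask].astype(float))
    y = np.log(curve.values[mask])
    if len(x) < 3:
        raise ValueError(f"fit_power_law: need >= 3 usable points, got {len(x)}")
    beta, intercept = np.polyfit(x, y, 1)
    resid = y - (beta * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(
        alpha=float(np.exp(intercept)),
        beta=float(beta),
        r_squared=float(r2),
        ages_used=tuple(int(a) for a in curve.ages[mask]),
    )


def _cumulative_count(ts: list[float], t_birth: float, age: float) -> int:
    """Studies with ceil(age) <= age, including the first study."""
    ages = np.ceil(np.asarray(ts) - t_birth)
    return int(np.count_nonzero(ages <= age))


def _count_in_age_range(ts: list[float], t_birth: float, lo: int, hi: int) -> int:
    ages = np.ceil(np.asarray(ts) - t_birth)
    return int(np.count_nonzero((ages >= lo) & (ages <= hi)))


def assign_quintiles(
    events: EventTable,
    cohort_year: int,
    horizon: int | None = None,
    window: ObservationWindow = DEFAULT_WINDOW,
) -> QuintileAssignment:
    """Rank a birth cohort by cumulative study count and split into
    quintiles (5 = most studied).

    ``horizon`` is an integer age; ``None`` means "by the end of the
    observation window".  Drugs studied only once are excluded.  Ties are
    broken by earlier birth time within the year, then drug id, so the
    assignment is deterministic.
    """
    times = _event_ages_by_drug(events, "studies")
    rows = []
    for drug, ts in times.items():
        if math.floor(ts[0]) != cohort_year or len(ts) < 2:
            continue
        if horizon is None:
            count = int(np.count_nonzero(np.asarray(ts) <= window.t_max))
        else:
            count = _cumulative_count(ts, ts[0], horizon)
        rows.append((count, ts[0], drug))
    if not rows:
        raise ValueError(f"no eligible drugs in cohort {cohort_year}")
    if len(rows) < 5:
        logger.warning("assign_quintiles: cohort %d has only %d drugs", cohort_year, len(rows))
    rows.sort()  # ascending count, then earlier birth, then drug_id
    chunks = np.array_split(np.arange(len(rows)), 5)
    assignments = {}
    for q_idx, chunk in enumerate(chunks, start=1):
        for pos in chunk:
            count, _, drug = rows[pos]
            assignments[drug] = (cohort_year, q_idx, count)
    return QuintileAssignment(assignments=assignments)


def quintile_transitions(
    events: EventTable,
    cohort_years: Iterable[int],
    window1: tuple[int, int] = (0, 5),
    window2: tuple[int, int] = (6, 10),
    window: ObservationWindow = DEFAULT_WINDOW,
) -> TransitionMatrix:
    """Quintile persistence ("momentum") between two age windows.

    Quintiles are computed independently per cohort and per window; the
    window-2 ranking uses study counts accumulated strictly within its age
    range.  Returns row-normalized transition frequencies over all drugs
    present in both windows, plus the fraction of window-1 top-quintile
    drugs that accumulate no studies at all in window 2.
    """
    times = _event_ages_by_drug(events, "studies")
    counts_mat = np.zeros((5, 5), dtype=int)
    n_top = 0
    n_top_zero = 0
    total = 0
    for cohort_year in sorted(set(cohort_years)):
        rows1, rows2 = [], []
        count2_by_drug = {}
        for drug, ts in times.items():
            if math.floor(ts[0]) != cohort_year or len(ts) < 2:
                continue
            if window.t_max - ts[0] < window2[1]:
                continue  # drug's span does not cover both windows
            c1 = _count_in_age_range(ts, ts[0], window1[0], window1[1])
            c2 = _count_in_age_range(ts, ts[0], window2[0], window2[1])
            rows1.append((c1, ts[0], drug))
            rows2.append((c2, ts[0], drug))
            count2_by_drug[drug] = c2
        if not rows1:
            continue

        def quintile_of(rows):
            rows = sorted(rows)
            chunks = np.array_split(np.arange(len(rows)), 5)
            out = {}
            for q_idx, chunk in enumerate(chunks, start=1):
                for pos in chunk:
                    out[rows[pos][2]] = q_idx
            return out

        q1 = quintile_of(rows1)
        q2 = quintile_of(rows2)
        for drug in q1:
            counts_mat[q1[drug] - 1, q2[drug] - 1] += 1
            total += 1
            if q1[drug] == 5:
                n_top += 1
                if count2_by_drug[drug] == 0:
                    n_top_zero += 1
    row_sums = counts_mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row_sums > 0, counts_mat / row_sums, 0.0)
    zero_frac = n_top_zero / n_top if n_top else float("nan")
    return TransitionMatrix(
        matrix=probs, counts=counts_mat, n_drugs=total, top_quintile_zero_fraction=zero_frac
    )


def rate_in_window(events: EventTable, drug_id: str, age_a: float, age_b: float) -> float:
    """Average studies per year for one drug between two ages.

    Cumulative counts include the first study.  For a window starting at
    birth (``age_a == 0``) the birth-year studies are counted inside the
    window, i.e. the rate over (0, b) is C(b)/b -- the convention the
    worked accumulation examples use.
    """
    if not age_a < age_b:
        raise ValueError("age_a must be < age_b")
    ts = [r.time for r in events.for_drug(drug_id)]
    t_birth = min(ts)
    c_b = _cumulative_count(ts, t_birth, age_b)
    c_a = 0 if age_a == 0 else _cumulative_count(ts, t_birth, age_a)
    return (c_b - c_a) / (age_b - age_a)
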