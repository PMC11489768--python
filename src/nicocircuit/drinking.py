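"""Two-bottle-choice drinking analysis.

Home-cage oral self-administration with two lickometer-metered bottles
sampled at one-minute resolution. The pipeline is: artifact filtering
(minute readings above a volume threshold are sensor/leak errors),
windowing into overnight sessions (20:00 -> 14:00 next day), per-session
preference for the test solution as a percentage of total liquid intake,
daily nicotine dose in mg/kg/day from interpolated body weights, and
exclusion of animals with a strong side bias during the water-vs-water
habituation period.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "BottleSeries",
    "ChoiceSessionResult",
    "Session",
    "clean_minutes",
    "session_windows",
    "session_preference",
    "interpolate_weight",
    "daily_dose",
    "side_bias_filter",
    "analyze_series",
]

#: Minute readings strictly above this volume (ml) are treated as erroneous
#: (leak / sensor artifact) and excluded from all sums.
ARTIFACT_THRESHOLD_ML = 0.1

#: Overnight session window: [start, end) in clock hours, end on the next day.
SESSION_START_HOUR = 20
SESSION_END_HOUR = 14


@dataclass
class BottleSeries:
    """Per-minute two-bottle volume record for one animal.

    Parameters
    ----------
    animal : str
        Animal identifier.
    data : pandas.DataFrame
        Columns ``timestamp`` (datetime64, minute resolution), ``bottle``
        (sensor id, e.g. ``"b1"``/``"b2"``), ``volume_ml`` (volume change
        in that minute, >= 0).
    labels : pandas.DataFrame
        One row per (session date, bottle): columns ``date``, ``bottle``,
        ``content`` (e.g. ``"water"``, ``"nicotine 100ug/ml"``) and
        ``side`` (``"left"``/``"right"``). The row dated ``d`` describes
        the configuration of the session starting at 20:00 on day ``d``.
    weights : pandas.DataFrame
        Columns ``animal``, ``date``, ``grams``; measured every other day.
    """

    animal: str
    data: pd.DataFrame
    labels: pd.DataFrame
    weights: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["animal", "date", "grams"]))

    def __post_init__(self) -> None:
        ts = pd.to_datetime(self.data["timestamp"])
        per_bottle_sorted = (
            self.data.assign(timestamp=ts)
            .groupby("bottle")["timestamp"]
            .apply(lambda s: s.is_monotonic_increasing and s.is_unique)
        )
        if not bool(per_bottle_sorted.all()):
            raise ValueError("timestamps must be strictly increasing per bottle")
        if (self.data["volume_ml"] < 0).any():
            raise ValueError("volumes must be non-negative")

    def copy_with(self, data: pd.DataFrame) -> "BottleSeries":
        return dataclasses.replace(self, data=data.reset_index(drop=True))


@dataclass
class Session:
    """One overnight session slice of a :class:`BottleSeries`."""

    start: datetime
    end: datetime
    data: pd.DataFrame

    @property
    def date(self) -> date:
        return self.start.date()

    @property
    def empty(self) -> bool:
        return len(self.data) == 0


@dataclass
class ChoiceSessionResult:
    """Per-session preference and intake quantities."""

    session_date: date
    test_content: str
    test_volume_ml: float
    control_volume_ml: float
    preference_pct: float | None  # None when total intake is zero
    total_intake_ml: float
    dose_mg_per_kg_day: float | None = None

    @property
    def undefined(self) -> bool:
        return self.preference_pct is None


def clean_minutes(
    raw: BottleSeries, threshold_ml: float = ARTIFACT_THRESHOLD_ML
) -> tuple[BottleSeries, int]:
    """Remove artifact minutes with volume strictly above ``threshold_ml``.

    Readings above the threshold are erroneous measurements (leaks, sensor
    glitches); they are *excluded*, not interpolated or zeroed, so they
    contribute to no downstream sum. The boundary value (exactly the
    threshold) is retained: the rule is strictly-greater-than.

    Returns the cleaned series and the number of removed minutes.
    """
    keep = raw.data["volume_ml"] <= threshold_ml
    n_removed = int((~keep).sum())
    return raw.copy_with(raw.data.loc[keep]), n_removed


def session_windows(
    series: BottleSeries,
    start_hour: int = SESSION_START_HOUR,
    end_hour: int = SESSION_END_HOUR,
) -> list[Session]:
    """Slice a series into overnight sessions [start_hour, end_hour next day).

    Minutes in the off window [end_hour, start_hour) are discarded: bottle
    contents and sides change during that window, so only the overnight
    block is comparable across days. Sessions are labeled by their start
    date; the interval is half-open so a minute stamped exactly at the
    start hour belongs to that evening's session and nothing is counted
    twice. Empty sessions are kept and flagged via :attr:`Session.empty`.
    """
    if not (0 <= end_hour <= start_hour <= 23):
        raise ValueError("expected an overnight window with end_hour <= start_hour")
    ts = pd.to_datetime(series.data["timestamp"])
    if len(ts) == 0:
        return []
    first_day = ts.min().normalize()
    last_day = ts.max().normalize()
    sessions: list[Session] = []
    day = first_day
    while day <= last_day:
        start = day + pd.Timedelta(hours=start_hour)
        end = day + pd.Timedelta(days=1, hours=end_hour)
        mask = (ts >= start) & (ts < end)
        sessions.append(Session(start=start.to_pydatetime(), end=end.to_pydatetime(), data=series.data.loc[mask.values]))
        day += pd.Timedelta(days=1)
    # drop leading/trailing all-empty days that the stamp range never covered
    while sessions and sessions[-1].empty:
        sessions.pop()
    return sessions


def _session_labels(series: BottleSeries, session_date: date) -> pd.DataFrame:
    lab = series.labels
    lab_dates = pd.to_datetime(lab["date"]).dt.date
    rows = lab.loc[lab_dates == session_date]
    if len(rows) == 0:
        raise KeyError(f"no bottle labels for session date {session_date}")
    return rows


def session_preference(
    session: Session, series: BottleSeries, test_content: str
) -> ChoiceSessionResult:
    """Preference for the test solution in one session.

    preference = 100 * test_volume / (test_volume + control_volume).

    The bottle holding the test solution is resolved from the per-day
    labels (which track the side swaps every 2 days); bottle contents are
    constant within a session because all changes happen in the off
    window. A session with zero total intake yields an undefined
    (``None``) preference rather than a silent 0 or NaN.
    """
    rows = _session_labels(series, session.date)
    test_bottles = set(rows.loc[rows["content"] == test_content, "bottle"])
    if not test_bottles:
        raise KeyError(
            f"no bottle labeled {test_content!r} on {session.date}; "
            f"contents that day: {sorted(rows['content'])}"
        )
    vols = session.data.groupby("bottle")["volume_ml"].sum()
    test_vol = float(vols.reindex(sorted(test_bottles)).fillna(0.0).sum())
    total = float(vols.sum())
    control_vol = total - test_vol
    pref = 100.0 * test_vol / total if total > 0 else None
    return ChoiceSessionResult(
        session_date=session.date,
        test_content=test_content,
        test_volume_ml=test_vol,
        control_volume_ml=control_vol,
        preference_pct=pref,
        total_intake_ml=total,
    )


def interpolate_weight(
    weights: pd.DataFrame, animal: str, when: date
) -> tuple[float, bool]:
    """Body weight (g) on ``when``, linearly interpolated between the
    every-other-day measurements.

    Returns ``(grams, extrapolated)``; when ``when`` falls outside the
    measured range the nearest measurement is used and the flag is True.
    """
    w = weights.loc[weights["animal"] == animal]
    if len(w) == 0:
        raise KeyError(f"no weights for animal {animal!r}")
    d = pd.to_datetime(w["date"]).map(pd.Timestamp.toordinal).to_numpy(float)
    g = w["grams"].to_numpy(float)
    order = np.argsort(d)
    d, g = d[order], g[order]
    x = float(pd.Timestamp(when).toordinal())
    if x < d[0]:
        return float(g[0]), True
    if x > d[-1]:
        return float(g[-1]), True
    return float(np.interp(x, d, g)), False


def daily_dose(
    result: ChoiceSessionResult, concentration_ug_per_ml: float, weight_g: float
) -> float:
    """Nicotine dose in mg/kg per session-day.

    dose = concentration(ug/ml) * test_volume(ml) / 1000 / (weight(g)/1000)
         = concentration * volume / weight.
    """
    if concentration_ug_per_ml <= 0:
        raise ValueError("concentration must be positive")
    if weight_g <= 0:
        raise ValueError("weight must be positive")
    return concentration_ug_per_ml * result.test_volume_ml / weight_g


def side_bias_filter(
    series: BottleSeries,
    low_pct: float = 20.0,
    high_pct: float = 80.0,
) -> tuple[bool, float]:
    """Habituation side-bias exclusion.

    Over the whole water-vs-water habituation period (both bottles labeled
    ``"water"``), the share of total volume drunk on the *left* side is
    computed; the animal is excluded iff that share is strictly below
    ``low_pct`` or strictly above ``high_pct`` percent. Boundary values
    are retained (strict inequalities).

    Returns ``(keep, left_share_pct)``.
    """
    lab = series.labels.copy()
    lab["date"] = pd.to_datetime(lab["date"]).dt.date
    water_days = {
        d for d, rows in lab.groupby("date") if set(rows["content"]) == {"water"}
    }
    if not water_days:
        raise ValueError("no water-vs-water habituation days in labels")
    left_vol = 0.0
    total_vol = 0.0
    for sess in session_windows(series):
        if sess.date not in water_days:
            continue
        rows = _session_labels(series, sess.date)
        side_of = dict(zip(rows["bottle"], rows["side"]))
        vols = sess.data.groupby("bottle")["volume_ml"].sum()
        for bottle, v in vols.items():
            total_vol += float(v)
            if side_of.get(bottle) == "left":
                left_vol += float(v)
    if total_vol == 0:
        raise ValueError("no habituation intake: side bias undecidable")
    share = 100.0 * left_vol / total_vol
    keep = not (share < low_pct or share > high_pct)
    return keep, share


def analyze_series(
    series: BottleSeries,
    test_content: str,
    concentration_ug_per_ml: float | None = None,
    threshold_ml: float = ARTIFACT_THRESHOLD_ML,
) -> pd.DataFrame:
    """End-to-end per-session analysis of one animal's series.

    Cleans artifact minutes, windows into overnight sessions, and computes
    per-session preference, intake, and (for nicotine sessions, when a
    concentration is given) the daily dose from interpolated weights.
    Sessions whose labels do not include ``test_content`` (e.g.
    habituation days) are skipped.
    """
    cleaned, n_removed = clean_minutes(series, threshold_ml)
    out = []
    for sess in session_windows(cleaned):
        try:
            res = session_preference(sess, cleaned, test_content)
        except KeyError:
            continue
        dose = None
        if concentration_ug_per_ml is not None and len(cleaned.weights):
            grams, extrapolated = interpolate_weight(
                cleaned.weights, cleaned.animal, res.session_date
            )
            dose = daily_dose(res, concentration_ug_per_ml, grams)
        out.append(
            {
                "animal": cleaned.animal,
                "date": res.session_date,
                "test_content": test_content,
                "test_volume_ml": res.test_volume_ml,
                "control_volume_ml": res.control_volume_ml,
                "total_intake_ml": res.total_intake_ml,
                "preference_pct": res.preference_pct,
                "dose_mg_per_kg_day": dose,
                "artifact_minutes_removed": n_removed,
            }
        )
    return pd.DataFrame(out)
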