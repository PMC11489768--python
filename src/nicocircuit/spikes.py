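"""In vivo single-unit spike-train response quantification.

Firing of putative dopamine neurons is quantified on overlapping 60-s
windows shifted by 15-s steps, rescaled to a percentage of the mean rate
over the 3 minutes preceding an intravenous injection, and summarized by
the maximal activation (or minimal, for inhibition) within the 3-minute
response period after the injection. The nicotine effect for a unit is
the difference of maximum variation after nicotine vs saline. Burst
firing is quantified as %SWB: the percentage of spikes fired within
bursts, with bursts delimited by the classic 80-ms-onset / 160-ms-offset
inter-spike-interval criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SpikeTrain",
    "FiringTimecourse",
    "ResponseSummary",
    "BaselineUndefinedError",
    "rate_gate",
    "sliding_rate",
    "normalize_to_baseline",
    "response_summary",
    "burst_metrics",
]

WINDOW_S = 60.0
STEP_S = 15.0
BASELINE_S = 180.0
RESPONSE_WINDOW_S = 180.0
#: burst onset when an ISI drops below this (s); classic criterion
BURST_ONSET_ISI_S = 0.080
#: burst ends when an ISI exceeds this (s)
BURST_OFFSET_ISI_S = 0.160
#: |max-100| and |100-min| both below this -> unit classified flat
FLAT_BAND_PCT = 20.0


class BaselineUndefinedError(ValueError):
    """Raised when a unit has no usable (non-zero) baseline."""


@dataclass
class SpikeTrain:
    """Spike timestamps for one unit with injection events."""

    times: np.ndarray  # sorted spike times (s)
    duration_s: float
    injections: list[tuple[float, str]] = field(default_factory=list)  # (time, type)
    unit: str = "unit"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be sorted and unique")
        if len(self.times) and (self.times[0] < 0 or self.times[-1] > self.duration_s):
            raise ValueError("spike times outside [0, duration]")

    def injection_time(self, kind: str) -> float:
        for t, k in self.injections:
            if k == kind:
                return t
        raise KeyError(f"no {kind!r} injection in train {self.unit!r}")


@dataclass
class FiringTimecourse:
    """Sliding-window firing-rate time course for one unit."""

    centers: np.ndarray  # window center times (s)
    rates_hz: np.ndarray
    window_s: float = WINDOW_S
    step_s: float = STEP_S
    normalized_pct: np.ndarray | None = None  # % of baseline
    baseline_hz: float | None = None


@dataclass
class ResponseSummary:
    """Post-injection response summary for one unit."""

    max_activation_pct: float  # max normalized rate in the response window
    max_inhibition_pct: float  # min normalized rate in the response window
    variation_pct: float  # signed dominant deviation from 100%
    response_class: str  # {"activated", "inhibited", "flat"}
    delta_vs_saline_pct: float | None = None
    swb_pct: float | None = None


def rate_gate(
    train: SpikeTrain, low_hz: float = 0.5, high_hz: float = 10.0
) -> bool:
    """Configurable inclusion gate on a unit's overall firing rate.

    Units arrive pre-identified as dopaminergic; this gate only screens
    for rates outside the plausible range (default 0.5-10 Hz)."""
    rate = len(train.times) / train.duration_s
    return low_hz <= rate <= high_hz


def sliding_rate(
    train: SpikeTrain, window_s: float = WINDOW_S, step_s: float = STEP_S
) -> FiringTimecourse:
    """Firing rate on overlapping windows.

    Only windows fully inside the recording are emitted; edge windows are
    dropped, never renormalized. An empty train yields all-zero rates.
    """
    if train.duration_s < window_s:
        raise ValueError("recording shorter than one window")
    starts = np.arange(0.0, train.duration_s - window_s + 1e-9, step_s)
    counts = np.searchsorted(train.times, starts + window_s, side="right") - np.searchsorted(
        train.times, starts, side="left"
    )
    return FiringTimecourse(
        centers=starts + window_s / 2.0,
        rates_hz=counts / window_s,
        window_s=window_s,
        step_s=step_s,
    )


def normalize_to_baseline(
    tc: FiringTimecourse, injection_time_s: float, baseline_s: float = BASELINE_S
) -> FiringTimecourse:
    """Rescale rates to a percentage of the pre-injection baseline.

    The baseline is the mean rate over windows fully inside
    ``[injection - baseline_s, injection)``. A unit whose baseline is
    zero (or that has no complete baseline window) cannot be normalized
    and raises :class:`BaselineUndefinedError` so it can be excluded with
    a reason rather than silently producing infinities.
    """
    starts = tc.centers - tc.window_s / 2.0
    ends = tc.centers + tc.window_s / 2.0
    in_baseline = (starts >= injection_time_s - baseline_s - 1e-9) & (
        ends <= injection_time_s + 1e-9
    )
    if not np.any(in_baseline):
        raise BaselineUndefinedError("no complete window inside the baseline period")
    baseline = float(np.mean(tc.rates_hz[in_baseline]))
    if baseline <= 0:
        raise BaselineUndefinedError("zero baseline rate")
    return replace(
        tc,
        normalized_pct=100.0 * tc.rates_hz / baseline,
        baseline_hz=baseline,
    )


def _max_variation(
    tc: FiringTimecourse, injection_time_s: float, response_window_s: float
) -> tuple[float, float, float]:
    """(max, min, signed dominant variation) of the normalized rate over
    windows whose center lies in (injection, injection + response_window]."""
    if tc.normalized_pct is None:
        raise ValueError("time course not normalized; call normalize_to_baseline first")
    m = (tc.centers > injection_time_s) & (
        tc.centers <= injection_time_s + response_window_s + 1e-9
    )
    if not np.any(m):
        raise ValueError("no windows centered inside the response period")
    vals = tc.normalized_pct[m]
    vmax, vmin = float(vals.max()), float(vals.min())
    up, down = vmax - 100.0, 100.0 - vmin
    variation = up if up >= down else -down
    return vmax, vmin, variation


def response_summary(
    tc_nicotine: FiringTimecourse,
    nicotine_injection_s: float,
    tc_saline: FiringTimecourse | None = None,
    saline_injection_s: float | None = None,
    response_window_s: float = RESPONSE_WINDOW_S,
    flat_band_pct: float = FLAT_BAND_PCT,
) -> ResponseSummary:
    """Summarize a unit's response to the nicotine injection.

    The unit's class is decided from the normalized nicotine time course:
    flat when both the upward and downward excursions stay inside the
    flat band, otherwise activated or inhibited by whichever excursion
    dominates. When a saline time course is given, the delta statistic is
    the difference of maximum variation after nicotine vs after saline.
    """
    vmax, vmin, variation = _max_variation(
        tc_nicotine, nicotine_injection_s, response_window_s
    )
    if (vmax - 100.0) < flat_band_pct and (100.0 - vmin) < flat_band_pct:
        cls = "flat"
    elif variation >= 0:
        cls = "activated"
    else:
        cls = "inhibited"
    delta = None
    if tc_saline is not None:
        if saline_injection_s is None:
            raise ValueError("saline time course given without its injection time")
        _, _, sal_variation = _max_variation(
            tc_saline, saline_injection_s, response_window_s
        )
        delta = variation - sal_variation
    return ResponseSummary(
        max_activation_pct=vmax,
        max_inhibition_pct=vmin,
        variation_pct=variation,
        response_class=cls,
        delta_vs_saline_pct=delta,
    )


def burst_metrics(
    train: SpikeTrain,
    window: tuple[float, float] | None = None,
    onset_isi_s: float = BURST_ONSET_ISI_S,
    offset_isi_s: float = BURST_OFFSET_ISI_S,
) -> float:
    """%SWB: percentage of spikes fired within bursts in a window.

    A burst opens when an inter-spike interval falls below the onset
    criterion and extends while intervals stay below the offset
    criterion. %SWB = 100 * spikes inside bursts / total spikes in the
    window. An empty window is undefined and raises ValueError.
    """
    t = train.times
    if window is not None:
        lo, hi = window
        t = t[(t >= lo) & (t <= hi)]
    n = len(t)
    if n == 0:
        raise ValueError("no spikes in window: %SWB undefined")
    if n == 1:
        return 0.0
    isi = np.diff(t)
    in_burst = np.zeros(n, dtype=bool)
    i = 0
    while i < n - 1:
        if isi[i] < onset_isi_s:
            j = i + 1
            while j < n - 1 and isi[j] < offset_isi_s:
                j += 1
            in_burst[i : j + 1] = True
            i = j + 1
        else:
            i += 1
    return 100.0 * in_burst.sum() / n
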