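"""Ex vivo patch-clamp current analysis.

Voltage-clamp sweeps (time in s, current in pA) are analyzed for: peak
amplitude; mono/bi-exponential decay fits with the weighted time
constant tau_w = (AF*tau_f + AS*tau_s)/(AF + AS); charge transfer as the
integral (AUC) of the baseline-subtracted current between onset and the
end of the decay; paired-pulse ratio (two evoked pulses 50 ms apart);
AMPA/NMDA ratio from a composite sweep and its AMPA-blocked (DNQX)
counterpart; percentage change of current under a drug (e.g. ifenprodil)
relative to a stable baseline period; and threshold-based detection of
spontaneous EPSCs in >= 30-s epochs.

Sign convention: inward currents are negative in storage; peaks and
charges are reported as magnitudes. The number of exponential terms is
chosen by small-sample-corrected AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Sweep",
    "DecayFit",
    "fit_decay",
    "charge_transfer",
    "charge_window",
    "evoked_ratios",
    "pharmacology_change",
    "detect_sepscs",
]


@dataclass
class Sweep:
    """One time-current trace with optional event markers."""

    t: np.ndarray  # s, uniform dt
    i: np.ndarray  # pA
    events: dict = field(default_factory=dict)  # e.g. {"puff": 0.1, "stims": [t1, t2]}
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.i = np.asarray(self.i, float)
        if self.t.shape != self.i.shape:
            raise ValueError("time and current arrays differ in length")
        dt = np.diff(self.t)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("sweep must be uniformly sampled")
        if not np.all(np.isfinite(self.i)):
            raise ValueError("non-finite current samples")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def window(self, t0: float, t1: float) -> tuple[np.ndarray, np.ndarray]:
        m = (self.t >= t0) & (self.t <= t1)
        return self.t[m], self.i[m]


@dataclass
class DecayFit:
    """Exponential decay fit of a current transient."""

    n_terms: int  # 1 or 2
    af_pa: float  # fast amplitude (magnitude)
    as_pa: float  # slow amplitude (0 for mono fits)
    tau_f_ms: float
    tau_s_ms: float  # equals tau_f for mono fits
    tau_w_ms: float
    peak_pa: float
    rms_residual_pa: float
    aicc: dict[int, float]
    converged: bool = True

    def __post_init__(self) -> None:
        if self.n_terms == 2 and not (self.tau_f_ms < self.tau_s_ms):
            raise ValueError("expected tau_f < tau_s for a bi-exponential fit")


def weighted_tau(af: float, tau_f: float, as_: float, tau_s: float) -> float:
    """tau_w = (AF*tau_f + AS*tau_s) / (AF + AS)."""
    if af + as_ <= 0:
        raise ValueError("amplitudes must be positive")
    return (af * tau_f + as_ * tau_s) / (af + as_)


def _baseline(sweep: Sweep, onset: float) -> float:
    m = sweep.t < onset
    if not np.any(m):
        return 0.0
    return float(np.median(sweep.i[m]))


def _magnitude_trace(sweep: Sweep, onset: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Baseline-subtracted magnitude trace after onset (y >= 0 at peak)."""
    base = _baseline(sweep, onset)
    m = sweep.t >= onset
    t, y = sweep.t[m], sweep.i[m] - base
    # orient so the transient is positive
    if abs(y.min()) > abs(y.max()):
        y = -y
    return t, y, base


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    aic = n * np.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def fit_decay(sweep: Sweep, onset: float, fit_duration_s: float | None = None) -> DecayFit:
    """Fit the post-peak decay with 1- and 2-exponential models.

    Both models are fitted by nonlinear least squares from the peak of
    the baseline-subtracted transient; the number of terms is chosen by
    the small-sample-corrected AIC. For bi-exponential fits the
    components are ordered tau_f < tau_s and tau_w is the
    amplitude-weighted mean of the two time constants (tau_w = tau for
    mono fits). Non-convergence raises rather than silently falling back.
    """
    t, y, _ = _magnitude_trace(sweep, onset)
    ipk = int(np.argmax(y))
    td = t[ipk:] - t[ipk]
    yd = y[ipk:]
    if fit_duration_s is not None:
        m = td <= fit_duration_s
        td, yd = td[m], yd[m]
    if len(td) < 8:
        raise ValueError("too few post-peak samples to fit a decay")
    peak = float(yd[0])
    # crude tau guess: time to fall to 1/e of peak
    below = np.nonzero(yd < peak / np.e)[0]
    tau0 = float(td[below[0]]) if len(below) else float(td[-1] / 3)
    tau0 = max(tau0, 2 * sweep.dt)

    def mono(tt, a, tau):
        return a * np.exp(-tt / tau)

    def bi(tt, a1, tau1, a2, tau2):
        return a1 * np.exp(-tt / tau1) + a2 * np.exp(-tt / tau2)

    fits: dict[int, tuple[np.ndarray, float]] = {}
    try:
        p1, _ = curve_fit(
            mono, td, yd, p0=[peak, tau0],
            bounds=([0, sweep.dt / 10], [np.inf, np.inf]), maxfev=20000,
        )
        rss1 = float(np.sum((yd - mono(td, *p1)) ** 2))
        fits[1] = (p1, rss1)
    except RuntimeError:
        pass
    try:
        p2, _ = curve_fit(
            bi, td, yd, p0=[0.7 * peak, tau0 / 3, 0.3 * peak, tau0 * 3],
            bounds=([0, sweep.dt / 10, 0, sweep.dt / 10], [np.inf] * 4), maxfev=40000,
        )
        rss2 = float(np.sum((yd - bi(td, *p2)) ** 2))
        fits[2] = (p2, rss2)
    except RuntimeError:
        pass
    if not fits:
        raise RuntimeError("decay fit did not converge for either model")

    n = len(td)
    aicc = {k: _aicc(rss, n, {1: 3, 2: 5}[k]) for k, (_, rss) in fits.items()}
    best = min(aicc, key=aicc.get)
    if best == 2 and 1 in fits:
        # a collapsed second component (vanishing amplitude or nearly
        # equal time constants) is an over-parameterized mono fit
        a1, tau1, a2, tau2 = fits[2][0]
        share = min(a1, a2) / max(a1 + a2, 1e-300)
        ratio = max(tau1, tau2) / max(min(tau1, tau2), 1e-300)
        if share < 0.01 or ratio < 1.2:
            best = 1
    params, rss = fits[best]
    if best == 1:
        a, tau = params
        af, as_, tf, ts = float(a), 0.0, float(tau), float(tau)
        tw = tf
    else:
        a1, tau1, a2, tau2 = params
        if tau1 <= tau2:
            af, tf, as_, ts = float(a1), float(tau1), float(a2), float(tau2)
        else:
            af, tf, as_, ts = float(a2), float(tau2), float(a1), float(tau1)
        if not tf < ts:  # the two components collapsed: effectively mono
            best, (params, rss) = 1, fits[1]
            af, as_, tf, ts = float(params[0]), 0.0, float(params[1]), float(params[1])
        tw = weighted_tau(af, tf, as_, ts)
    return DecayFit(
        n_terms=best,
        af_pa=af,
        as_pa=as_,
        tau_f_ms=tf * 1e3,
        tau_s_ms=ts * 1e3,
        tau_w_ms=tw * 1e3,
        peak_pa=peak,
        rms_residual_pa=float(np.sqrt(rss / n)),
        aicc=aicc,
    )


def charge_transfer(
    sweep: Sweep, onset: float, end: float, baseline: float | None = None
) -> float:
    """Charge (pC) as the trapezoidal AUC of the baseline-subtracted
    current over [onset, end]. 1 pA*s = 1 pC; the sign follows the
    baseline-subtracted current (report magnitudes for inward events).
    The baseline defaults to the median pre-onset current; pass it
    explicitly when integrating sub-windows of one event so adjacent
    windows share a reference and charges add."""
    if not (sweep.t[0] <= onset < end <= sweep.t[-1] + 1e-12):
        raise ValueError("integration window outside the sweep")
    base = _baseline(sweep, onset) if baseline is None else baseline
    t, i = sweep.window(onset, end)
    return float(np.trapezoid(i - base, t))


def charge_window(
    sweep: Sweep,
    event_time: float,
    onset_fraction: float = 0.1,
    end_noise_mult: float = 2.0,
) -> tuple[float, float]:
    """Default onset/end for charge transfer around one transient.

    Onset is the crossing of ``onset_fraction`` of the peak after the
    event; end is the first return to within ``end_noise_mult`` noise
    SDs of baseline after the peak (or the sweep end).
    """
    t, y, base = _magnitude_trace(sweep, event_time)
    noise = 1.4826 * np.median(np.abs(sweep.i[sweep.t < event_time] - base)) if np.any(
        sweep.t < event_time
    ) else 0.0
    ipk = int(np.argmax(y))
    peak = y[ipk]
    pre = np.nonzero(y[: ipk + 1] >= onset_fraction * peak)[0]
    onset = float(t[pre[0]]) if len(pre) else float(t[0])
    post = np.nonzero(y[ipk:] <= end_noise_mult * noise)[0]
    end = float(t[ipk + post[0]]) if len(post) else float(t[-1])
    return onset, end


def _peak_after(sweep: Sweep, t0: float, search_s: float, baseline: float) -> float:
    t, i = sweep.window(t0, t0 + search_s)
    if len(i) == 0:
        raise ValueError("no samples in the pulse search window")
    y = i - baseline
    return float(np.max(np.abs(y)))


def evoked_ratios(
    sweep: Sweep,
    mode: str,
    dnqx_sweep: Sweep | None = None,
    search_s: float = 0.045,
) -> float:
    """Evoked-response ratios.

    - ``mode="ppr"``: paired-pulse ratio peak2/peak1 from two evoked
      pulses ~50 ms apart; stimulus times in ``sweep.events["stims"]``.
    - ``mode="ampa_nmda"``: AMPA/NMDA ratio from a composite sweep and
      the DNQX-resistant (NMDA-only) sweep at +40 mV: the AMPA component
      is composite minus NMDA, and the ratio is peak(AMPA)/peak(NMDA)
      with peaks of the decomposed, baseline-subtracted components.
    """
    if mode == "ppr":
        stims = sweep.events.get("stims")
        if stims is None or len(stims) != 2:
            raise ValueError("ppr mode needs two stimulus times in events['stims']")
        base = _baseline(sweep, stims[0])
        p1 = _peak_after(sweep, stims[0], search_s, base)
        p2 = _peak_after(sweep, stims[1], search_s, base)
        noise = 1.4826 * np.median(np.abs(sweep.i[sweep.t < stims[0]] - base))
        # the peak is a max over the search window, so the detectability
        # bar sits above the expected extreme of pure noise
        if p1 <= 5 * noise:
            raise ValueError("first pulse undetectable above noise")
        return p2 / p1
    if mode == "ampa_nmda":
        if dnqx_sweep is None:
            raise ValueError("ampa_nmda mode needs the DNQX (NMDA-only) sweep")
        stim = sweep.events.get("stim", sweep.t[0])
        base_c = _baseline(sweep, stim)
        base_n = _baseline(dnqx_sweep, stim)
        if len(sweep.i) != len(dnqx_sweep.i):
            raise ValueError("composite and DNQX sweeps must share a time base")
        ampa = (sweep.i - base_c) - (dnqx_sweep.i - base_n)
        nmda_peak = float(np.max(np.abs(dnqx_sweep.i - base_n)))
        ampa_peak = float(np.max(np.abs(ampa)))
        if nmda_peak == 0:
            raise ValueError("no NMDA component")
        return ampa_peak / nmda_peak
    raise ValueError(f"unknown mode {mode!r}")


def pharmacology_change(
    baseline_sweeps: list[Sweep],
    drug_sweeps: list[Sweep],
    onset: float,
    end: float,
) -> float:
    """Percentage change of the evoked current under a drug.

    The averaged drug-condition trace is compared to the averaged stable
    baseline trace: 100 * (AUC_drug - AUC_baseline) / AUC_baseline, with
    AUC per the charge-transfer contract over [onset, end] (magnitudes,
    so a reduction in current is a negative change).
    """
    if not baseline_sweeps or not drug_sweeps:
        raise ValueError("need at least one sweep per condition")

    def mean_sweep(sweeps: list[Sweep]) -> Sweep:
        i = np.mean([s.i for s in sweeps], axis=0)
        return Sweep(t=sweeps[0].t, i=i)

    auc_base = abs(charge_transfer(mean_sweep(baseline_sweeps), onset, end))
    auc_drug = abs(charge_transfer(mean_sweep(drug_sweeps), onset, end))
    if auc_base == 0:
        raise ValueError("zero baseline AUC")
    return 100.0 * (auc_drug - auc_base) / auc_base


def detect_sepscs(
    sweep: Sweep,
    epoch: tuple[float, float],
    detection_sd_mult: float = 3.0,
    refractory_s: float = 0.010,
    min_duration_s: float = 0.0005,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Threshold-based detection of spontaneous EPSCs in an epoch.

    Events are negative (inward) excursions beyond ``detection_sd_mult``
    robust noise SDs below the baseline (median of the epoch) that stay
    below threshold for at least ``min_duration_s`` (single-sample noise
    crossings are not synaptic events), with a refractory period between
    event peaks no shorter than a typical event's duration, so a decay
    tail split by noise is not double-counted. Returns (times,
    amplitudes in pA as magnitudes, frequency in Hz).
    """
    import warnings

    t0, t1 = epoch
    if t1 - t0 < 30.0:
        warnings.warn("sEPSC epoch shorter than 30 s", stacklevel=2)
    t, i = sweep.window(t0, t1)
    if len(t) == 0:
        raise ValueError("epoch outside the sweep")
    base = float(np.median(i))
    noise = 1.4826 * float(np.median(np.abs(i - base)))
    thr = base - detection_sd_mult * noise
    below = i < thr
    times, amps = [], []
    idx = np.nonzero(below)[0]
    if len(idx):
        # split threshold crossings into contiguous excursions
        splits = np.nonzero(np.diff(idx) > 1)[0] + 1
        min_samples = max(1, int(round(min_duration_s / sweep.dt)))
        for seg in np.split(idx, splits):
            if len(seg) < min_samples:
                continue
            k = seg[int(np.argmin(i[seg]))]
            if times and t[k] - times[-1] < refractory_s:
                continue
            times.append(float(t[k]))
            # median of a short window at the peak: the raw minimum
            # sample carries an extreme-value noise bias
            lo, hi = max(k - 3, 0), min(k + 4, len(i))
            amps.append(base - float(np.median(i[lo:hi])))
    freq = len(times) / (t1 - t0)
    return np.asarray(times), np.asarray(amps), freq
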