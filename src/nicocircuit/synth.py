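"""Seeded synthetic-data generators with known ground truth.

Every input modality the analysis modules consume can be generated here
with programmed, recoverable parameters: diurnal two-bottle drinking
series with a set preference and rare artifact minutes; dopamine-like
spike trains with activated/inhibited/flat responses to an injection;
multi-animal region-count matrices with planted block-correlation
modules and group mean shifts; frame-wise maze zone traces and CPP
chamber times; Gaussian-spot image stacks; and mono/bi-exponential
current transients, evoked pulse pairs and sEPSC trains.

Design notes: spike trains are a piecewise-constant-rate renewal process
with a 2-ms refractory period (dopamine-like firing without waveforms);
drinking is per-minute gamma-distributed bout volumes gated by a
circadian weight peaking after dark onset; noise is Gaussian white noise
wherever a noise SD is exposed. Identical seed and parameters always
regenerate identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import CPP_SESSION_S, EOM_BLOCK_S, CppTimes, ZoneTrace
from .boutons import VoxelStack
from .currents import Sweep
from .drinking import ARTIFACT_THRESHOLD_ML, BottleSeries
from .fosnet import RegionCountMatrix
from .spikes import SpikeTrain

__all__ = [
    "GroundTruth",
    "gen_region_counts",
    "gen_spike_train",
    "gen_drink_series",
    "gen_behavior_session",
    "gen_bouton_stack",
    "gen_current_trace",
]

#: absolute refractory period of the spike generator (s)
SPIKE_REFRACTORY_S = 0.002


@dataclass
class GroundTruth:
    """True parameters behind one generated dataset."""

    modality: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def as_json(self) -> dict:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.integer, np.floating)):
                return v.item()
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [conv(x) for x in v]
            return v

        return {"modality": self.modality, "seed": self.seed, "params": conv(self.params)}


# ---------------------------------------------------------------------------
# region-count matrices with planted correlation modules


def gen_region_counts(
    n_per_group: int,
    regions: list[str],
    planted_modules: list[list[str]],
    within_module_rho: float,
    group_mean_shift: float | dict[str, float] = 1.0,
    seed: int = 0,
    base_mean: float = 500.0,
    cv: float = 0.2,
    group_names: tuple[str, str] = ("SAC", "NIC"),
) -> tuple[RegionCountMatrix, GroundTruth]:
    """Animals x regions cFos-count matrix with planted structure.

    Counts are built from a latent equicorrelated Gaussian: regions of
    one planted module share a module factor with correlation
    ``within_module_rho``; between modules the latent variables are
    independent. Counts are ``round(mean * (1 + cv * z))`` clipped at
    zero, so the latent correlation transfers almost unchanged to the
    counts at the default coefficient of variation. Group 2's region
    means are scaled by ``group_mean_shift`` (a scalar, or a per-region
    mapping defaulting to 1).
    """
    if n_per_group < 3:
        raise ValueError("need at least 3 animals per group")
    if not regions:
        raise ValueError("regions must be non-empty")
    if not (0 <= within_module_rho < 1):
        raise ValueError("within_module_rho must lie in [0, 1)")
    flat = [r for mod in planted_modules for r in mod]
    if sorted(flat) != sorted(regions) or len(set(flat)) != len(flat):
        raise ValueError("planted_modules must partition the regions exactly once")
    if any(len(mod) == 0 for mod in planted_modules):
        raise ValueError("empty planted module")
    if isinstance(group_mean_shift, dict):
        shift = {r: float(group_mean_shift.get(r, 1.0)) for r in regions}
    else:
        shift = {r: float(group_mean_shift) for r in regions}

    rng = np.random.default_rng(seed)
    module_of = {r: m for m, mod in enumerate(planted_modules) for r in mod}
    rows, animals, groups = [], [], []
    for g, gname in enumerate(group_names):
        factors = rng.standard_normal((n_per_group, len(planted_modules)))
        eps = rng.standard_normal((n_per_group, len(regions)))
        for a in range(n_per_group):
            z = np.array(
                [
                    np.sqrt(within_module_rho) * factors[a, module_of[r]]
                    + np.sqrt(1 - within_module_rho) * eps[a, j]
                    for j, r in enumerate(regions)
                ]
            )
            mean = np.array(
                [base_mean * (shift[r] if g == 1 else 1.0) for r in regions]
            )
            counts = np.rint(np.clip(mean * (1 + cv * z), 0, None)).astype(int)
            rows.append(counts)
            animals.append(f"{gname}{a + 1:02d}")
            groups.append(gname)
    counts_df = pd.DataFrame(rows, index=animals, columns=regions)
    rcm = RegionCountMatrix(counts=counts_df, groups=pd.Series(groups, index=animals))
    gt = GroundTruth(
        modality="region_counts",
        seed=seed,
        params={
            "n_per_group": n_per_group,
            "planted_modules": planted_modules,
            "module_of": module_of,
            "within_module_rho": within_module_rho,
            "group_mean_shift": shift,
            "base_mean": base_mean,
            "cv": cv,
            "group_names": list(group_names),
        },
    )
    return rcm, gt


# ---------------------------------------------------------------------------
# spike trains


def _renewal_lambda(
    rate_hz: float, refractory_s: float, short_isi_s: float | None
) -> float:
    """Exponential rate for the renewal ISI tail so the mean ISI is
    exactly 1/rate.

    Without the short-ISI constraint this is closed form. With it (no
    ISI below ``short_isi_s`` may follow another), ISIs form a two-state
    Markov chain - a draw following a short ISI is floored at the short
    limit - and lambda solves the stationary mean-ISI equation
    numerically."""
    if short_isi_s is None:
        return rate_hz / (1.0 - rate_hz * refractory_s)

    from scipy.optimize import brentq

    target = 1.0 / rate_hz

    def mean_isi(lam: float) -> float:
        p_short = 1.0 - np.exp(-lam * max(short_isi_s - refractory_s, 0.0))
        q = p_short / (1.0 + p_short)  # stationary fraction of floored draws
        m_free = refractory_s + 1.0 / lam
        m_floored = short_isi_s + 1.0 / lam
        return (1.0 - q) * m_free + q * m_floored

    lo = rate_hz / 2.0
    hi = rate_hz
    while mean_isi(hi) > target and hi < 1e6:
        hi *= 2.0
    return float(brentq(lambda lam: mean_isi(lam) - target, lo, hi))


def _renewal_times(
    rng: np.random.Generator,
    segments: list[tuple[float, float, float]],
    refractory_s: float = SPIKE_REFRACTORY_S,
    no_consecutive_short_s: float | None = None,
) -> list[float]:
    """One renewal chain over piecewise-constant-rate ``segments``
    ((t0, t1, rate) triples), mean rate exact per segment.

    ISI = refractory + Exp(lambda(segment)); when
    ``no_consecutive_short_s`` is set, an ISI following one shorter than
    that limit is floored at the limit (so no two consecutive short ISIs
    occur anywhere in the train) and lambda is compensated to preserve
    the mean rate."""
    lams = [
        _renewal_lambda(rate, refractory_s, no_consecutive_short_s) if rate > 0 else 0.0
        for _, _, rate in segments
    ]
    end = segments[-1][1]

    def lam_at(t: float) -> float:
        for (t0, t1, _), lam in zip(segments, lams):
            if t0 <= t < t1:
                return lam
        return lams[-1]

    out: list[float] = []
    lam0 = lam_at(0.0)
    if lam0 <= 0:
        return out
    t = rng.exponential(1.0 / lam0)  # start mid-interval
    prev_short = False
    while t < end:
        out.append(t)
        lam = lam_at(t)
        if lam <= 0:  # silent segment: jump to its end
            t = next(t1 for t0, t1, r in segments if t0 <= t < t1)
            prev_short = False
            continue
        floor = (
            no_consecutive_short_s
            if (no_consecutive_short_s is not None and prev_short)
            else refractory_s
        )
        isi = floor + rng.exponential(1.0 / lam)
        prev_short = no_consecutive_short_s is not None and isi < no_consecutive_short_s
        t += isi
    return out


def gen_spike_train(
    duration_s: float,
    baseline_rate_hz: float,
    response_kind: str,
    response_magnitude: float = 0.0,
    injection_time_s: float = 300.0,
    burst_fraction: float = 0.0,
    seed: int = 0,
    response_duration_s: float = 180.0,
    injection_type: str = "nicotine",
) -> tuple[SpikeTrain, GroundTruth]:
    """Dopamine-like spike train with a rate step after an injection.

    The firing rate is piecewise constant: baseline before the injection
    and after the response period, and baseline * (1 + magnitude)
    (activated) or * (1 - magnitude) (inhibited) in between; flat trains
    ignore the magnitude. Optionally a fraction of spikes is organized
    into bursts (3-spike groups with 20-70 ms intra-burst intervals,
    isolated by >160-ms gaps); with ``burst_fraction=0`` the generator
    enforces that no ISI below 80 ms directly follows another, so no
    multi-spike burst exists by construction.
    """
    if response_kind not in {"activated", "inhibited", "flat"}:
        raise ValueError(f"unknown response kind {response_kind!r}")
    if duration_s < injection_time_s + 180.0:
        raise ValueError("duration must cover injection + 180 s")
    if not (0.1 < baseline_rate_hz <= 15.0):
        raise ValueError("baseline rate must lie in (0.1, 15] Hz (dopamine-like)")
    if response_kind == "inhibited" and not (0 <= response_magnitude <= 1):
        raise ValueError("inhibited magnitude must lie in [0, 1]")
    if response_kind == "activated" and response_magnitude < 0:
        raise ValueError("activated magnitude must be non-negative")

    rng = np.random.default_rng(seed)
    if response_kind == "activated":
        resp_rate = baseline_rate_hz * (1 + response_magnitude)
    elif response_kind == "inhibited":
        resp_rate = baseline_rate_hz * (1 - response_magnitude)
    else:
        resp_rate = baseline_rate_hz
    segs = [
        (0.0, injection_time_s, baseline_rate_hz),
        (injection_time_s, injection_time_s + response_duration_s, resp_rate),
        (injection_time_s + response_duration_s, duration_s, baseline_rate_hz),
    ]
    # with burst_fraction 0 the renewal chain itself forbids consecutive
    # <80-ms ISIs (rate-compensated), so no multi-spike burst exists
    no_short = 0.080 if burst_fraction == 0.0 else None
    segs = [(t0, t1, r) for t0, t1, r in segs if t1 > t0]
    times = _renewal_times(rng, segs, no_consecutive_short_s=no_short)
    if burst_fraction > 0.0:
        times = _insert_bursts(rng, times, burst_fraction)

    train = SpikeTrain(
        times=np.asarray(times),
        duration_s=duration_s,
        injections=[(injection_time_s, injection_type)],
    )
    gt = GroundTruth(
        modality="spike_train",
        seed=seed,
        params={
            "baseline_rate_hz": baseline_rate_hz,
            "response_kind": response_kind,
            "response_magnitude": response_magnitude,
            "injection_time_s": injection_time_s,
            "response_duration_s": response_duration_s,
            "burst_fraction": burst_fraction,
        },
    )
    return train, gt


def _insert_bursts(
    rng: np.random.Generator, times: list[float], burst_fraction: float
) -> list[float]:
    """Replace isolated spikes by 3-spike bursts until roughly the target
    fraction of spikes lies within bursts."""
    times = list(times)
    if not times:
        return times
    n_target = burst_fraction * len(times)
    burst_spikes = 0
    out: list[float] = []
    i = 0
    while i < len(times):
        t = times[i]
        gap_ok = (i + 1 >= len(times) or times[i + 1] - t > 0.4) and (
            not out or t - out[-1] > 0.4
        )
        if burst_spikes < n_target and gap_ok:
            isis = rng.uniform(0.020, 0.070, size=2)
            out.extend([t, t + isis[0], t + isis[0] + isis[1]])
            burst_spikes += 3
        else:
            out.append(t)
        i += 1
    return sorted(out)


# ---------------------------------------------------------------------------
# two-bottle drinking


def gen_drink_series(
    n_days: int,
    true_preference: float,
    dark_onset_hour: int = 20,
    diurnal_concentration: float = 2.0,
    artifact_rate: float = 0.0,
    seed: int = 0,
    test_content: str = "nicotine 100ug/ml",
    habituation_days: int = 0,
    side_preference: float = 0.5,
    animal: str = "m1",
    mean_bout_ml: float = 0.010,
    bouts_per_day: float = 400.0,
    start_weight_g: float = 25.0,
) -> tuple[BottleSeries, GroundTruth]:
    """Minute-resolution two-bottle drinking series.

    Each minute independently hosts a drinking bout with probability
    proportional to a von Mises circadian weight (concentration
    ``diurnal_concentration``) peaking one hour after dark onset, so
    drinking concentrates shortly after the dark cycle begins. Bout
    volumes are gamma-distributed (shape 4) with mean ``mean_bout_ml``,
    capped at the 0.1-ml artifact threshold so genuine bouts survive
    cleaning; the defaults (~400 drinking minutes/day of ~0.01 ml)
    give a realistic ~4 ml daily intake with enough events that an
    8-session preference estimate carries roughly a one-percentage-point
    standard error. Each bout goes to the test bottle with probability
    ``true_preference`` (during habituation both bottles hold water and
    the choice follows ``side_preference`` for the left side). Bottle
    sides swap every 2 days. Artifact minutes (volume > 0.1 ml) are
    injected with per-minute probability ``artifact_rate``. Weights are
    emitted every other day with slow linear growth.
    """
    if not (0 <= true_preference <= 1):
        raise ValueError("preference must lie in [0, 1]")
    if not (0 <= side_preference <= 1):
        raise ValueError("side_preference must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    total_days = habituation_days + n_days
    start = pd.Timestamp("2024-01-01 00:00")
    minutes = pd.date_range(start, periods=total_days * 1440, freq="min")

    hour_angle = np.asarray(
        (minutes.hour + minutes.minute / 60.0 - (dark_onset_hour + 1)) / 24.0 * 2 * np.pi
    )
    weight = np.exp(diurnal_concentration * np.cos(hour_angle))
    p_bout = np.minimum(bouts_per_day * weight / weight[:1440].sum(), 1.0)

    is_bout = rng.random(len(minutes)) < p_bout
    n_bouts = int(is_bout.sum())
    vols = np.minimum(
        rng.gamma(shape=4.0, scale=mean_bout_ml / 4.0, size=n_bouts),
        ARTIFACT_THRESHOLD_ML,
    )
    day_index = np.asarray((minutes - start).days)
    in_habituation = day_index < habituation_days

    # per-day side of bottle b1 (swap every 2 days); b2 is the opposite
    b1_side = ["left" if (d // 2) % 2 == 0 else "right" for d in range(total_days)]

    choose_test = rng.random(n_bouts) < true_preference
    choose_left = rng.random(n_bouts) < side_preference

    rows = []
    bout_minutes = np.nonzero(is_bout)[0]
    for k, m in enumerate(bout_minutes):
        d = int(day_index[m])
        if in_habituation[m]:
            side = "left" if choose_left[k] else "right"
            bottle = "b1" if b1_side[d] == side else "b2"
        else:
            bottle = "b1" if choose_test[k] else "b2"  # b1 holds the test solution
        rows.append((minutes[m], bottle, float(vols[k])))

    if artifact_rate > 0:
        is_art = rng.random(len(minutes)) < artifact_rate
        for m in np.nonzero(is_art)[0]:
            rows.append(
                (minutes[m], rng.choice(["b1", "b2"]), float(rng.uniform(0.11, 0.5)))
            )

    data = (
        pd.DataFrame(rows, columns=["timestamp", "bottle", "volume_ml"])
        # one reading per bottle-minute: a bout and an artifact falling on
        # the same minute add on the same sensor
        .groupby(["bottle", "timestamp"], as_index=False)["volume_ml"]
        .sum()
        .sort_values(["bottle", "timestamp"], kind="stable")
        .reset_index(drop=True)[["timestamp", "bottle", "volume_ml"]]
    )
    n_artifacts = int((data["volume_ml"] > ARTIFACT_THRESHOLD_ML).sum())

    labels = []
    for d in range(total_days):
        date = (start + pd.Timedelta(days=d)).date()
        content_b1 = "water" if d < habituation_days else test_content
        s1 = b1_side[d]
        s2 = "right" if s1 == "left" else "left"
        labels.append((date, "b1", content_b1, s1))
        labels.append((date, "b2", "water", s2))
    labels_df = pd.DataFrame(labels, columns=["date", "bottle", "content", "side"])

    weights = []
    for d in range(0, total_days + 1, 2):
        date = (start + pd.Timedelta(days=d)).date()
        weights.append((animal, date, start_weight_g + 0.05 * d + rng.normal(0, 0.1)))
    weights_df = pd.DataFrame(weights, columns=["animal", "date", "grams"])

    series = BottleSeries(animal=animal, data=data, labels=labels_df, weights=weights_df)
    gt = GroundTruth(
        modality="drink_series",
        seed=seed,
        params={
            "n_days": n_days,
            "habituation_days": habituation_days,
            "true_preference": true_preference,
            "side_preference": side_preference,
            "dark_onset_hour": dark_onset_hour,
            "diurnal_concentration": diurnal_concentration,
            "artifact_rate": artifact_rate,
            "n_artifact_minutes": n_artifacts,
            "test_content": test_content,
        },
    )
    return series, gt


# ---------------------------------------------------------------------------
# maze / CPP sessions


def gen_behavior_session(
    kind: str,
    params: dict,
    fps: float = 30.0,
    seed: int = 0,
) -> tuple[ZoneTrace | CppTimes, GroundTruth]:
    """Synthetic EOM zone trace or CPP session times.

    - ``kind="eom"``: ``params["block_biases"]`` gives the per-block
      probability that a frame is in the open arms; the trace is 9 min
      of frame-wise Bernoulli draws, so per-block open fractions match
      the programmed bias up to binomial error.
    - ``kind="cpp"``: ``params["shift_s"]`` is the programmed gain of
      paired-chamber time from pretest to test (taken from the unpaired
      chamber); ``params.get("noise_s", 7.0)`` is the SD of Gaussian
      noise on chamber times. Sessions are renormalized to 900 s.
    """
    rng = np.random.default_rng(seed)
    if kind == "eom":
        biases = params["block_biases"]
        if len(biases) != 3 or any(not (0 <= b <= 1) for b in biases):
            raise ValueError("need three open-arm biases in [0, 1]")
        frames_per_block = int(round(EOM_BLOCK_S * fps))
        zones = []
        for b in biases:
            opens = rng.random(frames_per_block) < b
            zones.extend("open" if o else "closed" for o in opens)
        trace = ZoneTrace(fps=fps, zones=np.asarray(zones))
        gt = GroundTruth(
            modality="eom", seed=seed, params={"block_biases": list(biases), "fps": fps}
        )
        return trace, gt
    if kind == "cpp":
        shift = float(params["shift_s"])
        noise = float(params.get("noise_s", 7.0))
        paired = params.get("paired", "A")
        base = {"A": 375.0, "B": 375.0, "neutral": 150.0}
        pre = {k: v + rng.normal(0, noise) for k, v in base.items()}
        unpaired = "B" if paired == "A" else "A"
        post = dict(pre)
        post[paired] = pre[paired] + shift + rng.normal(0, noise)
        post[unpaired] = pre[unpaired] - shift + rng.normal(0, noise)
        post["neutral"] = pre["neutral"] + rng.normal(0, noise)

        def renorm(d: dict) -> dict:
            s = sum(d.values())
            return {k: v * CPP_SESSION_S / s for k, v in d.items()}

        times = CppTimes(pretest=renorm(pre), test=renorm(post), paired=paired)
        gt = GroundTruth(
            modality="cpp",
            seed=seed,
            params={"shift_s": shift, "noise_s": noise, "paired": paired},
        )
        return times, gt
    raise ValueError(f"unknown behavior session kind {kind!r}")


# ---------------------------------------------------------------------------
# bouton stacks


def gen_bouton_stack(
    shape_vox: tuple[int, int, int],
    voxel_size_um: tuple[float, float, float],
    spots: list[tuple[tuple[float, float, float], float, float]],
    background: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[VoxelStack, GroundTruth]:
    """Stack = background + sum of anisotropic Gaussian spots + noise.

    ``spots`` is a list of (centroid_vox (z, y, x), amplitude, sigma_um);
    each spot's sigma is isotropic in um, hence anisotropic in voxels.
    Centroids must be inside the stack and pairwise distinct.
    """
    for c, _, sigma in spots:
        if sigma <= 0:
            raise ValueError("spot sigma must be positive")
        if any(not (0 <= c[a] < shape_vox[a]) for a in range(3)):
            raise ValueError(f"spot centroid {c} outside stack bounds {shape_vox}")
    centroids = [tuple(c) for c, _, _ in spots]
    if len(set(centroids)) != len(centroids):
        raise ValueError("overlapping identical centroids")

    rng = np.random.default_rng(seed)
    img = np.full(shape_vox, float(background))
    vox = np.asarray(voxel_size_um)
    for (cz, cy, cx), amp, sigma in spots:
        sig_vox = sigma / vox  # per-axis sigma in voxels
        half = np.ceil(4 * sig_vox).astype(int)
        lo = np.maximum(np.floor([cz, cy, cx]).astype(int) - half, 0)
        hi = np.minimum(np.ceil([cz, cy, cx]).astype(int) + half + 1, shape_vox)
        zz, yy, xx = np.meshgrid(
            np.arange(lo[0], hi[0]),
            np.arange(lo[1], hi[1]),
            np.arange(lo[2], hi[2]),
            indexing="ij",
        )
        d2 = (
            ((zz - cz) / sig_vox[0]) ** 2
            + ((yy - cy) / sig_vox[1]) ** 2
            + ((xx - cx) / sig_vox[2]) ** 2
        )
        img[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amp * np.exp(-d2 / 2.0)
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0, noise_sd, size=img.shape), 0, None)
    stack = VoxelStack(data=img, voxel_size_um=tuple(voxel_size_um))
    gt = GroundTruth(
        modality="bouton_stack",
        seed=seed,
        params={
            "spots": [
                {"centroid_vox": list(c), "amplitude": a, "sigma_um": s}
                for c, a, s in spots
            ],
            "background": background,
            "noise_sd": noise_sd,
        },
    )
    return stack, gt


# ---------------------------------------------------------------------------
# patch-clamp traces


def _epsc_template(t: np.ndarray, rise_s: float = 0.001, decay_s: float = 0.005) -> np.ndarray:
    y = (1 - np.exp(-t / rise_s)) * np.exp(-t / decay_s)
    return y / y.max()


def gen_current_trace(
    kind: str,
    params: dict,
    dt: float = 1e-4,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Sweep, GroundTruth]:
    """Synthetic voltage-clamp sweep (inward currents negative).

    - ``kind="puff_decay"``: bi-exponential transient after
      ``params.get("onset_s", 0.05)``:
      I(t) = -(AF exp(-t/tau_f) + AS exp(-t/tau_s)); params AF, AS in
      pA, tau_f, tau_s in s (tau_f < tau_s when both amplitudes > 0).
    - ``kind="evoked_pair"``: two stereotyped EPSC transients 50 ms
      apart with ``params["amplitudes"]``; stimulus times in events.
    - ``kind="sepsc_train"``: Poisson events at ``params["rate_hz"]``
      with template shape and i.i.d. normal amplitudes
      (``amp_mean_pa``, ``amp_sd_pa``) over ``params["duration_s"]``.
    """
    rng = np.random.default_rng(seed)
    if kind == "puff_decay":
        af, as_ = float(params["AF"]), float(params.get("AS", 0.0))
        tf = float(params["tau_f"])
        ts = float(params.get("tau_s", tf))
        if tf <= 0 or ts <= 0:
            raise ValueError("time constants must be positive")
        if as_ > 0 and not tf < ts:
            raise ValueError("expected tau_f < tau_s")
        onset = float(params.get("onset_s", 0.05))
        duration = float(params.get("duration_s", onset + 10 * ts))
        t = np.arange(0.0, duration, dt)
        i = np.zeros_like(t)
        post = t >= onset
        td = t[post] - onset
        i[post] = -(af * np.exp(-td / tf) + as_ * np.exp(-td / ts))
        events = {"puff": onset}
        gt_params = {"AF": af, "AS": as_, "tau_f": tf, "tau_s": ts, "onset_s": onset}
    elif kind == "evoked_pair":
        a1, a2 = (float(a) for a in params["amplitudes"])
        gap = float(params.get("gap_s", 0.050))
        onset = float(params.get("onset_s", 0.05))
        duration = float(params.get("duration_s", onset + gap + 0.15))
        t = np.arange(0.0, duration, dt)
        i = np.zeros_like(t)
        for t0, amp in ((onset, a1), (onset + gap, a2)):
            post = t >= t0
            i[post] += -amp * _epsc_template(t[post] - t0)
        events = {"stims": [onset, onset + gap]}
        gt_params = {"amplitudes": [a1, a2], "gap_s": gap, "ppr": a2 / a1}
    elif kind == "sepsc_train":
        rate = float(params["rate_hz"])
        duration = float(params.get("duration_s", 30.0))
        amp_mean = float(params.get("amp_mean_pa", 30.0))
        amp_sd = float(params.get("amp_sd_pa", 5.0))
        t = np.arange(0.0, duration, dt)
        i = np.zeros_like(t)
        n_events = rng.poisson(rate * duration)
        ev_times = np.sort(rng.uniform(0, duration - 0.05, size=n_events))
        ev_amps = np.clip(rng.normal(amp_mean, amp_sd, size=n_events), 5.0, None)
        for t0, amp in zip(ev_times, ev_amps):
            post = (t >= t0) & (t < t0 + 0.04)
            i[post] += -amp * _epsc_template(t[post] - t0)
        events = {"sepsc_times": ev_times.tolist()}
        gt_params = {
            "rate_hz": rate,
            "duration_s": duration,
            "n_events": int(n_events),
            "amp_mean_pa": amp_mean,
            "amp_sd_pa": amp_sd,
            "event_times": ev_times.tolist(),
            "event_amps": ev_amps.tolist(),
        }
    else:
        raise ValueError(f"unknown current trace kind {kind!r}")
    if noise_sd > 0:
        i = i + rng.normal(0, noise_sd, size=i.shape)
    sweep = Sweep(t=t, i=i, events=events)
    gt = GroundTruth(modality=f"current_{kind}", seed=seed, params=gt_params)
    return sweep, gt
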