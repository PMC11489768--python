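"""3D segmentation of fluorescent presynaptic boutons.

Seeds are 26-neighborhood local intensity maxima above a histogram-derived
(or explicit) threshold. Around each seed the local intensity profile is
fitted to a Gaussian per axis; the border intensity is set where the
central 95% of the Gaussian's area lies (|x| <= 1.96 sigma), i.e.

    border = background + exp(-1.96**2 / 2) * amplitude
           ~ background + 0.146 * amplitude,

so boutons of similar size but different brightness segment to similar
volumes. From each seed, voxels are grown block-wise under three
criteria: intensity above the border threshold, intensity not above the
previously included voxel on the inclusion path (monotone descent), and
confirmation by an already-included neighbor closer to the seed.
Contested voxels go to the seed reached along the brighter path (growth
is driven by a global intensity-ordered queue). Counts are normalized to
a standard volume of 10 x 10 x 10 um to compare stacks of different
sizes.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.stats import norm

__all__ = [
    "VoxelStack",
    "Bouton",
    "BoutonDensity",
    "border_factor",
    "auto_threshold",
    "detect_seeds",
    "grow_boutons",
    "bouton_density",
]

STANDARD_VOLUME_UM3 = 10.0 * 10.0 * 10.0
DEFAULT_VOLUME_BOUNDS_UM3 = (0.01, 1.0)


@dataclass
class VoxelStack:
    """3D grayscale stack with anisotropic voxel size.

    ``data`` is indexed (z, y, x); ``voxel_size_um`` gives the um extent
    of one voxel per axis in the same order (e.g. (0.2, 0.05, 0.05) for
    a 200-nm z-step and 50-nm pixels).
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("expected a 3D stack")
        if not np.all(np.isfinite(self.data)) or self.data.min() < 0:
            raise ValueError("intensities must be finite and non-negative")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))

    @property
    def volume_um3(self) -> float:
        return float(self.data.size) * self.voxel_volume_um3


@dataclass
class Bouton:
    """One segmented bouton."""

    seed: tuple[int, int, int]
    voxels: list[tuple[int, int, int]]
    volume_um3: float
    centroid_um: tuple[float, float, float]
    peak_intensity: float
    border_threshold: float


@dataclass
class BoutonDensity:
    count: int
    stack_volume_um3: float
    per_standard_volume: float  # boutons per 10x10x10 um


def border_factor(area_fraction: float = 0.95) -> float:
    """Intensity fraction at the border of the central ``area_fraction``
    of a Gaussian: exp(-z**2/2) with z the two-sided quantile (1.96 for
    95%), ~0.146."""
    z = norm.ppf(0.5 + area_fraction / 2.0)
    return float(np.exp(-(z**2) / 2.0))


def _histogram_mode(values: np.ndarray, bins: int = 256) -> float:
    hist, edges = np.histogram(values, bins=bins)
    k = int(np.argmax(hist))
    return float((edges[k] + edges[k + 1]) / 2.0)


def auto_threshold(stack: VoxelStack, noise_mult: float = 5.0) -> float:
    """Histogram-based seed-detection threshold.

    Background is the mode of the intensity histogram; noise is the
    robust (MAD) spread around it; the threshold sits ``noise_mult``
    noise SDs above background so only maxima from labeled objects are
    retained.
    """
    vals = stack.data.ravel()
    bg = _histogram_mode(vals)
    noise = 1.4826 * float(np.median(np.abs(vals - bg)))
    return bg + noise_mult * max(noise, 1e-12)


_NEIGHBORS26 = [
    d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
]


def detect_seeds(
    stack: VoxelStack,
    intensity_threshold: float | None = None,
    smooth_sigma_vox: float = 0.0,
) -> list[tuple[int, int, int]]:
    """26-neighborhood local maxima at or above the intensity threshold.

    Optional Gaussian pre-smoothing (in voxel units) suppresses
    single-voxel noise maxima on noisy stacks. Plateau maxima (flat
    connected regions of equal value) are resolved to the single voxel
    with the lowest linear index. An above-global-max threshold yields
    an empty list with a warning.
    """
    import warnings

    img = stack.data
    if smooth_sigma_vox > 0:
        img = ndimage.gaussian_filter(img, smooth_sigma_vox)
    if intensity_threshold is None:
        intensity_threshold = auto_threshold(VoxelStack(img, stack.voxel_size_um))
    if intensity_threshold > img.max():
        warnings.warn("threshold above the global maximum: no seeds", stacklevel=2)
        return []
    is_max = (img == ndimage.maximum_filter(img, size=3, mode="reflect")) & (
        img >= intensity_threshold
    )
    # objects clipped by the stack border are not counted; this also
    # removes spurious maxima from the filter's edge padding
    for axis in range(3):
        is_max[(slice(None),) * axis + (0,)] = False
        is_max[(slice(None),) * axis + (-1,)] = False
    labels, n = ndimage.label(is_max, structure=np.ones((3, 3, 3), dtype=int))
    seeds = []
    flat = np.arange(img.size).reshape(img.shape)
    for lab in range(1, n + 1):
        idx = flat[labels == lab].min()  # lowest linear index on the plateau
        seeds.append(tuple(int(c) for c in np.unravel_index(idx, img.shape)))
    return sorted(seeds)


def _fit_axis_gaussian(
    profile: np.ndarray, center: int, background: float
) -> tuple[float, float] | None:
    """Fit A*exp(-(x-mu)^2/(2 sigma^2)) + b to a 1D profile through the
    seed; returns (amplitude, sigma) or None on a degenerate fit."""
    x = np.arange(len(profile), dtype=float)
    a0 = max(profile[center] - background, 1e-9)

    def model(xx, a, mu, sigma, b):
        return a * np.exp(-((xx - mu) ** 2) / (2 * sigma**2)) + b

    try:
        p, _ = curve_fit(
            model, x, profile,
            p0=[a0, float(center), 2.0, background],
            bounds=([0, -1, 1e-3, -np.inf], [np.inf, len(profile), len(profile), np.inf]),
            maxfev=5000,
        )
    except RuntimeError:
        return None
    a, _, sigma, _ = p
    if a <= 0 or sigma <= 0:
        return None
    return float(a), float(sigma)


def _seed_threshold(
    img: np.ndarray,
    seed: tuple[int, int, int],
    background: float,
    area_fraction: float,
    fit_halfwidth: int = 10,
) -> float | None:
    """Per-seed border threshold from per-axis Gaussian fits.

    The border is background + exp(-z^2/2) * amplitude with z the
    central-area quantile; the amplitude is the mean of the per-axis
    fitted amplitudes. None when every axis fit is degenerate.
    """
    amps = []
    for axis in range(3):
        sl = list(seed)
        lo = max(seed[axis] - fit_halfwidth, 0)
        hi = min(seed[axis] + fit_halfwidth + 1, img.shape[axis])
        sl[axis] = slice(lo, hi)
        profile = img[tuple(sl)].astype(float)
        fit = _fit_axis_gaussian(profile, seed[axis] - lo, background)
        if fit is not None:
            amps.append(fit[0])
    if not amps:
        return None
    return background + border_factor(area_fraction) * float(np.mean(amps))


def grow_boutons(
    stack: VoxelStack,
    seeds: list[tuple[int, int, int]],
    area_fraction: float = 0.95,
    volume_bounds_um3: tuple[float, float] = DEFAULT_VOLUME_BOUNDS_UM3,
    background: float | None = None,
    smooth_sigma_vox: float = 0.0,
) -> list[Bouton]:
    """Grow boutons from seeds under the block-inclusion criteria.

    Growth is driven by one global priority queue ordered by candidate
    intensity, so each voxel is claimed by whichever seed reaches it
    along the brighter path; a candidate is included when (1) its
    intensity is at or above the seed's border threshold, (2) it is not
    brighter than the already-included voxel it extends (monotone
    descent from the seed), and (3) it has an already-included
    26-neighbor strictly closer (in um) to the seed. Objects outside
    ``volume_bounds_um3`` are discarded; seeds with degenerate Gaussian
    fits are dropped.
    """
    img = stack.data
    if smooth_sigma_vox > 0:
        img = ndimage.gaussian_filter(img, smooth_sigma_vox)
    if background is None:
        background = _histogram_mode(img.ravel())
    vz, vy, vx = stack.voxel_size_um

    def dist_um(a: tuple[int, int, int], b: tuple[int, int, int]) -> float:
        return float(
            np.sqrt(((a[0] - b[0]) * vz) ** 2 + ((a[1] - b[1]) * vy) ** 2 + ((a[2] - b[2]) * vx) ** 2)
        )

    thresholds: dict[int, float] = {}
    kept_seeds: list[tuple[int, int, int]] = []
    for s in seeds:
        thr = _seed_threshold(img, s, background, area_fraction)
        if thr is None:
            continue  # degenerate fit: seed dropped
        thresholds[len(kept_seeds)] = thr
        kept_seeds.append(s)

    owner = np.full(img.shape, -1, dtype=int)
    heap: list[tuple[float, int, tuple[int, int, int], int, float]] = []
    counter = 0
    for sid, s in enumerate(kept_seeds):
        heapq.heappush(heap, (-float(img[s]), counter, s, sid, np.inf))
        counter += 1
    shape = img.shape
    while heap:
        negint, _, vox, sid, parent_int = heapq.heappop(heap)
        if owner[vox] != -1:
            continue
        inten = -negint
        if inten < thresholds[sid]:
            continue
        if inten > parent_int + 1e-12:
            continue  # would break monotone descent
        if np.isfinite(parent_int):
            # criterion 3: an included neighbor closer to the seed
            d = dist_um(vox, kept_seeds[sid])
            confirmed = False
            for dz, dy, dx in _NEIGHBORS26:
                nb = (vox[0] + dz, vox[1] + dy, vox[2] + dx)
                if (
                    0 <= nb[0] < shape[0]
                    and 0 <= nb[1] < shape[1]
                    and 0 <= nb[2] < shape[2]
                    and owner[nb] == sid
                    and dist_um(nb, kept_seeds[sid]) < d
                ):
                    confirmed = True
                    break
            if not confirmed:
                continue
        owner[vox] = sid
        for dz, dy, dx in _NEIGHBORS26:
            nb = (vox[0] + dz, vox[1] + dy, vox[2] + dx)
            if (
                0 <= nb[0] < shape[0]
                and 0 <= nb[1] < shape[1]
                and 0 <= nb[2] < shape[2]
                and owner[nb] == -1
            ):
                heapq.heappush(heap, (-float(img[nb]), counter, nb, sid, inten))
                counter += 1

    vol_per_vox = stack.voxel_volume_um3
    out: list[Bouton] = []
    for sid, s in enumerate(kept_seeds):
        coords = np.argwhere(owner == sid)
        if len(coords) == 0:
            continue
        volume = len(coords) * vol_per_vox
        if not (volume_bounds_um3[0] <= volume <= volume_bounds_um3[1]):
            continue
        centroid = coords.mean(axis=0) * np.array([vz, vy, vx])
        out.append(
            Bouton(
                seed=s,
                voxels=[tuple(int(c) for c in row) for row in coords],
                volume_um3=float(volume),
                centroid_um=tuple(float(c) for c in centroid),
                peak_intensity=float(stack.data[s]),
                border_threshold=thresholds[sid],
            )
        )
    return out


def bouton_density(boutons: list[Bouton], stack: VoxelStack) -> BoutonDensity:
    """Bouton count normalized to the 10 x 10 x 10 um standard volume."""
    vol = stack.volume_um3
    if vol <= 0:
        raise ValueError("stack volume must be positive")
    return BoutonDensity(
        count=len(boutons),
        stack_volume_um3=vol,
        per_standard_volume=len(boutons) * STANDARD_VOLUME_UM3 / vol,
    )
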