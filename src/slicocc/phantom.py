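"""Digital occupancy phantom: ground-truth EC50 volumes and simulated image series.

The phantom emulates a voxel-level receptor-occupancy study: a brain-shaped
mask holds a ground-truth EC50 volume (low-EC50 background plus bilateral
high-EC50 "hot spots"), from which ideal occupancy volumes are generated at a
set of plasma concentrations with the hyperbolic Emax model

    Occ = Occ_max * C / (C + EC50).

Measurement noise is occupancy-dependent Gaussian, sigma = slope*Occ +
intercept (per voxel, per concentration), and spatial correlation is induced
by a small fixed-size Gaussian smoothing kernel.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "Ellipsoid",
    "PhantomSpec",
    "GroundTruth",
    "OccupancySeries",
    "build_phantom",
    "ideal_occupancy",
    "apply_noise",
    "smooth_series",
    "simulate_study",
    "stage_seed",
]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage RNG seed (< 2**31) from one global seed."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in voxel coordinates (0-based indices)."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        idx = np.indices(shape, dtype=float)
        d = sum(
            ((idx[i] - self.center[i]) / self.radii[i]) ** 2 for i in range(3)
        )
        return d <= 1.0


def _default_hotspots() -> list[tuple[str, Ellipsoid, float]]:
    # Bilateral pairs: caudate-like (EC50 = 25 ng/mL) superior,
    # putamen-like (EC50 = 50 ng/mL) inferior; each ellipsoid > 1500 voxels
    # on the default 64^3 grid.
    return [
        ("caudate", Ellipsoid((22.0, 34.0, 40.0), (7.0, 8.0, 7.0)), 25.0),
        ("caudate", Ellipsoid((41.0, 34.0, 40.0), (7.0, 8.0, 7.0)), 25.0),
        ("putamen", Ellipsoid((16.0, 30.0, 24.0), (6.0, 8.0, 8.0)), 50.0),
        ("putamen", Ellipsoid((47.0, 30.0, 24.0), (6.0, 8.0, 8.0)), 50.0),
    ]


@dataclass
class PhantomSpec:
    """Complete recipe for one simulated occupancy study.

    Defaults give the desk-scale study: 64^3 grid (1 mm isotropic), an
    ellipsoidal brain of ~1.1e5 voxels, hot spots at EC50 = 25 and 50 ng/mL,
    background EC50 uniform in [6, 10] ng/mL, Occ_max = 0.85, ten log-spaced
    plasma concentrations spanning 3-279 ng/mL, noise SD = -0.22*Occ + 0.25,
    and 3x3x3 Gaussian smoothing with sigma = 0.5 voxels.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 1.0
    brain_region: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((31.5, 31.5, 31.5), (30.0, 30.0, 29.0))
    )
    hotspot_regions: list[tuple[str, Ellipsoid, float]] = field(
        default_factory=_default_hotspots
    )
    background_ec50_range: tuple[float, float] = (6.0, 10.0)
    background_mode: str = "uniform"  # "uniform" per-voxel draw, or "constant"
    occ_max_true: float = 0.85
    concentrations: np.ndarray = field(
        default_factory=lambda: np.geomspace(3.0, 279.0, 10)
    )
    noise_slope: float = -0.22
    noise_intercept: float = 0.25
    sigma_gauss_voxels: float = 0.5
    smooth_kernel: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        lo, hi = self.background_ec50_range
        if lo > hi or lo <= 0:
            raise ValueError("background_ec50_range must satisfy 0 < low <= high")
        if not (0 < self.occ_max_true <= 1):
            raise ValueError("occ_max_true must lie in (0, 1]")
        c = self.concentrations
        if c.ndim != 1 or np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be positive and strictly increasing")
        if self.smooth_kernel % 2 == 0 or self.smooth_kernel < 1:
            raise ValueError("smooth_kernel must be a positive odd integer")
        if self.sigma_gauss_voxels < 0:
            raise ValueError("sigma_gauss_voxels must be nonnegative")
        if self.background_mode not in ("uniform", "constant"):
            raise ValueError("background_mode must be 'uniform' or 'constant'")
        # the noise SD must stay positive over the occupancy range [0, occ_max]
        noise_on = not (self.noise_slope == 0.0 and self.noise_intercept == 0.0)
        if noise_on:
            sd_lo = self.noise_slope * self.occ_max_true + self.noise_intercept
            sd_hi = self.noise_intercept
            if min(sd_lo, sd_hi) <= 0:
                raise ValueError(
                    "noise SD slope*Occ + intercept must be positive on [0, occ_max]"
                )


@dataclass
class GroundTruth:
    """Voxelwise truth of the phantom.

    label_image: 0 outside the brain, 1 background, >= 2 hot-spot regions
    (bilateral pairs of one named region share a label).
    """

    ec50_image: np.ndarray
    occmax_image: np.ndarray
    label_image: np.ndarray
    brain_mask: np.ndarray
    region_labels: dict[str, int] = field(default_factory=dict)
    region_ec50: dict[str, float] = field(default_factory=dict)

    def region_mask(self, region: str | int) -> np.ndarray:
        label = self.region_labels[region] if isinstance(region, str) else int(region)
        return self.label_image == label


@dataclass
class OccupancySeries:
    """V aligned occupancy volumes (axis 0) with their plasma concentrations."""

    data: np.ndarray  # (V, nx, ny, nz); NaN outside brain_mask
    concentrations: np.ndarray  # (V,), ng/mL, strictly increasing
    brain_mask: np.ndarray  # (nx, ny, nz) bool
    stage: str  # ideal | noisy | smoothed | external
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (V volumes x 3D grid)")
        if self.data.shape[0] != self.concentrations.shape[0]:
            raise ValueError("number of volumes must match number of concentrations")
        if self.data.shape[1:] != self.brain_mask.shape:
            raise ValueError("volume grid must match brain_mask grid")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if not np.all(np.isfinite(self.data[:, self.brain_mask])):
            raise ValueError("occupancy values inside the mask must be finite")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    def masked_curves(self) -> np.ndarray:
        """In-mask occupancy curves as an (n_voxels, V) matrix."""
        return self.data[:, self.brain_mask].T


def build_phantom(spec: PhantomSpec) -> GroundTruth:
    """Construct the ground-truth EC50 / Occ_max / label volumes.

    Hot spots carry exactly their region's true EC50; background voxels get
    values in ``background_ec50_range`` (per-voxel uniform draw by default,
    or the mid-range constant when ``background_mode == 'constant'``).
    Overlapping hot spots, or a hot spot leaking outside the brain, raise
    ``ValueError``.
    """
    shape = spec.grid_shape
    brain = spec.brain_region.mask(shape)
    if not brain.any():
        raise ValueError("brain region contains no voxels")

    label = np.zeros(shape, dtype=np.int32)
    label[brain] = 1
    ec50 = np.full(shape, np.nan)
    lo, hi = spec.background_ec50_range
    if spec.background_mode == "uniform":
        rng = np.random.default_rng(stage_seed(spec.seed, "phantom-background"))
        ec50[brain] = rng.uniform(lo, hi, size=int(brain.sum()))
    else:
        ec50[brain] = 0.5 * (lo + hi)

    region_labels: dict[str, int] = {}
    region_ec50: dict[str, float] = {}
    claimed = np.zeros(shape, dtype=bool)
    next_label = 2
    for name, geom, ec50_true in spec.hotspot_regions:
        if ec50_true <= 0:
            raise ValueError(f"hot spot {name!r} needs a positive EC50")
        m = geom.mask(shape)
        if (m & ~brain).any():
            raise ValueError(f"hot spot {name!r} extends outside the brain region")
        if (m & claimed).any():
            raise ValueError(f"hot spot {name!r} overlaps another hot spot")
        claimed |= m
        if name not in region_labels:
            region_labels[name] = next_label
            region_ec50[name] = float(ec50_true)
            next_label += 1
        elif region_ec50[name] != ec50_true:
            raise ValueError(f"region {name!r} given two different EC50 truths")
        label[m] = region_labels[name]
        ec50[m] = ec50_true

    occmax = np.full(shape, np.nan)
    occmax[brain] = spec.occ_max_true
    return GroundTruth(
        ec50_image=ec50,
        occmax_image=occmax,
        label_image=label,
        brain_mask=brain,
        region_labels=region_labels,
        region_ec50=region_ec50,
    )


def ideal_occupancy(truth: GroundTruth, concentrations: np.ndarray) -> OccupancySeries:
    """Noise-free occupancy series: Occ = Occ_max * C / (C + EC50) per voxel."""
    conc = np.asarray(concentrations, dtype=float)
    if conc.ndim != 1 or np.any(conc <= 0):
        raise ValueError("concentrations must be a 1D positive vector")
    mask = truth.brain_mask
    data = np.full((conc.size,) + mask.shape, np.nan)
    ec50 = truth.ec50_image[mask]
    occmax = truth.occmax_image[mask]
    for v, c in enumerate(conc):
        data[v][mask] = occmax * c / (c + ec50)
    return OccupancySeries(data, conc, mask, stage="ideal")


def apply_noise(
    series: OccupancySeries, slope: float, intercept: float, seed: int
) -> OccupancySeries:
    """Add occupancy-dependent Gaussian noise, SD = slope*Occ + intercept.

    Noise is drawn independently per voxel and per concentration; values are
    deliberately not clipped to [0, 1]. Reproducible for a given seed.
    """
    if series.stage != "ideal":
        raise ValueError("noise is applied to the ideal series")
    if slope == 0.0 and intercept == 0.0:
        return replace(series, data=series.data.copy(), stage="noisy")
    inmask = series.data[:, series.brain_mask]
    sd = slope * inmask + intercept
    if np.any(sd <= 0):
        raise ValueError("noise SD must be positive over the occupancy range")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(size=series.data.shape)
    data = series.data.copy()
    data[:, series.brain_mask] = inmask + sd * z[:, series.brain_mask]
    return replace(series, data=data, stage="noisy")


def gaussian_kernel_3d(sigma: float, size: int) -> np.ndarray:
    """Normalized truncated Gaussian kernel of odd edge length ``size``."""
    if size % 2 == 0 or size < 1:
        raise ValueError("kernel size must be a positive odd integer")
    r = size // 2
    d = np.arange(-r, r + 1, dtype=float)
    if sigma == 0:
        w1 = (d == 0).astype(float)
    else:
        w1 = np.exp(-0.5 * (d / sigma) ** 2)
    k = w1[:, None, None] * w1[None, :, None] * w1[None, None, :]
    return k / k.sum()


def smooth_series(
    series: OccupancySeries, sigma_voxels: float, kernel: int = 3
) -> OccupancySeries:
    """Smooth each volume with a fixed-size normalized Gaussian kernel.

    The whole (zero-filled outside the mask) volume is convolved and the mask
    re-applied; there is no boundary renormalization.
    """
    if sigma_voxels < 0:
        raise ValueError("sigma_voxels must be nonnegative")
    k = gaussian_kernel_3d(sigma_voxels, kernel)
    data = series.data.copy()
    mask = series.brain_mask
    for v in range(series.n_volumes):
        vol = np.where(mask, series.data[v], 0.0)
        sm = ndimage.convolve(vol, k, mode="constant", cval=0.0)
        data[v] = np.where(mask, sm, np.nan)
    return replace(series, data=data, stage="smoothed")


def simulate_study(
    spec: PhantomSpec, return_stages: bool = False
) -> tuple[GroundTruth, OccupancySeries] | tuple[GroundTruth, dict[str, OccupancySeries]]:
    """Phantom -> ideal -> noisy -> smoothed occupancy series, fully seeded.

    With ``return_stages=True`` the intermediate series are returned as a
    dict keyed by stage name. Noise is skipped when slope and intercept are
    both zero; smoothing is skipped when sigma_gauss_voxels is zero.
    """
    truth = build_phantom(spec)
    stages: dict[str, OccupancySeries] = {}
    series = ideal_occupancy(truth, spec.concentrations)
    stages["ideal"] = series
    if not (spec.noise_slope == 0.0 and spec.noise_intercept == 0.0):
        series = apply_noise(
            series,
            spec.noise_slope,
            spec.noise_intercept,
            stage_seed(spec.seed, "noise"),
        )
        stages["noisy"] = series
    if spec.sigma_gauss_voxels > 0:
        series = smooth_series(series, spec.sigma_gauss_voxels, spec.smooth_kernel)
        stages["smoothed"] = series
    if return_stages:
        return truth, stages
    return truth, series
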