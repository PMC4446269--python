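"""Seeded synthetic light-sheet brain volumes with planted ground truth.

This module emulates the raw material of an ultramicroscopy plaque study:
bright, quasi-spherical beta-amyloid plaques on a dark parenchyma background,
imaged by a Gaussian light sheet whose axial thickness grows away from the
beam waist (limited Rayleigh range), with exponential intensity loss over
imaging depth, tubular blood-vessel artifacts from incomplete perfusion,
fine stripe artifacts along the illumination axis, and 12-bit CCD noise.

Axis convention (configurable in downstream analysis, fixed here):
``z`` = optical-section/stack axis (array axis 0), ``y`` = depth-from-surface
axis used for attenuation (axis 1), ``x`` = illumination axis along which the
sheet diverges (axis 2).  All physical positions are micrometres in
``(z, y, x)`` order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .errors import ConfigurationError, PackingError
from .quantify import SampleCube

__all__ = [
    "NoiseConfig",
    "SimulationConfig",
    "SizeDistributionSpec",
    "ADULT_SIZE_DISTRIBUTION",
    "YOUNG_SIZE_DISTRIBUTION",
    "Vessel",
    "Stripe",
    "GroundTruth",
    "GroupConfig",
    "CohortConfig",
    "AnimalScene",
    "fwhm_to_sigma",
    "sample_diameters",
    "place_plaques",
    "rasterize",
    "add_vessels",
    "add_stripes",
    "apply_lightsheet_blur",
    "apply_attenuation",
    "add_noise_and_quantize",
    "generate_cohort",
]


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian full width at half maximum to its sigma."""
    return fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseConfig:
    """Camera noise model: optional Poisson shot noise plus additive
    Gaussian read noise (camera counts)."""

    gaussian_sigma: float = 20.0
    poisson: bool = False

    def __post_init__(self):
        if self.gaussian_sigma < 0:
            raise ConfigurationError("gaussian_sigma must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the image-formation model.

    ``axial_fwhm_um`` is the sheet thickness (FWHM of the axial PSF) at the
    beam waist; ``sheet_waist_halfwidth_w0_um`` only controls how fast that
    thickness grows off-waist through the Rayleigh range
    ``x_R = pi * w0**2 / wavelength``.
    """

    grid_shape: tuple = (64, 64, 64)        # (z, y, x) voxels
    voxel_size_um: tuple = (2.0, 2.0, 2.0)  # per axis (z, y, x)
    bit_depth: int = 12
    background_level: float = 100.0
    plaque_amplitude: float = 3000.0
    lateral_fwhm_um: float = 2.0
    axial_fwhm_um: float = 5.0
    sheet_waist_halfwidth_w0_um: float = 2.5
    wavelength_um: float = 0.405
    field_center_x_um: Optional[float] = None  # None -> grid centre
    attenuation_mu_per_mm: float = 0.0
    attenuation_axis: int = 1
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    rng_seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise ConfigurationError("grid_shape must be three positive integers")
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ConfigurationError("voxel sizes must be positive")
        if self.bit_depth not in (8, 12, 16):
            raise ConfigurationError("bit_depth must be one of 8, 12, 16")
        top = 2 ** self.bit_depth - 1
        if not (0 <= self.background_level < self.plaque_amplitude <= top):
            raise ConfigurationError(
                "require 0 <= background_level < plaque_amplitude <= "
                f"2^bit_depth - 1 = {top}"
            )
        if self.lateral_fwhm_um < 0 or self.axial_fwhm_um < 0:
            raise ConfigurationError("PSF widths must be >= 0")
        if self.attenuation_mu_per_mm < 0:
            raise ConfigurationError("attenuation_mu_per_mm must be >= 0")
        if self.attenuation_axis not in (0, 1, 2):
            raise ConfigurationError("attenuation_axis must be 0, 1 or 2")

    @property
    def intensity_max(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def extent_um(self) -> np.ndarray:
        """Physical (z, y, x) extent of the grid in micrometres."""
        return np.asarray(self.grid_shape, float) * np.asarray(self.voxel_size_um, float)

    @property
    def rayleigh_range_um(self) -> float:
        w0 = self.sheet_waist_halfwidth_w0_um
        return math.pi * w0 * w0 / self.wavelength_um


@dataclass(frozen=True)
class SizeDistributionSpec:
    """Distribution of true plaque equivalent diameters (um).

    ``empirical_bins`` draws a bin by probability and then uniformly within
    it; ``truncated_lognormal`` rejects lognormal draws outside
    ``[d_min, d_max]``.
    """

    mode: str = "empirical_bins"
    bin_edges_um: tuple = ()
    probabilities: tuple = ()
    log_mean: float = 0.0
    log_sd: float = 1.0
    d_min_um: float = 0.0
    d_max_um: float = math.inf

    def __post_init__(self):
        if self.mode not in ("empirical_bins", "truncated_lognormal"):
            raise ConfigurationError(f"unknown size-distribution mode {self.mode!r}")
        if self.mode == "empirical_bins":
            edges = np.asarray(self.bin_edges_um, float)
            probs = np.asarray(self.probabilities, float)
            if edges.size < 2 or probs.size != edges.size - 1:
                raise ConfigurationError("need k+1 edges for k bin probabilities")
            if np.any(np.diff(edges) <= 0):
                raise ConfigurationError("bin edges must be strictly increasing")
            if edges[0] < 0:
                raise ConfigurationError("diameters must be non-negative")
            if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
                raise ConfigurationError("probabilities must be >= 0 and sum to 1")
        else:
            if self.log_sd <= 0:
                raise ConfigurationError("log_sd must be > 0")
            if self.d_min_um < 0 or self.d_max_um <= self.d_min_um:
                raise ConfigurationError("require 0 <= d_min < d_max")

    @classmethod
    def empirical(cls, edges_um: Sequence[float], probabilities: Sequence[float]):
        probs = np.asarray(probabilities, float)
        probs = probs / probs.sum()
        return cls(mode="empirical_bins", bin_edges_um=tuple(edges_um),
                   probabilities=tuple(probs))

    @classmethod
    def truncated_lognormal(cls, log_mean: float, log_sd: float,
                            d_min_um: float, d_max_um: float):
        return cls(mode="truncated_lognormal", log_mean=log_mean, log_sd=log_sd,
                   d_min_um=d_min_um, d_max_um=d_max_um)

    def moment(self, k: int) -> float:
        """E[d^k] of the true-diameter distribution (analytic for bins)."""
        if self.mode == "empirical_bins":
            edges = np.asarray(self.bin_edges_um, float)
            probs = np.asarray(self.probabilities, float)
            lo, hi = edges[:-1], edges[1:]
            return float(np.sum(probs * (hi ** (k + 1) - lo ** (k + 1))
                                / ((k + 1) * (hi - lo))))
        mu, sd = self.log_mean, self.log_sd

        def dens(d):
            return math.exp(-0.5 * ((math.log(d) - mu) / sd) ** 2) / d

        lo = max(self.d_min_um, 1e-12)
        hi = self.d_max_um if math.isfinite(self.d_max_um) else math.exp(mu + 10 * sd)
        norm, _ = integrate.quad(dens, lo, hi)
        num, _ = integrate.quad(lambda d: d ** k * dens(d), lo, hi)
        return num / norm


#: Adult-group (7-8.5 months) empirical equivalent-diameter distribution:
#: bins 8-10, 10-20, 20-30, 30-40 um with relative frequencies
#: 11.7 / 38.7 / 27.7 / 21.9 percent.
ADULT_SIZE_DISTRIBUTION = SizeDistributionSpec.empirical(
    (8.0, 10.0, 20.0, 30.0, 40.0), (0.117, 0.387, 0.277, 0.219))

#: Young-group (2.5 months) default: same support, mass shifted toward the
#: 20-30 um class, which is relatively more frequent in young animals.
#: A package default (no young-group table is published), stated in config.
YOUNG_SIZE_DISTRIBUTION = SizeDistributionSpec.empirical(
    (8.0, 10.0, 20.0, 30.0, 40.0), (0.12, 0.40, 0.33, 0.15))


# --------------------------------------------------------------------------
# ground truth containers
# --------------------------------------------------------------------------

@dataclass
class Vessel:
    """A planted blood-vessel artifact: polyline (n,3) um + radius."""
    polyline_um: np.ndarray
    radius_um: float
    voxels: np.ndarray  # (m, 3) voxel indices covered

@dataclass
class Stripe:
    """A planted stripe artifact extended along the illumination (x) axis."""
    z_index: int
    y_index: int
    thickness_voxels: tuple  # (z, y)
    voxels: np.ndarray

@dataclass
class GroundTruth:
    """Exact specification of everything planted in one volume."""
    plaques: pd.DataFrame  # columns: animal, group, x_um, y_um, z_um, diameter_um, object_type, cube_id
    vessels: list = field(default_factory=list)
    stripes: list = field(default_factory=list)
    rng_seed: Optional[int] = None

    @staticmethod
    def empty_plaque_frame() -> pd.DataFrame:
        return pd.DataFrame({
            "animal": pd.Series(dtype=str),
            "group": pd.Series(dtype=str),
            "x_um": pd.Series(dtype=float),
            "y_um": pd.Series(dtype=float),
            "z_um": pd.Series(dtype=float),
            "diameter_um": pd.Series(dtype=float),
            "object_type": pd.Series(dtype=str),
            "cube_id": pd.Series(dtype="Int64"),
        })


# --------------------------------------------------------------------------
# sampling and placement
# --------------------------------------------------------------------------

def sample_diameters(dist: SizeDistributionSpec, n: int, seed) -> np.ndarray:
    """Draw ``n`` true equivalent diameters (um) from a size distribution."""
    if n < 0:
        raise ConfigurationError("n must be >= 0")
    rng = _rng(seed)
    if n == 0:
        return np.empty(0, float)
    if dist.mode == "empirical_bins":
        edges = np.asarray(dist.bin_edges_um, float)
        probs = np.asarray(dist.probabilities, float)
        idx = rng.choice(probs.size, size=n, p=probs)
        return rng.uniform(edges[idx], edges[idx + 1])
    out = np.empty(0, float)
    while out.size < n:
        draw = np.exp(rng.normal(dist.log_mean, dist.log_sd, size=2 * (n - out.size) + 16))
        keep = draw[(draw >= dist.d_min_um) & (draw <= dist.d_max_um)]
        out = np.concatenate([out, keep])
    return out[:n]


def _place_nonoverlapping(lo: np.ndarray, hi: np.ndarray, diameters: np.ndarray,
                          min_separation_um: float, rng: np.random.Generator,
                          accept=None, max_total_tries: Optional[int] = None
                          ) -> np.ndarray:
    """Random sequential placement of sphere centres in the box [lo, hi)
    per sphere (``lo``/``hi`` may be (n,3), already shrunk by each radius).

    Spheres are placed largest-first; the returned centres match the input
    diameter order.  ``accept(c)`` may veto a candidate centre.
    """
    n = diameters.size
    centers = np.full((n, 3), np.nan)
    if n == 0:
        return centers
    order = np.argsort(-diameters, kind="stable")
    radii = diameters / 2.0
    placed = np.empty((n, 3))
    placed_r = np.empty(n)
    k = 0
    budget = max_total_tries if max_total_tries is not None else max(20_000, 400 * n)
    tries = 0
    for j in order:
        r = radii[j]
        l, h = lo[j], hi[j]
        if np.any(h <= l):
            raise PackingError(
                f"region too small for a sphere of diameter {diameters[j]:.3g} um "
                f"(placed {k} of {n})", achieved=k, requested=n)
        while True:
            tries += 1
            if tries > budget:
                raise PackingError(
                    f"sphere packing failed after {tries - 1} tries: "
                    f"placed {k} of {n} spheres", achieved=k, requested=n)
            c = rng.uniform(l, h)
            if accept is not None and not accept(c, r):
                continue
            if k:
                d2 = np.sum((placed[:k] - c) ** 2, axis=1)
                lim = (placed_r[:k] + r + min_separation_um) ** 2
                if np.any(d2 <= lim):
                    continue
            placed[k] = c
            placed_r[k] = r
            centers[j] = c
            k += 1
            break
    return centers


def place_plaques(region_mask: np.ndarray, diameters, min_separation_um: float,
                  seed, voxel_size_um=(2.0, 2.0, 2.0),
                  max_total_tries: Optional[int] = None) -> np.ndarray:
    """Place non-overlapping sphere centres inside a voxel mask.

    Centres are uniform over the mask volume (a random mask voxel plus a
    uniform jitter within it); every pair satisfies
    ``distance > r_i + r_j + min_separation_um``.  Raises
    :class:`PackingError` (naming the achieved count) if the retry budget is
    exhausted.
    """
    rng = _rng(seed)
    diameters = np.asarray(diameters, float)
    mask = np.asarray(region_mask, bool)
    n = diameters.size
    if n == 0:
        return np.empty((0, 3))
    vox = np.argwhere(mask)
    if vox.size == 0:
        raise PackingError("region mask is empty", achieved=0, requested=n)
    v = np.asarray(voxel_size_um, float)

    def accept(c, r):
        idx = np.floor(c / v).astype(int)
        return bool(mask[tuple(idx)])

    # candidate box spans the mask bounding box; accept() enforces membership
    lo_box = vox.min(axis=0) * v
    hi_box = (vox.max(axis=0) + 1) * v
    lo = np.broadcast_to(lo_box, (n, 3))
    hi = np.broadcast_to(np.nextafter(hi_box, -np.inf), (n, 3))
    return _place_nonoverlapping(lo, hi, diameters, min_separation_um, rng,
                                 accept=accept, max_total_tries=max_total_tries)


# --------------------------------------------------------------------------
# rasterization and image formation
# --------------------------------------------------------------------------

def rasterize(centers, diameters, config: SimulationConfig,
              supersample: int = 1, out: Optional[np.ndarray] = None) -> np.ndarray:
    """Paint spheres into a float intensity grid.

    Default membership is the voxel-centre test: a voxel is set to
    ``plaque_amplitude`` when its centre lies inside any sphere, otherwise it
    keeps ``background_level``.  With ``supersample=s > 1`` each voxel is
    subdivided s^3 times and gets a partial-volume intensity
    ``background + amplitude * fill_fraction``.
    """
    centers = np.asarray(centers, float).reshape(-1, 3)
    diameters = np.asarray(diameters, float).reshape(-1)
    if centers.shape[0] != diameters.size:
        raise ConfigurationError("centers and diameters must have equal length")
    shape = tuple(int(s) for s in config.grid_shape)
    v = np.asarray(config.voxel_size_um, float)
    if out is None:
        out = np.full(shape, config.background_level, dtype=np.float32)
    ext = config.extent_um
    if centers.size and (np.any(centers < 0) or np.any(centers >= ext)):
        raise ConfigurationError("all centers must lie within the grid bounds")
    s = int(supersample)
    if s < 1:
        raise ConfigurationError("supersample must be >= 1")
    amp = config.plaque_amplitude
    bg = config.background_level
    for c, d in zip(centers, diameters):
        r = d / 2.0
        i0 = np.maximum(np.floor((c - r) / v).astype(int) - 1, 0)
        i1 = np.minimum(np.ceil((c + r) / v).astype(int) + 1, shape)
        if np.any(i1 <= i0):
            continue
        axes = []
        for a in range(3):
            idx = np.arange(i0[a], i1[a])
            if s == 1:
                coords = (idx + 0.5) * v[a]
            else:
                sub = (np.arange(s) + 0.5) / s
                coords = ((idx[:, None] + sub[None, :]) * v[a])
            axes.append((coords - c[a]) ** 2)
        if s == 1:
            inside = (axes[0][:, None, None] + axes[1][None, :, None]
                      + axes[2][None, None, :]) <= r * r
            frac = inside.astype(np.float32)
        else:
            inside = (axes[0][:, :, None, None, None, None]
                      + axes[1][None, None, :, :, None, None]
                      + axes[2][None, None, None, None, :, :]) <= r * r
            frac = inside.mean(axis=(1, 3, 5)).astype(np.float32)
        region = out[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
        np.maximum(region, bg + amp * frac, out=region)
    return out


def add_vessels(grid: np.ndarray, truth: GroundTruth, n_vessels: int,
                radius_um_range=(3.0, 8.0), seed=0,
                config: Optional[SimulationConfig] = None,
                segment_length_um_range=(60.0, 150.0)) -> np.ndarray:
    """Plant tubular vessel artifacts (random-walk polylines dilated to a
    radius) at plaque-like intensity, recording them in the ground truth."""
    if n_vessels == 0:
        return grid
    rng = _rng(seed)
    v = np.asarray(config.voxel_size_um, float)
    ext = config.extent_um
    stamp = np.zeros(grid.shape, bool)
    for _ in range(int(n_vessels)):
        radius = rng.uniform(*radius_um_range)
        n_seg = int(rng.integers(3, 7))
        start = rng.uniform(radius, ext - radius)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pts = [start]
        for _s in range(n_seg):
            length = rng.uniform(*segment_length_um_range)
            direction = direction + rng.normal(scale=0.35, size=3)
            direction /= np.linalg.norm(direction)
            nxt = np.clip(pts[-1] + direction * length, radius, ext - radius)
            pts.append(nxt)
        poly = np.asarray(pts)
        one = np.zeros(grid.shape, bool)
        step = float(v.min()) / 2.0
        half = np.array([int(math.ceil(radius / vv)) + 1 for vv in v])
        off = np.argwhere(np.ones(2 * half + 1, bool)) - half
        ball = off[np.sum((off * v) ** 2, axis=1) <= radius * radius]
        for a, b in zip(poly[:-1], poly[1:]):
            seg = b - a
            length = np.linalg.norm(seg)
            npts = max(int(length / step) + 1, 2)
            for t in np.linspace(0.0, 1.0, npts):
                p = a + t * seg
                ctr = np.floor(p / v).astype(int)
                cells = ctr + ball
                ok = np.all((cells >= 0) & (cells < np.array(grid.shape)), axis=1)
                cells = cells[ok]
                one[cells[:, 0], cells[:, 1], cells[:, 2]] = True
        stamp |= one
        truth.vessels.append(Vessel(polyline_um=poly, radius_um=radius,
                                    voxels=np.argwhere(one)))
    np.maximum(grid, np.where(stamp, config.plaque_amplitude, grid.dtype.type(0)),
               out=grid)
    return grid


def add_stripes(grid: np.ndarray, truth: GroundTruth, n_stripes: int, seed=0,
                config: Optional[SimulationConfig] = None,
                amplitude_factor: float = 0.8) -> np.ndarray:
    """Plant thin elevated-intensity ridges running the full illumination (x)
    extent, 1-2 voxels thick in y and z."""
    if n_stripes == 0:
        return grid
    rng = _rng(seed)
    nz, ny, nx = grid.shape
    level = config.background_level + amplitude_factor * config.plaque_amplitude
    for _ in range(int(n_stripes)):
        tz, ty = int(rng.integers(1, 3)), int(rng.integers(1, 3))
        z0 = int(rng.integers(0, nz - tz + 1))
        y0 = int(rng.integers(0, ny - ty + 1))
        region = grid[z0:z0 + tz, y0:y0 + ty, :]
        np.maximum(region, region.dtype.type(level), out=region)
        vox = np.argwhere(np.ones((tz, ty, nx), bool))
        vox[:, 0] += z0
        vox[:, 1] += y0
        truth.stripes.append(Stripe(z_index=z0, y_index=y0,
                                    thickness_voxels=(tz, ty), voxels=vox))
    return grid


def lightsheet_sigma_z_um(x_um: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Axial PSF sigma as a function of position along the illumination axis:
    sigma_z(x) = sigma_z0 * sqrt(1 + ((x - x0)/x_R)^2)."""
    if config.sheet_waist_halfwidth_w0_um <= 0 or config.wavelength_um <= 0:
        raise ConfigurationError("waist half-width and wavelength must be > 0")
    sig0 = fwhm_to_sigma(config.axial_fwhm_um)
    x0 = config.field_center_x_um
    if x0 is None:
        x0 = config.extent_um[2] / 2.0
    xr = config.rayleigh_range_um
    return sig0 * np.sqrt(1.0 + ((np.asarray(x_um, float) - x0) / xr) ** 2)


def apply_lightsheet_blur(grid: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Blur with the light-sheet PSF: constant lateral Gaussian blur, plus an
    axial (z) blur whose sigma grows with distance from the beam waist along
    the illumination axis (limited Rayleigh range)."""
    v = np.asarray(config.voxel_size_um, float)
    out = np.asarray(grid, np.float32).copy()
    sig0 = fwhm_to_sigma(config.axial_fwhm_um)
    if sig0 > 0:
        x_um = (np.arange(grid.shape[2]) + 0.5) * v[2]
        sig_z = lightsheet_sigma_z_um(x_um, config) / v[0]
        if float(np.ptp(sig_z)) < 1e-3 * float(sig_z.min()):
            out = gaussian_filter1d(out, float(sig_z[0]), axis=0, mode="nearest")
        else:
            for i in range(grid.shape[2]):
                out[:, :, i] = gaussian_filter1d(out[:, :, i], float(sig_z[i]),
                                                 axis=0, mode="nearest")
    sig_lat = fwhm_to_sigma(config.lateral_fwhm_um)
    if sig_lat > 0:
        out = gaussian_filter(out, sigma=(0.0, sig_lat / v[1], sig_lat / v[2]),
                              mode="nearest")
    return out


def apply_attenuation(grid: np.ndarray, mu_per_mm: float,
                      voxel_size_um=(2.0, 2.0, 2.0), depth_axis: int = 1
                      ) -> np.ndarray:
    """Multiply intensity by exp(-mu * depth) with depth measured from the
    volume surface (index 0) along ``depth_axis``, at voxel centres."""
    if mu_per_mm < 0:
        raise ConfigurationError("mu_per_mm must be >= 0")
    out = np.asarray(grid, np.float32).copy()
    if mu_per_mm == 0:
        return out
    v = np.asarray(voxel_size_um, float)
    depth_mm = (np.arange(grid.shape[depth_axis]) + 0.5) * v[depth_axis] / 1000.0
    factor = np.exp(-mu_per_mm * depth_mm).astype(np.float32)
    shape = [1, 1, 1]
    shape[depth_axis] = -1
    return out * factor.reshape(shape)


def add_noise_and_quantize(grid: np.ndarray, config: SimulationConfig, seed
                           ) -> np.ndarray:
    """Apply optional Poisson and Gaussian noise, round, and clip to the
    camera's integer range.  Returns uint8 for 8-bit, uint16 otherwise."""
    rng = _rng(seed)
    g = np.asarray(grid, np.float64)
    if config.noise.poisson:
        g = rng.poisson(np.clip(g, 0, None)).astype(np.float64)
    if config.noise.gaussian_sigma > 0:
        g = g + rng.normal(0.0, config.noise.gaussian_sigma, size=g.shape)
    g = np.clip(np.rint(g), 0, config.intensity_max)
    dtype = np.uint8 if config.bit_depth == 8 else np.uint16
    return g.astype(dtype)


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupConfig:
    """One age group: either an exact planted total over all sample cubes
    (``exact_total``) or a plaque density in the cortex mask
    (``density_per_mm3``)."""

    name: str
    n_animals: int = 5
    size_distribution: SizeDistributionSpec = ADULT_SIZE_DISTRIBUTION
    exact_total: Optional[int] = None
    density_per_mm3: Optional[float] = None

    def __post_init__(self):
        if self.n_animals < 1:
            raise ConfigurationError("n_animals must be >= 1")
        if (self.exact_total is None) == (self.density_per_mm3 is None):
            raise ConfigurationError(
                "give exactly one of exact_total or density_per_mm3")
        if self.exact_total is not None and self.exact_total < 0:
            raise ConfigurationError("exact_total must be >= 0")


#: Default density-mode plaque densities (plaques per mm^3 of cortex mask).
#: Package defaults on the scale implied by group totals over cubes of a few
#: hundredths of a mm^3 — config values, not published measurements.
DEFAULT_DENSITIES = {"young": 2500.0, "adult": 10000.0}


@dataclass(frozen=True)
class CohortConfig:
    """Study-level generator configuration.

    In exact-totals mode plaques are planted only inside pre-declared sample
    cubes (laid out on a grid with gaps), so the summed pipeline count is
    directly comparable to the planted total.  ``effective_fill`` is the
    packing fraction of separation-inflated spheres used to size the cubes.
    """

    groups: tuple
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    cubes_per_animal: int = 6
    effective_fill: float = 0.2
    min_separation_um: float = 6.0
    cube_gap_voxels: int = 3
    border_voxels: int = 3
    supersample: int = 2
    apply_blur: bool = True
    n_vessels_per_animal: int = 0
    n_stripes_per_animal: int = 0
    vessel_radius_um_range: tuple = (3.0, 8.0)

    def __post_init__(self):
        if not self.groups:
            raise ConfigurationError("at least one group required")
        if not (0 < self.effective_fill < 0.35):
            raise ConfigurationError("effective_fill must be in (0, 0.35)")


@dataclass
class AnimalScene:
    """One simulated animal: imaged volume, ground truth, cubes, cortex."""
    animal_id: str
    group: str
    volume: np.ndarray            # quantized (z, y, x) integer grid
    truth: GroundTruth
    cubes: Optional[list]         # SampleCube list (exact-totals mode)
    cortex_mask: np.ndarray
    config: SimulationConfig


def _split_total(total: int, k: int) -> list:
    base, rem = divmod(int(total), k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def _cube_tiling(n: int) -> tuple:
    ny = max(int(math.sqrt(n)), 1)
    while n % ny:
        ny -= 1
    return 1, ny, n // ny


def _support_max_um(dist: SizeDistributionSpec) -> float:
    if dist.mode == "empirical_bins":
        return float(dist.bin_edges_um[-1])
    cap = math.exp(dist.log_mean + 3.0 * dist.log_sd)
    return min(dist.d_max_um, cap)


def _exact_cube_edge_voxels(max_count: int, dist: SizeDistributionSpec,
                            cfg: CohortConfig, voxel_um: float) -> int:
    """Cube edge sized so separation-inflated spheres fill the interior at
    ``effective_fill``, plus the containment margin for the largest sphere."""
    s = cfg.min_separation_um
    e3 = dist.moment(3) + 3 * s * dist.moment(2) + 3 * s * s * dist.moment(1) + s ** 3
    eff_vol = math.pi / 6.0 * e3
    interior_um = (max(max_count, 1) * eff_vol / cfg.effective_fill) ** (1.0 / 3.0)
    edge_um = interior_um + _support_max_um(dist) + 2.0 * voxel_um
    return max(int(math.ceil(edge_um / voxel_um)), 4)


def _ellipsoid_mask(shape, semi_frac=0.42) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, float)
    for g, s in zip(grids, shape):
        c = (s - 1) / 2.0
        acc = acc + ((g - c) / (semi_frac * s)) ** 2
    return acc <= 1.0


def _image_scene(scene: np.ndarray, config: SimulationConfig,
                 apply_blur: bool, rng) -> np.ndarray:
    if apply_blur:
        scene = apply_lightsheet_blur(scene, config)
    if config.attenuation_mu_per_mm > 0:
        scene = apply_attenuation(scene, config.attenuation_mu_per_mm,
                                  config.voxel_size_um, config.attenuation_axis)
    return add_noise_and_quantize(scene, config, rng)


def generate_cohort(cohort: CohortConfig, seed) -> list:
    """Generate every animal of every group with exact ground truth.

    Returns a list of :class:`AnimalScene`.  Identical config + seed gives
    bit-identical volumes.  In exact-totals mode the planted plaque count
    summed over each group's declared sample cubes equals the requested
    group total exactly.
    """
    root = np.random.SeedSequence(seed)
    group_seeds = root.spawn(len(cohort.groups))
    scenes = []
    for g_idx, group in enumerate(cohort.groups):
        animal_seeds = group_seeds[g_idx].spawn(group.n_animals)
        if group.exact_total is not None:
            per_animal = _split_total(group.exact_total, group.n_animals)
        for a_idx in range(group.n_animals):
            ss = animal_seeds[a_idx]
            place_rng, image_rng, artifact_rng = (np.random.default_rng(s)
                                                  for s in ss.spawn(3))
            animal_id = f"{group.name}_{a_idx + 1:02d}"
            if group.exact_total is not None:
                scene = _generate_exact_animal(
                    cohort, group, animal_id, per_animal[a_idx],
                    place_rng, image_rng)
            else:
                scene = _generate_density_animal(
                    cohort, group, animal_id, place_rng, image_rng, artifact_rng)
            scenes.append(scene)
    return scenes


def _generate_exact_animal(cohort: CohortConfig, group: GroupConfig,
                           animal_id: str, n_plaques: int,
                           place_rng, image_rng) -> AnimalScene:
    sim0 = cohort.sim
    v = np.asarray(sim0.voxel_size_um, float)
    if not (v[0] == v[1] == v[2]):
        raise ConfigurationError("exact-totals mode assumes isotropic voxels")
    counts = _split_total(n_plaques, cohort.cubes_per_animal)
    edge_vox = _exact_cube_edge_voxels(max(counts), group.size_distribution,
                                       cohort, float(v[0]))
    gap, border = cohort.cube_gap_voxels, cohort.border_voxels
    tz, ty, tx = _cube_tiling(cohort.cubes_per_animal)
    shape = (tz * edge_vox + (tz - 1) * gap + 2 * border,
             ty * edge_vox + (ty - 1) * gap + 2 * border,
             tx * edge_vox + (tx - 1) * gap + 2 * border)
    config = replace(sim0, grid_shape=shape)
    edge_um = edge_vox * float(v[0])

    cubes = []
    rows = []
    all_centers = []
    all_diams = []
    cube_idx = 0
    for iz in range(tz):
        for iy in range(ty):
            for ix in range(tx):
                origin_vox = np.array([border + iz * (edge_vox + gap),
                                       border + iy * (edge_vox + gap),
                                       border + ix * (edge_vox + gap)])
                origin_um = origin_vox * v
                cube = SampleCube(id=cube_idx, origin_um=tuple(origin_um),
                                  edge_um=edge_um,
                                  hemisphere="right" if ix < (tx + 1) // 2 else "left")
                cubes.append(cube)
                n_c = counts[cube_idx]
                diams = sample_diameters(group.size_distribution, n_c, place_rng)
                margin = diams[:, None] / 2.0 + float(v[0])  # sphere inside cube
                lo = origin_um[None, :] + margin
                hi = origin_um[None, :] + edge_um - margin
                centers = _place_nonoverlapping(lo, hi, diams,
                                                cohort.min_separation_um, place_rng)
                all_centers.append(centers)
                all_diams.append(diams)
                for c, d in zip(centers, diams):
                    rows.append((animal_id, group.name, c[2], c[1], c[0], d,
                                 "plaque", cube_idx))
                cube_idx += 1

    centers = np.concatenate(all_centers) if all_centers else np.empty((0, 3))
    diams = np.concatenate(all_diams) if all_diams else np.empty(0)
    scene = rasterize(centers, diams, config, supersample=cohort.supersample)
    volume = _image_scene(scene, config, cohort.apply_blur, image_rng)
    plaques = pd.DataFrame(rows, columns=["animal", "group", "x_um", "y_um",
                                          "z_um", "diameter_um", "object_type",
                                          "cube_id"])
    truth = GroundTruth(plaques=plaques, rng_seed=config.rng_seed)
    cortex = np.ones(shape, bool)
    return AnimalScene(animal_id=animal_id, group=group.name, volume=volume,
                       truth=truth, cubes=cubes, cortex_mask=cortex,
                       config=config)


def _generate_density_animal(cohort: CohortConfig, group: GroupConfig,
                             animal_id: str, place_rng, image_rng,
                             artifact_rng) -> AnimalScene:
    config = cohort.sim
    v = np.asarray(config.voxel_size_um, float)
    cortex = _ellipsoid_mask(config.grid_shape)
    mask_mm3 = cortex.sum() * float(np.prod(v)) * 1e-9
    n = int(place_rng.poisson(group.density_per_mm3 * mask_mm3))
    diams = sample_diameters(group.size_distribution, n, place_rng)
    centers = place_plaques(cortex, diams, cohort.min_separation_um, place_rng,
                            voxel_size_um=config.voxel_size_um)
    scene = rasterize(centers, diams, config, supersample=cohort.supersample)
    rows = [(animal_id, group.name, c[2], c[1], c[0], d, "plaque", np.nan)
            for c, d in zip(centers, diams)]
    plaques = pd.DataFrame(rows, columns=["animal", "group", "x_um", "y_um",
                                          "z_um", "diameter_um", "object_type",
                                          "cube_id"])
    truth = GroundTruth(plaques=plaques, rng_seed=config.rng_seed)
    add_vessels(scene, truth, cohort.n_vessels_per_animal,
                cohort.vessel_radius_um_range, artifact_rng, config)
    add_stripes(scene, truth, cohort.n_stripes_per_animal, artifact_rng, config)
    volume = _image_scene(scene, config, cohort.apply_blur, image_rng)
    return AnimalScene(animal_id=animal_id, group=group.name, volume=volume,
                       truth=truth, cubes=None, cortex_mask=cortex,
                       config=config)
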