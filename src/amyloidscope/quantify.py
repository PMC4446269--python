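"""Cube-based stereological quantification of segmented plaques.

Implements the measurement scheme of the ultramicroscopy study: the cortex
volume is determined from a (low-resolution) segmentation, sample cubes are
fixed to 0.1% of that volume, and within the cubes plaque counts per mm^3,
plaque load (volume percent) and equivalent-sphere diameter histograms are
computed and compared between age groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, DegenerateInputError, PackingError

__all__ = [
    "SampleCube",
    "QuantParams",
    "SizeHistogram",
    "equivalent_diameter",
    "equivalent_volume",
    "segment_cortex",
    "place_sample_cubes",
    "records_in_cube",
    "cube_count_density",
    "cube_plaque_load",
    "size_histogram",
    "correct_shrinkage",
    "compare_group_fractions",
    "quantify_animal",
]

#: Default histogram bin edges (um): the first bin starts at the 8 um
#: counting floor and matches the published 8-10 row; later bins are the
#: 10 um size groups, with an open-ended bin above 50 um.
DEFAULT_HISTOGRAM_EDGES_UM = (8.0, 10.0, 20.0, 30.0, 40.0, 50.0, math.inf)


@dataclass(frozen=True)
class SampleCube:
    """Axis-aligned sample cube, volume fixed to a fraction of the cortex."""

    id: int
    origin_um: tuple          # (z, y, x)
    edge_um: float
    hemisphere: str = "right"

    def __post_init__(self):
        if self.edge_um <= 0:
            raise ConfigurationError("cube edge must be > 0")

    @property
    def volume_mm3(self) -> float:
        return (self.edge_um ** 3) * 1e-9

    def contains(self, points_um: np.ndarray) -> np.ndarray:
        """Half-open membership test [origin, origin + edge) for (n,3) zyx
        points; a point exactly on an upper face is not counted."""
        p = np.atleast_2d(np.asarray(points_um, float))
        o = np.asarray(self.origin_um, float)
        return np.all((p >= o) & (p < o + self.edge_um), axis=1)


@dataclass(frozen=True)
class QuantParams:
    cubes_per_hemisphere: int = 6
    cube_volume_fraction: float = 0.001
    histogram_edges_um: tuple = DEFAULT_HISTOGRAM_EDGES_UM
    shrinkage_fraction: float = 0.20
    membership: str = "centroid_in_cube"

    def __post_init__(self):
        if not (0 < self.cube_volume_fraction < 1):
            raise ConfigurationError("cube_volume_fraction must be in (0, 1)")
        edges = np.asarray(self.histogram_edges_um, float)
        if edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ConfigurationError("histogram edges must be strictly increasing")
        if not (0 <= self.shrinkage_fraction < 1):
            raise ConfigurationError("shrinkage_fraction must be in [0, 1)")
        if self.membership != "centroid_in_cube":
            raise ConfigurationError("only centroid_in_cube membership is supported")


@dataclass
class SizeHistogram:
    """Binned diameter counts with relative percentages (half-open bins)."""

    edges_um: np.ndarray
    counts: np.ndarray
    relative_percent: np.ndarray
    n_input: int
    empty: bool = False


def equivalent_diameter(volume_um3):
    """Equivalent-sphere diameter d = 2 * (3V / (4 pi))^(1/3) in um."""
    v = np.asarray(volume_um3, float)
    if np.any(v <= 0):
        raise ValueError("volume must be > 0 for an equivalent diameter")
    d = 2.0 * np.cbrt(3.0 * v / (4.0 * math.pi))
    return float(d) if np.isscalar(volume_um3) else d


def equivalent_volume(diameter_um):
    """Inverse of :func:`equivalent_diameter`: V = (pi/6) d^3 in um^3."""
    d = np.asarray(diameter_um, float)
    v = math.pi / 6.0 * d ** 3
    return float(v) if np.isscalar(diameter_um) else v


def segment_cortex(volume_or_mask: np.ndarray, voxel_size_um,
                   mode: str = "mask", closing_iterations: int = 2):
    """Cortex mask and volume (mm^3).

    ``mask`` mode takes a boolean/binary mask as given; ``intensity`` mode
    thresholds a low-resolution intensity volume (Otsu), keeps the largest
    connected component and closes small holes.
    """
    v = np.asarray(voxel_size_um, float)
    if mode == "mask":
        mask = np.asarray(volume_or_mask).astype(bool)
    elif mode == "intensity":
        from skimage.filters import threshold_otsu
        grid = np.asarray(volume_or_mask)
        if grid.max() == grid.min():
            raise DegenerateInputError("constant volume: cannot segment cortex")
        mask = grid >= threshold_otsu(grid)
        labels, n = ndimage.label(mask)
        if n == 0:
            raise DegenerateInputError("no foreground after thresholding")
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
        if closing_iterations:
            mask = ndimage.binary_closing(mask, iterations=closing_iterations)
    else:
        raise ConfigurationError(f"unknown cortex mode {mode!r}")
    count = int(mask.sum())
    if count == 0:
        raise DegenerateInputError("cortex mask is empty")
    return mask, count * float(np.prod(v)) * 1e-9


def place_sample_cubes(cortex_mask: np.ndarray, params: QuantParams, seed,
                       voxel_size_um=(2.0, 2.0, 2.0),
                       max_tries_per_cube: int = 2000) -> list:
    """Seeded placement of non-overlapping sample cubes fully inside the
    cortex mask, each with volume ``cube_volume_fraction`` of the cortex
    volume (edge rounded to whole voxels)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = np.asarray(cortex_mask, bool)
    v = np.asarray(voxel_size_um, float)
    if not (v[0] == v[1] == v[2]):
        raise ConfigurationError("cube placement assumes isotropic voxels")
    vol_um3 = mask.sum() * float(np.prod(v))
    edge_um_target = (params.cube_volume_fraction * vol_um3) ** (1.0 / 3.0)
    edge_vox = max(int(round(edge_um_target / v[0])), 1)
    e = edge_vox
    # integral image -> number of mask voxels in each e^3 window
    ii = np.cumsum(np.cumsum(np.cumsum(mask.astype(np.int64), 0), 1), 2)
    ii = np.pad(ii, ((1, 0), (1, 0), (1, 0)))
    nz, ny, nx = mask.shape
    if nz < e or ny < e or nx < e:
        raise PackingError("cortex mask smaller than one cube edge",
                           achieved=0, requested=params.cubes_per_hemisphere)
    w = (ii[e:, e:, e:] - ii[:-e, e:, e:] - ii[e:, :-e, e:] - ii[e:, e:, :-e]
         + ii[:-e, :-e, e:] + ii[:-e, e:, :-e] + ii[e:, :-e, :-e]
         - ii[:-e, :-e, :-e])
    valid = np.argwhere(w == e ** 3)
    n_req = params.cubes_per_hemisphere
    if valid.shape[0] == 0:
        raise PackingError("no cube-sized region fits inside the cortex mask",
                           achieved=0, requested=n_req)
    cubes = []
    origins = []
    tries = 0
    while len(cubes) < n_req:
        tries += 1
        if tries > max_tries_per_cube * n_req:
            raise PackingError(
                f"placed only {len(cubes)} of {n_req} sample cubes",
                achieved=len(cubes), requested=n_req)
        o = valid[int(rng.integers(valid.shape[0]))]
        if any(np.all(np.abs(o - p) < e) for p in origins):
            continue
        origins.append(o)
        cubes.append(SampleCube(id=len(cubes), origin_um=tuple(o * v),
                                edge_um=e * float(v[0])))
    return cubes


def records_in_cube(records: pd.DataFrame, cube: SampleCube,
                    retained_only: bool = True) -> pd.DataFrame:
    """Rows whose centroid lies in the half-open cube."""
    df = records
    if retained_only and "retained" in df.columns:
        df = df[df["retained"].astype(bool)]
    if df.empty:
        return df
    pts = df[["centroid_z_um", "centroid_y_um", "centroid_x_um"]].to_numpy()
    return df[cube.contains(pts)]


def cube_count_density(records: pd.DataFrame, cube: SampleCube):
    """Retained plaque count in the cube (centroid rule) and count per mm^3."""
    count = int(len(records_in_cube(records, cube)))
    return count, count / cube.volume_mm3


def cube_plaque_load(labels: np.ndarray, retained_ids, cube: SampleCube,
                     voxel_size_um=(2.0, 2.0, 2.0)) -> float:
    """Plaque load (volume percent) of the cube: retained plaque voxels
    inside the cube over cube voxels, by voxel membership (not centroid)."""
    v = np.asarray(voxel_size_um, float)
    o = np.asarray(cube.origin_um, float)
    i0 = np.round(o / v).astype(int)
    e = int(round(cube.edge_um / v[0]))
    i1 = np.minimum(i0 + e, labels.shape)
    sub = labels[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
    ids = np.asarray(list(retained_ids), dtype=labels.dtype)
    if ids.size == 0 or sub.size == 0:
        return 0.0
    inside = np.isin(sub, ids)
    return 100.0 * float(inside.sum()) / float(e ** 3)


def size_histogram(diameters, edges_um=DEFAULT_HISTOGRAM_EDGES_UM) -> SizeHistogram:
    """Bin diameters into half-open bins [e_i, e_{i+1}).

    With no input the counts are zero, the percentages are reported as 0 and
    the histogram is flagged ``empty``.
    """
    edges = np.asarray(edges_um, float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ConfigurationError("histogram edges must be strictly increasing")
    d = np.asarray(diameters, float).ravel()
    k = edges.size - 1
    idx = np.searchsorted(edges, d, side="right") - 1
    ok = (idx >= 0) & (idx < k) & (d >= edges[0])
    counts = np.bincount(idx[ok], minlength=k).astype(np.int64)
    total = counts.sum()
    if total > 0:
        rel = 100.0 * counts / total
        return SizeHistogram(edges, counts, rel, n_input=int(d.size))
    return SizeHistogram(edges, counts, np.zeros(k), n_input=int(d.size), empty=True)


def correct_shrinkage(diameters, s: float = 0.20):
    """Undo the clearing-induced size bias: measured = true * (1 - s), so
    corrected = measured / (1 - s).  Off by default in pipeline outputs."""
    if not (0 <= s < 1):
        raise ValueError("shrinkage fraction s must satisfy 0 <= s < 1")
    d = np.asarray(diameters, float)
    out = d / (1.0 - s)
    return float(out) if np.isscalar(diameters) else out


def compare_group_fractions(histograms_a: Sequence[SizeHistogram],
                            histograms_b: Sequence[SizeHistogram],
                            labels=("young", "adult")) -> pd.DataFrame:
    """Per-bin comparison of animal-level relative plaque fractions.

    Each histogram is one animal; per bin, a two-sided Mann-Whitney rank
    test compares the animal-level fractions between the groups.  With
    fewer than two animals in a group the p-value is reported as NaN.
    """
    from .stats import mann_whitney_u, significance_stars

    if not histograms_a or not histograms_b:
        raise ConfigurationError("both groups need at least one histogram")
    edges = histograms_a[0].edges_um
    for h in list(histograms_a) + list(histograms_b):
        if not np.array_equal(h.edges_um, edges):
            raise ConfigurationError("histograms must share bin edges")
    fa = np.vstack([h.relative_percent for h in histograms_a])
    fb = np.vstack([h.relative_percent for h in histograms_b])
    rows = []
    computable = fa.shape[0] >= 2 and fb.shape[0] >= 2
    for i in range(edges.size - 1):
        mean_a, mean_b = fa[:, i].mean(), fb[:, i].mean()
        diff = mean_b - mean_a
        if computable:
            res = mann_whitney_u(fa[:, i], fb[:, i])
            p, u, stars = res.p_value, res.statistic, res.stars
        else:
            p, u, stars = math.nan, math.nan, "na"
        rows.append({
            "bin_lo_um": edges[i], "bin_hi_um": edges[i + 1],
            f"mean_percent_{labels[0]}": mean_a,
            f"mean_percent_{labels[1]}": mean_b,
            "difference_pp": diff,
            "direction": (f"higher_in_{labels[1]}" if diff > 0
                          else f"higher_in_{labels[0]}" if diff < 0 else "equal"),
            "U": u, "p_value": p, "stars": stars,
        })
    return pd.DataFrame(rows)


def quantify_animal(records: pd.DataFrame, labels: Optional[np.ndarray],
                    cubes: Sequence[SampleCube],
                    voxel_size_um=(2.0, 2.0, 2.0)) -> pd.DataFrame:
    """Per-cube count, density and (if a label map is given) plaque load."""
    retained = (records[records["retained"].astype(bool)]
                if "retained" in records.columns else records)
    rows = []
    for cube in cubes:
        count, density = cube_count_density(retained, cube)
        row = {"cube_id": cube.id, "hemisphere": cube.hemisphere,
               "edge_um": cube.edge_um, "volume_mm3": cube.volume_mm3,
               "count": count, "density_per_mm3": density}
        if labels is not None:
            row["load_percent"] = cube_plaque_load(
                labels, retained["id"].to_numpy(), cube, voxel_size_um)
        rows.append(row)
    return pd.DataFrame(rows)
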