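"""Synthetic primordium, reporter, overview and qPCR data with exact ground truth.

The generator emulates what the imaging pipeline consumes: a membrane-labelled
epithelial cell cluster (the posterior lateral line primordium, pLLP) of
roughly 40–200 cells arranged in an elongated ellipsoid with optional rosettes,
a nuclear channel, reporter images with genotype-dependent intensity, EdU-like
nuclear subsets, 2D neuromast-deposition overviews, and qPCR Ct plates with a
known fold change.  Every output comes with its exact ground truth so each
downstream stage has an oracle.

Geometry is deliberately simple rather than photorealistic: cell centres are
rejection-sampled with a minimum spacing and the tissue ellipsoid is
partitioned by nearest-centre assignment in *physical* (anisotropy-aware)
coordinates, so every per-cell volume is exactly known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .exceptions import InfeasibleGeometryError
from .types import LabelVolume, VoxelStack

# Fraction of the tissue ellipsoid volume budgeted per cell, relative to
# cell_diameter³.  A nearest-centre cell at random packing occupies slightly
# less than the cube of its spacing; 0.95 gives mean cell volumes ≈ 330 µm³
# at the 7 µm default diameter, in the range of epithelial pLLP cells.
_CELL_VOLUME_FACTOR = 0.95

# z semi-axis relative to y semi-axis: the primordium is a flattened,
# elongated epithelial plate, thinner in z than wide in y.
_Z_FLATTENING = 0.8

_MIN_SPACING_FACTOR = 0.8  # minimum centre spacing, × cell_diameter
_CELLS_PER_ROSETTE = 8


@dataclass(frozen=True)
class PrimordiumParams:
    """Geometry and noise parameters of one synthetic primordium.

    The defaults describe the wild-type tissue: ~120 cells in an ellipsoid
    with a 2.5:1 footprint, 7 µm cells, confocal-like anisotropic voxels.
    """

    n_cells: int = 120
    elongation: float = 2.5
    n_rosettes: int = 2
    rosette_radius_um: float = 5.0
    cell_diameter_um: float = 7.0
    membrane_width_um: float = 1.0
    voxel_spacing_um: tuple[float, float, float] = (1.0, 0.4, 0.4)
    noise_sd: float = 0.02
    photon_scale: float = 200.0
    orientation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.elongation < 1:
            raise ValueError("elongation must be >= 1")
        if self.n_rosettes < 0:
            raise ValueError("n_rosettes must be >= 0")
        if self.rosette_radius_um <= 0 or self.cell_diameter_um <= 0:
            raise ValueError("radii/diameters must be positive")
        if not self.membrane_width_um < self.cell_diameter_um:
            raise ValueError("membrane_width_um must be < cell_diameter_um")
        if any(s <= 0 for s in self.voxel_spacing_um):
            raise ValueError(f"non-positive voxel spacing {self.voxel_spacing_um}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.photon_scale > 0:
            raise ValueError("photon_scale must be > 0 (may be inf)")


@dataclass
class GroundTruth:
    """Exact truth accompanying one synthetic stack."""

    label_volume: LabelVolume
    cell_centers_um: np.ndarray        # (n, 3) in (z, y, x) µm, stack coords
    per_cell_volume_um3: np.ndarray    # (n,)
    rosette_centers_um: np.ndarray     # (k, 2) in (y, x) µm, stack coords
    true_count: int
    extras: dict = field(default_factory=dict)


@dataclass(frozen=True)
class GenotypePreset:
    """Simulation parameters of one genotype / treatment arm.

    ``count_multiplier`` scales the wild-type mean cell count of 120;
    ``reporter_multiplier`` scales Tead-reporter intensity;
    ``diving_probability`` is the per-embryo chance of the diving phenotype;
    ``edu_fraction`` the expected EdU-positive (S-phase) cell fraction.
    """

    name: str
    count_multiplier: float = 1.0
    count_cv: float = 0.08
    reporter_multiplier: float = 1.0
    diving_probability: float = 0.0
    edu_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.count_multiplier <= 0 or self.reporter_multiplier <= 0:
            raise ValueError("multipliers must be > 0")
        if self.count_cv < 0:
            raise ValueError("count_cv must be >= 0")
        if not 0 <= self.diving_probability <= 1:
            raise ValueError("diving_probability must be in [0, 1]")
        if not 0 <= self.edu_fraction <= 1:
            raise ValueError("edu_fraction must be in [0, 1]")


WT_MEAN_COUNT = 120

#: Genotype presets with effect sizes anchored to the published cohort effects.
PRESETS: dict[str, GenotypePreset] = {
    p.name: p
    for p in [
        GenotypePreset("wt", 1.0, 0.08, 1.0, diving_probability=0.0129),
        GenotypePreset("yap1", 0.80, 0.08, diving_probability=0.16),
        GenotypePreset("vgll4b", 1.35, 0.08),
        GenotypePreset("vgll4b_vgll4l", 1.50, 0.08),
        GenotypePreset("vgll4b_vgll4l_19hpf", 1.14, 0.08),
        GenotypePreset("vgll4b_oe", 0.80, 0.08),
        # yap1 overexpression in the double mutant adds +25% on top of the
        # double-mutant count (1.50 × 1.25)
        GenotypePreset("yap1_oe_in_double", 1.50 * 1.25, 0.08),
        GenotypePreset("vgll4b_yap1_triple", 0.90, 0.08),
        GenotypePreset("yap1_plus_vgll4b_oe", 0.80, 0.08, diving_probability=0.68),
        GenotypePreset("yap1_plus_vgll4l_oe", 0.80, 0.08, diving_probability=0.25),
        # reporter-intensity presets (counts unchanged)
        GenotypePreset("reporter_baseline", 1.0, 0.08, 1.0),
        GenotypePreset("reporter_yap1_oe", 1.0, 0.08, 1.70),
        GenotypePreset("reporter_yap1_mo", 1.0, 0.08, 0.88),
        GenotypePreset("reporter_vgll4b_kd", 1.0, 0.08, 1.27),
    ]
}


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def _ellipsoid_semi_axes(params: PrimordiumParams) -> tuple[float, float, float]:
    """Semi-axes (rz, ry, rx) of the tissue ellipsoid, µm, before rotation."""
    v_cell = _CELL_VOLUME_FACTOR * params.cell_diameter_um ** 3
    volume = params.n_cells * v_cell
    # rx = E·ry, rz = f·ry  =>  (4π/3)·E·f·ry³ = V
    ry = (3.0 * volume / (4.0 * math.pi * params.elongation * _Z_FLATTENING)) ** (1 / 3)
    return _Z_FLATTENING * ry, ry, params.elongation * ry


def _rotate_yx(points_yx: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate (y, x) points by ``angle_deg`` about the origin (array coords)."""
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    y, x = points_yx[..., 0], points_yx[..., 1]
    # positive angle tips the +x axis toward +y (downward in image display),
    # matching the moment-ellipse angle convention in registration.fit_ellipse
    return np.stack([x * s + y * c, x * c - y * s], axis=-1)


def _sample_centers(params: PrimordiumParams, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Cell centres (n, 3) µm in the *unrotated* ellipsoid frame, plus
    rosette centres (k, 2) as (y, x)."""
    rz, ry, rx = _ellipsoid_semi_axes(params)
    min_spacing = _MIN_SPACING_FACTOR * params.cell_diameter_um

    centers: list[np.ndarray] = []
    rosette_centers: list[np.ndarray] = []

    n_ros = params.n_rosettes
    per_ros = min(_CELLS_PER_ROSETTE, max(3, params.n_cells // max(n_ros, 1)))
    if n_ros * per_ros > params.n_cells:
        n_ros = params.n_cells // per_ros
    if n_ros > 0:
        r = params.rosette_radius_um
        # rosettes sit toward the trailing (−x) end where neuromasts mature,
        # staggered in y so several fit along the primordium
        need = 2 * r + min_spacing  # centre distance so rings never touch
        y_off = min(0.35 * ry, 0.45 * need) if n_ros > 1 else 0.0
        x_gap = math.sqrt(max(need ** 2 - (2 * y_off) ** 2, (0.5 * need) ** 2))
        x0 = -0.6 * rx
        for k in range(n_ros):
            cx = x0 + k * x_gap
            cy = y_off * (1 if k % 2 == 0 else -1)
            if cx + r > 0.8 * rx or abs(cy) + r > 0.9 * ry:
                raise InfeasibleGeometryError(
                    f"{params.n_rosettes} rosettes of radius {r} µm do not fit "
                    f"in a {2 * rx:.0f}×{2 * ry:.0f} µm primordium")
            rosette_centers.append(np.array([cy, cx]))
            phase = rng.uniform(0, 2 * math.pi)
            for j in range(per_ros):
                ang = phase + 2 * math.pi * j / per_ros
                centers.append(np.array([0.0, cy + r * math.sin(ang),
                                         cx + r * math.cos(ang)]))

    n_free = params.n_cells - len(centers)
    semi = np.array([rz, ry, rx])
    # centres stay slightly inside the shell so every cell keeps a dark
    # interior core under the outer membrane
    inner = 0.95 * semi
    if np.any(inner <= 0.5 * params.cell_diameter_um):
        if n_free == 1 and not centers:
            # degenerate single-cell tissue: the one cell sits at the centre
            return np.zeros((1, 3)), np.empty((0, 2))
        raise InfeasibleGeometryError(
            f"tissue ellipsoid {semi} µm too thin for "
            f"{params.cell_diameter_um} µm cells")
    max_attempts = 2000 * max(n_free, 1)
    attempts = 0
    placed = np.array(centers).reshape(-1, 3)
    while n_free > 0:
        if attempts >= max_attempts:
            raise InfeasibleGeometryError(
                f"could not place {params.n_cells} cells of diameter "
                f"{params.cell_diameter_um} µm after {max_attempts} attempts")
        attempts += 1
        p = rng.uniform(-1, 1, size=3) * semi
        if np.sum((p / inner) ** 2) > 1.0:
            continue
        if placed.size and np.min(np.linalg.norm(placed - p, axis=1)) < min_spacing:
            continue
        placed = np.vstack([placed, p])
        n_free -= 1

    ros = (np.array(rosette_centers).reshape(-1, 2)
           if rosette_centers else np.empty((0, 2)))
    return placed, ros


# --------------------------------------------------------------------------
# stack synthesis
# --------------------------------------------------------------------------

_OUTER_SHELL_WEIGHT = 2.0  # tissue-surface membrane vs inter-cell membrane


def _boundary_voxels(labels: np.ndarray) -> np.ndarray:
    """Weighted membrane indicator: voxels of a labelled cell that touch a
    different label (weight 1) or background (outer shell, weight 2) along
    any of the 6 axis directions."""
    out = np.zeros(labels.shape, dtype=np.float32)
    for ax in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(0, -1)
        hi[ax] = slice(1, None)
        a, b = labels[tuple(lo)], labels[tuple(hi)]
        inter = (a != b) & (a > 0) & (b > 0)
        outer_a = (b == 0) & (a > 0)
        outer_b = (a == 0) & (b > 0)
        lo_view, hi_view = out[tuple(lo)], out[tuple(hi)]
        np.maximum(lo_view, np.where(outer_a, _OUTER_SHELL_WEIGHT,
                                     np.where(inter, 1.0, lo_view)), out=lo_view)
        np.maximum(hi_view, np.where(outer_b, _OUTER_SHELL_WEIGHT,
                                     np.where(inter, 1.0, hi_view)), out=hi_view)
    return out


def _apply_noise(img: np.ndarray, params: PrimordiumParams,
                 rng: np.random.Generator) -> np.ndarray:
    """Poisson (photon) then additive Gaussian noise.  ``noise_sd == 0``
    together with an infinite photon_scale leaves the image untouched."""
    out = img
    if math.isfinite(params.photon_scale):
        out = rng.poisson(np.clip(out, 0, None) * params.photon_scale)
        out = out.astype(np.float32) / params.photon_scale
    if params.noise_sd > 0:
        out = out + rng.normal(0.0, params.noise_sd, size=out.shape).astype(np.float32)
    return out.astype(np.float32)


def make_primordium(params: PrimordiumParams, seed: int
                    ) -> tuple[VoxelStack, GroundTruth]:
    """Render one synthetic membrane-labelled primordium with exact truth.

    Channels: ``membrane`` (smoothed inter-cell + outer boundaries, the
    analogue of a lyn-GFP membrane label) and ``nuclei`` (Gaussian blobs at
    cell centres).  Deterministic given ``(params, seed)``.
    """
    rng = np.random.default_rng(seed)
    rz, ry, rx = _ellipsoid_semi_axes(params)
    centers, ros_centers = _sample_centers(params, rng)

    # rotate in-plane (y, x) by the requested orientation
    theta = params.orientation_deg
    cyx = _rotate_yx(centers[:, 1:], theta)
    centers = np.column_stack([centers[:, 0], cyx])
    if ros_centers.size:
        ros_centers = _rotate_yx(ros_centers, theta)

    # physical extents of the rotated ellipsoid + margin
    a = math.radians(theta)
    half_x = math.hypot(rx * math.cos(a), ry * math.sin(a))
    half_y = math.hypot(rx * math.sin(a), ry * math.cos(a))
    dz, dy, dx = params.voxel_spacing_um
    margin = params.membrane_width_um + 2.0 * np.array([dz, dy, dx])
    half = np.array([rz, half_y, half_x]) + margin
    shape = tuple(int(math.ceil(2 * h / s)) + 1
                  for h, s in zip(half, (dz, dy, dx)))
    center_off = np.array([(n - 1) / 2 * s for n, s in zip(shape, (dz, dy, dx))])

    # voxel physical coordinates
    zz = np.arange(shape[0]) * dz - center_off[0]
    yy = np.arange(shape[1]) * dy - center_off[1]
    xx = np.arange(shape[2]) * dx - center_off[2]
    Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij", sparse=False)

    # inside-ellipsoid test in the unrotated frame
    c, s = math.cos(a), math.sin(a)
    Xu = X * c + Y * s
    Yu = -X * s + Y * c
    inside = (Z / rz) ** 2 + (Yu / ry) ** 2 + (Xu / rx) ** 2 <= 1.0

    labels = np.zeros(shape, dtype=np.int32)
    pts = np.column_stack([Z[inside], Y[inside], X[inside]])
    if pts.size:
        tree = cKDTree(centers)
        _, idx = tree.query(pts, workers=-1)
        labels[inside] = idx.astype(np.int32) + 1

    # membrane channel: smoothed boundary indicator, normalized to max 1
    boundary = _boundary_voxels(labels).astype(np.float32)
    # apical constriction: membrane accumulates at the rosette centre, the
    # most salient rosette feature in membrane-labelled tissue
    for (cy, cx) in (ros_centers if ros_centers.size else []):
        cz = 0.0
        vz, vy, vx = np.rint((np.array([cz, cy, cx]) + center_off)
                             / np.array([dz, dy, dx])).astype(int)
        rr = params.membrane_width_um
        z_r = max(1, int(round(rr / dz)))
        y_r = max(1, int(round(rr / dy)))
        x_r = max(1, int(round(rr / dx)))
        zs = slice(max(0, vz - z_r), vz + z_r + 1)
        ys_ = slice(max(0, vy - y_r), vy + y_r + 1)
        xs_ = slice(max(0, vx - x_r), vx + x_r + 1)
        boundary[zs, ys_, xs_] = _OUTER_SHELL_WEIGHT
    sig_vox = (params.membrane_width_um / 2.0) / np.array([dz, dy, dx])
    membrane = ndi.gaussian_filter(boundary, sig_vox)
    peak = membrane.max()
    if peak > 0:
        membrane /= peak

    # nuclei channel: Gaussian blobs at cell centres
    nuclei = np.zeros(shape, dtype=np.float32)
    vox_idx = np.rint((centers + center_off) / np.array([dz, dy, dx])).astype(int)
    vox_idx = np.clip(vox_idx, 0, np.array(shape) - 1)
    nuclei[tuple(vox_idx.T)] = 1.0
    nuc_sig = (params.cell_diameter_um / 6.0) / np.array([dz, dy, dx])
    nuclei = ndi.gaussian_filter(nuclei, nuc_sig)
    peak = nuclei.max()
    if peak > 0:
        nuclei /= peak

    stack = VoxelStack(
        channels={
            "membrane": _apply_noise(membrane, params, rng),
            "nuclei": _apply_noise(nuclei, params, rng),
        },
        spacing_um=params.voxel_spacing_um,
        meta={"generator": "make_primordium", "seed": seed,
              "orientation_deg": theta},
    )

    vol = LabelVolume(labels, params.voxel_spacing_um)
    counts = np.bincount(labels.ravel(), minlength=params.n_cells + 1)[1:]
    truth = GroundTruth(
        label_volume=vol,
        cell_centers_um=centers + center_off,
        per_cell_volume_um3=counts * vol.voxel_volume_um3,
        rosette_centers_um=(ros_centers + center_off[1:]
                            if ros_centers.size else np.empty((0, 2))),
        true_count=int((counts > 0).sum()),
        extras={"semi_axes_um": (rz, ry, rx)},
    )
    return stack, truth


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

def draw_cohort_table(presets: Sequence[tuple[GenotypePreset, int]],
                      seed: int) -> pd.DataFrame:
    """Draw per-embryo ground-truth parameters for a cohort.

    One row per embryo: genotype, drawn cell count (rounded normal with mean
    ``120 × count_multiplier`` and CV ``count_cv``), diving flag
    (Bernoulli), EdU fraction, and the child seed used for its stack.
    """
    rng = np.random.default_rng(seed)
    ss = np.random.SeedSequence(seed)
    total = sum(n for _, n in presets)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(total)]
    rows = []
    i = 0
    for preset, n_embryos in presets:
        if n_embryos < 1:
            raise ValueError("n_embryos must be >= 1")
        mean = WT_MEAN_COUNT * preset.count_multiplier
        for j in range(n_embryos):
            n_cells = 0
            for _ in range(100):
                n_cells = int(round(rng.normal(mean, preset.count_cv * mean)))
                if n_cells >= 1:
                    break
            else:
                raise ValueError("could not draw a positive cell count")
            rows.append({
                "embryo": f"{preset.name}_{j:03d}",
                "genotype": preset.name,
                "true_n_cells": n_cells,
                "diving": bool(rng.random() < preset.diving_probability),
                "edu_fraction": preset.edu_fraction,
                "stack_seed": child_seeds[i],
            })
            i += 1
    return pd.DataFrame(rows)


def iter_cohort(presets: Sequence[tuple[GenotypePreset, int]],
                base: PrimordiumParams, seed: int
                ) -> Iterator[tuple[VoxelStack, GroundTruth, str]]:
    """Lazily generate the stacks of :func:`draw_cohort_table` one at a time."""
    table = draw_cohort_table(presets, seed)
    for row in table.itertuples():
        params = replace(base, n_cells=int(row.true_n_cells))
        stack, truth = make_primordium(params, int(row.stack_seed))
        truth.extras["diving"] = bool(row.diving)
        truth.extras["genotype"] = row.genotype
        yield stack, truth, str(row.embryo)


def make_cohort(presets: Sequence[tuple[GenotypePreset, int]],
                base: PrimordiumParams, seed: int
                ) -> tuple[list[tuple[VoxelStack, GroundTruth, str]], pd.DataFrame]:
    """Materialize a simulated cohort: per-embryo stacks + the truth table."""
    table = draw_cohort_table(presets, seed)
    embryos = list(iter_cohort(presets, base, seed))
    return embryos, table


# --------------------------------------------------------------------------
# reporter images
# --------------------------------------------------------------------------

def make_reporter_image(preset: GenotypePreset, base_intensity: float, seed: int,
                        *, noise_sd: float = 0.02,
                        mosaic_fraction: float = 0.3,
                        n_pseudo_cells: int = 40,
                        spacing_um: tuple[float, float, float] = (1.0, 0.5, 0.5),
                        ) -> VoxelStack:
    """Render a Tead-reporter stack whose in-primordium mean is exactly
    ``base_intensity × preset.reporter_multiplier`` before noise.

    Reporter expression is weak and mosaic: a fraction of pseudo-cells is
    "positive" (elevated above the surrounding tissue level), the rest sit at
    tissue background.  Tissue background outside the primordium also scales
    with the multiplier, so whole-image means scale by the multiplier too.
    Ground truth (mask, pseudo-cell labels, positive set) lives in
    ``stack.meta['truth']``.
    """
    if base_intensity <= 0:
        raise ValueError("base_intensity must be > 0")
    rng = np.random.default_rng(seed)
    level = base_intensity * preset.reporter_multiplier

    rz, ry, rx = 8.0, 12.0, 30.0
    dz, dy, dx = spacing_um
    shape = (int(2 * (rz + 2) / dz), int(2 * (ry + 3) / dy), int(2 * (rx + 3) / dx))
    off = np.array([(n - 1) / 2 * s for n, s in zip(shape, spacing_um)])
    zz = np.arange(shape[0]) * dz - off[0]
    yy = np.arange(shape[1]) * dy - off[1]
    xx = np.arange(shape[2]) * dx - off[2]
    Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
    mask = (Z / rz) ** 2 + (Y / ry) ** 2 + (X / rx) ** 2 <= 1.0

    # pseudo-cell partition of the mask (mosaic units)
    semi = np.array([rz, ry, rx])
    centers = []
    while len(centers) < n_pseudo_cells:
        p = rng.uniform(-1, 1, 3) * semi
        if np.sum((p / semi) ** 2) <= 0.9 ** 2:
            centers.append(p)
    centers = np.array(centers)
    pts = np.column_stack([Z[mask], Y[mask], X[mask]])
    _, idx = cKDTree(centers).query(pts, workers=-1)
    cell_of_voxel = idx + 1

    n_pos = int(round(mosaic_fraction * n_pseudo_cells))
    positive = rng.choice(np.arange(1, n_pseudo_cells + 1), size=n_pos, replace=False)
    w = np.full(n_pseudo_cells + 1, 0.5)
    w[positive] = 3.0
    weights = w[cell_of_voxel]
    weights /= weights.mean()  # in-mask mean weight exactly 1

    tissue_bg = 0.4  # non-expressing tissue, relative to the in-mask mean
    reporter = np.full(shape, tissue_bg * level, dtype=np.float32)
    reporter[mask] = (level * weights).astype(np.float32)

    if noise_sd > 0:
        reporter = reporter + rng.normal(0, noise_sd, shape).astype(np.float32)

    labels = np.zeros(shape, dtype=np.int32)
    labels[mask] = cell_of_voxel
    stack = VoxelStack(
        channels={"reporter": reporter, "marker": mask.astype(np.float32)},
        spacing_um=spacing_um,
        meta={
            "generator": "make_reporter_image",
            "seed": seed,
            "truth": {
                "mask": mask,
                "labels": labels,
                "positive_labels": np.sort(positive),
                "in_mask_mean": level,
                "tissue_background": tissue_bg * level,
            },
        },
    )
    return stack


def make_edu_channel(stack: VoxelStack, truth: GroundTruth, edu_fraction: float,
                     seed: int, *, intensity: float = 1.0,
                     noise_sd: float = 0.0) -> np.ndarray:
    """Add an ``edu`` channel: bright nuclear blobs in a random cell subset.

    The chosen labels are recorded in ``truth.extras['edu_labels']``; the
    channel is also returned.
    """
    if not 0 <= edu_fraction <= 1:
        raise ValueError("edu_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = truth.true_count
    n_pos = int(round(edu_fraction * n))
    pos = np.sort(rng.choice(np.arange(1, n + 1), size=n_pos, replace=False))

    dz, dy, dx = stack.spacing_um
    edu = np.zeros(stack.shape, dtype=np.float32)
    if n_pos:
        centers = truth.cell_centers_um[pos - 1]
        vox = np.rint(centers / np.array([dz, dy, dx])).astype(int)
        vox = np.clip(vox, 0, np.array(stack.shape) - 1)
        edu[tuple(vox.T)] = 1.0
        sig = 1.2 / np.array([dz, dy, dx])
        edu = ndi.gaussian_filter(edu, sig)
        edu *= intensity / edu.max()
    if noise_sd > 0:
        edu = edu + rng.normal(0, noise_sd, edu.shape).astype(np.float32)
    stack.channels["edu"] = edu
    truth.extras["edu_labels"] = pos
    return edu


# --------------------------------------------------------------------------
# qPCR plates
# --------------------------------------------------------------------------

def make_qpcr_plate(true_fold: float, ct_noise_sd: float, n_biological: int,
                    n_technical: int = 3, seed: int = 0, *,
                    target_gene: str = "target", ref_gene: str = "rpl13",
                    control_group: str = "control", test_group: str = "mutant",
                    baseline_ct: float = 24.0, ref_ct: float = 18.0
                    ) -> pd.DataFrame:
    """Simulate a Ct plate with a known expression fold change.

    Control-group target Ct sits at ``baseline_ct``; the test group's target
    Ct is shifted by ``−log2(true_fold)`` (higher Ct = less template).  The
    reference gene is group-independent.  Per-well Gaussian Ct noise.
    """
    if true_fold <= 0:
        raise ValueError("true_fold must be > 0")
    if n_biological < 1 or n_technical < 1:
        raise ValueError("replicate counts must be >= 1")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group in (control_group, test_group):
        shift = 0.0 if group == control_group else -math.log2(true_fold)
        for b in range(n_biological):
            sample = f"{group}_{b:02d}"
            for gene, mean in ((target_gene, baseline_ct + shift), (ref_gene, ref_ct)):
                for t in range(n_technical):
                    ct = mean + (rng.normal(0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
                    rows.append({"gene": gene, "sample": sample, "group": group,
                                 "replicate": t + 1, "ct": float(ct)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# deposition overviews
# --------------------------------------------------------------------------

def make_overview(cluster_positions_um: Sequence[tuple[float, float]],
                  cluster_n_cells: Sequence[int],
                  image_size: tuple[int, int] = (128, 512),
                  seed: int = 0, *, spacing_um: float = 1.0,
                  noise_sd: float = 0.0
                  ) -> tuple[np.ndarray, dict]:
    """Render a 2D trunk overview: ganglion (first cluster) + neuromasts.

    Returns ``(image, truth)``; truth records the positions (y, x) µm and
    cell counts.  Overlapping clusters are rejected.
    """
    positions = np.asarray(cluster_positions_um, dtype=float).reshape(-1, 2)
    counts = np.asarray(cluster_n_cells, dtype=int)
    if len(positions) != len(counts):
        raise ValueError("positions and counts must have equal length")
    if len(positions) == 0:
        raise ValueError("need at least one cluster (the ganglion)")
    ny, nx = image_size
    radii = 1.5 * np.sqrt(np.maximum(counts, 1))  # µm; blob area ∝ cell count
    for i, (p, r) in enumerate(zip(positions, radii)):
        if not (r <= p[0] <= ny * spacing_um - r and r <= p[1] <= nx * spacing_um - r):
            raise ValueError(f"cluster {i} at {tuple(p)} µm falls outside the image")
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            if np.linalg.norm(positions[i] - positions[j]) < radii[i] + radii[j] + 2:
                raise ValueError(f"clusters {i} and {j} overlap")

    yy = np.arange(ny) * spacing_um
    xx = np.arange(nx) * spacing_um
    Y, X = np.meshgrid(yy, xx, indexing="ij")
    img = np.zeros((ny, nx), dtype=np.float32)
    for p, r in zip(positions, radii):
        img[np.hypot(Y - p[0], X - p[1]) <= r] = 1.0
    img = ndi.gaussian_filter(img, 1.0 / spacing_um)
    if img.max() > 0:
        img /= img.max()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0, noise_sd, img.shape).astype(np.float32)
    truth = {"positions_um": positions, "n_cells": counts,
             "spacing_um": spacing_um, "radii_um": radii}
    return img, truth


# --------------------------------------------------------------------------
# fixture helpers for downstream tests
# --------------------------------------------------------------------------

def inject_speckle_labels(volume: LabelVolume, n: int, speckle_voxels: int,
                          seed: int = 0) -> tuple[LabelVolume, np.ndarray]:
    """Inject ``n`` tiny debris labels into background for filter tests.

    Each speckle is a compact blob of ``speckle_voxels`` voxels.  Returns the
    modified copy and the new label ids.
    """
    rng = np.random.default_rng(seed)
    data = volume.data.copy()
    start = int(data.max()) + 1
    bg = np.argwhere(data == 0)
    if len(bg) < n * speckle_voxels:
        raise ValueError("not enough background for speckles")
    new_ids = []
    placed = 0
    attempts = 0
    while placed < n and attempts < 10000:
        attempts += 1
        z, y, x = bg[rng.integers(len(bg))]
        side = max(1, int(round(speckle_voxels ** (1 / 3))))
        sl = (slice(z, z + 1), slice(y, y + side), slice(x, x + side * 2))
        region = data[sl]
        if region.size < speckle_voxels or (region != 0).any():
            continue
        flat = region.ravel()
        flat[:speckle_voxels] = start + placed
        data[sl] = flat.reshape(region.shape)
        new_ids.append(start + placed)
        placed += 1
    if placed < n:
        raise ValueError("could not place all speckles")
    return LabelVolume(data, volume.spacing_um, meta=dict(volume.meta)), np.array(new_ids)
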