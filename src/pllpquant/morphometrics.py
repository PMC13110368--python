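"""Morphometric readouts: counts, shape descriptors, rosettes, deposition, area.

Shape descriptors follow the ImageJ definitions (circularity = 4π·area/perimeter²,
AR = major/minor of the moment ellipse, roundness = 4·area/(π·major²),
solidity = area/convex area).  Rosette detection replaces a trained CNN with a
transparent geometric detector: normalized cross-correlation of a mid-tissue
membrane section against a radially symmetric apical-hub template; the
downstream statistic, rosettiness = Σ scores / n detections, is independent of
the score source and any external score list can be fed to it.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage as ndi
from skimage import measure as skmeasure
from skimage.feature import match_template, peak_local_max
from skimage.filters import threshold_otsu

from .exceptions import (BimodalSeparationError, DegenerateMaskError,
                         EmptyMaskError)
from .registration import minimum_threshold
from .types import (CellTable, DepositionPattern, Mask2D, PrimordiumSummary,
                    RosetteDetection, VoxelStack)

DEFAULT_ROSETTE_RADIUS_UM = 5.0
DEFAULT_HUB_RADIUS_UM = 1.5
DEFAULT_DETECTION_FLOOR = 0.8
DEFAULT_CLUSTER_FLOOR_PX = 20


def shape_descriptors(mask: Mask2D) -> tuple[float, float, float, float]:
    """(aspect_ratio, circularity, roundness, solidity) of a 2D mask.

    Requires isotropic pixels (dy == dx); all four are dimensionless.
    """
    dy, dx = mask.spacing_um
    if not math.isclose(dy, dx, rel_tol=1e-6):
        raise ValueError("shape descriptors require isotropic pixels")
    if mask.n_foreground == 0:
        raise EmptyMaskError("empty mask")
    props = skmeasure.regionprops(mask.data.astype(np.uint8))
    if not props:
        raise EmptyMaskError("empty mask")
    p = max(props, key=lambda r: r.area)
    if p.axis_minor_length == 0:
        raise DegenerateMaskError("mask degenerate: zero minor axis")
    area = float(p.area)
    # Crofton perimeter: far less rasterization bias than edge counting,
    # matching the calibrated perimeter ImageJ-style tools report
    perim = float(skmeasure.perimeter_crofton(p.image, directions=4))
    if perim == 0:
        raise DegenerateMaskError("mask degenerate: zero perimeter")
    aspect_ratio = float(p.axis_major_length / p.axis_minor_length)
    circularity = min(4.0 * math.pi * area / perim ** 2, 1.05)
    roundness = 4.0 * area / (math.pi * p.axis_major_length ** 2)
    solidity = float(p.solidity)
    return aspect_ratio, circularity, roundness, solidity


def _hub_template(radius_px: float, hub_px: float) -> np.ndarray:
    """Rosette template: a bright apical hub surrounded by the dark interiors
    of the ring cells.  Radially symmetric, so no phase search is needed."""
    r = max(int(math.ceil(0.5 * radius_px)), int(hub_px) + 3)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1].astype(float)
    rho = np.hypot(yy, xx)
    t = np.zeros_like(rho)
    t[rho <= hub_px] = 1.0
    return ndi.gaussian_filter(t, 1.0)


def detect_rosettes(image: Union[VoxelStack, np.ndarray], mask: Mask2D,
                    expected_radius_um: float = DEFAULT_ROSETTE_RADIUS_UM,
                    *, channel: str = "membrane",
                    floor: float = DEFAULT_DETECTION_FLOOR,
                    hub_radius_um: float = DEFAULT_HUB_RADIUS_UM
                    ) -> list[RosetteDetection]:
    """Template-correlation rosette detector on a mid-tissue optical section.

    Rosettes read out as a bright apical membrane focus (the constriction
    point where the ring cells meet) surrounded by their dark interiors.
    The score map is the normalized cross-correlation of the section with a
    radially symmetric hub-plus-dark-annulus template; detections are local
    maxima above ``floor`` inside the mask eroded by ¾ of the expected
    radius (rosettes are interior structures; the bright tissue shell is
    excluded), non-maximum-suppressed at 1.5× the radius.  Scores are
    clipped to [0, 1].

    ``image`` may be a :class:`VoxelStack` (the central z-slice of
    ``channel`` is used as the optical section) or a pre-computed 2D image.
    """
    if expected_radius_um <= 0:
        raise ValueError("expected_radius_um must be > 0")
    if isinstance(image, VoxelStack):
        arr = image.channel(channel)
        proj = arr[arr.shape[0] // 2]
    else:
        proj = np.asarray(image, dtype=float)
        if proj.ndim != 2:
            raise ValueError("need a 2D section or a VoxelStack")
    dy, dx = mask.spacing_um
    if proj.shape != mask.data.shape:
        raise ValueError("section and mask shapes differ")
    radius_px = expected_radius_um / dx
    template = _hub_template(radius_px, hub_radius_um / dx)
    if any(t > s for t, s in zip(template.shape, proj.shape)):
        return []

    corr = match_template(proj, template, pad_input=True, mode="constant")
    interior = ndi.binary_erosion(mask.data,
                                  iterations=max(1, int(0.75 * radius_px)))
    corr = np.where(interior, corr, -1.0)
    min_dist = max(1, int(round(1.5 * radius_px)))
    peaks = peak_local_max(corr, min_distance=min_dist, threshold_abs=floor,
                           exclude_border=False)
    out = []
    for y, x in peaks:
        score = float(np.clip(corr[y, x], 0.0, 1.0))
        out.append(RosetteDetection(center_um=(y * dy, x * dx),
                                    radius_um=expected_radius_um, score=score))
    out.sort(key=lambda d: -d.score)
    return out


def rosettiness(detections: Sequence) -> Optional[float]:
    """Σ detection scores / number of detections; ``None`` when there are no
    detections (undefined, deliberately distinct from 0).

    Accepts :class:`RosetteDetection` items or bare scores, so externally
    produced score lists (e.g. from a learned detector) plug in directly.
    """
    if len(detections) == 0:
        return None
    scores = [d.score if isinstance(d, RosetteDetection) else float(d)
              for d in detections]
    return float(sum(scores) / len(scores))


def summarize_primordium(cells: CellTable, mask: Optional[Mask2D] = None,
                         detections: Optional[Sequence[RosetteDetection]] = None,
                         diving: Optional[bool] = None) -> PrimordiumSummary:
    """Collect one embryo's readout: kept-cell count and volume, 2D shape
    descriptors of the projection mask, and rosettiness."""
    count = cells.n_kept
    total = cells.total_kept_volume_um3
    ar = circ = rnd = sol = None
    if mask is not None and count > 0:
        ar, circ, rnd, sol = shape_descriptors(mask)
    n_det = len(detections) if detections is not None else 0
    ros = rosettiness(detections) if detections else None
    return PrimordiumSummary(cell_count=count, total_volume_um3=total,
                             aspect_ratio=ar, circularity=circ, roundness=rnd,
                             solidity=sol, n_rosette_detections=n_det,
                             rosettiness=ros, diving=diving)


def deposition_pattern(image: np.ndarray, spacing_um: float = 1.0,
                       size_floor_px: int = DEFAULT_CLUSTER_FLOOR_PX,
                       primordium_at_end: bool = False) -> DepositionPattern:
    """Cluster positions along the AP (x) axis, normalized to the ganglion.

    Threshold → connected components → size floor → centroids sorted by x →
    subtract the first (ganglion) position.  ``primordium_at_end`` excludes a
    terminal primordium cluster from the neuromast count.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("overview image must be 2D")
    if img.max() == img.min():
        raise EmptyMaskError("no clusters: constant image")
    thr = threshold_otsu(img)
    lab, n = ndi.label(img > thr)
    if n == 0:
        raise EmptyMaskError("no clusters detected")
    sizes = np.bincount(lab.ravel())
    keep = [i for i in range(1, n + 1) if sizes[i] >= size_floor_px]
    if not keep:
        raise EmptyMaskError("all clusters below the size floor")
    cents = ndi.center_of_mass(np.ones_like(lab), lab, keep)
    xs = sorted(c[1] * spacing_um for c in cents)
    positions = [x - xs[0] for x in xs]
    n_neuromasts = len(positions) - 1 - (1 if primordium_at_end and
                                         len(positions) > 1 else 0)
    return DepositionPattern(positions_um=positions, n_neuromasts=n_neuromasts)


def stained_area(image: np.ndarray, calibration_um_per_px: float) -> float:
    """Area (µm²) of the largest dark-stained region of a 2D image.

    Uses the same bimodal-minimum auto-threshold as registration, inverted
    for a dark in-situ stain.  Returns 0 with a warning when no stain is
    separable (e.g. a blank image).
    """
    if calibration_um_per_px <= 0:
        raise ValueError("calibration must be > 0")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("stained-area image must be 2D")
    try:
        thr = minimum_threshold(img)
    except BimodalSeparationError:
        warnings.warn("no stain detected: histogram not bimodal", stacklevel=2)
        return 0.0
    stain = img < thr
    if not stain.any():
        warnings.warn("no stain detected below threshold", stacklevel=2)
        return 0.0
    lab, n = ndi.label(stain)
    sizes = np.bincount(lab.ravel())[1:]
    return float(sizes.max()) * calibration_um_per_px ** 2
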