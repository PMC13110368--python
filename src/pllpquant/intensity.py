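"""Fluorescence intensity readouts: mean gray values, positive-cell counts,
line profiles with midpoint ratios, and EdU proliferation fractions.

"Positive" cells are operationalized as cells whose mean intensity exceeds
the background mean by k standard deviations of the background (default
k = 2) — the quantitative stand-in for "significantly higher fluorescence
than the surrounding non-expressing tissue".
"""

from __future__ import annotations

import math
from typing import Optional, Union

import numpy as np
from scipy import ndimage as ndi

from .exceptions import UndefinedStatisticError
from .types import LabelVolume, Mask2D, ProfileCurve, VoxelStack

DEFAULT_POSITIVITY_K = 2.0
DEFAULT_PROFILE_STATIONS = 100
DEFAULT_PROFILE_WIDTH_PX = 3

MODE_WHOLE_IMAGE = "whole_image_avg_projection"
MODE_SINGLE_PLANE = "single_plane_roi"


def mean_gray(stack: VoxelStack, channel: str,
              roi: Union[Mask2D, np.ndarray, None] = None,
              mode: str = MODE_WHOLE_IMAGE, plane: Optional[int] = None
              ) -> float:
    """Mean gray value of a channel.

    ``whole_image_avg_projection``: mean over all pixels of the
    average-intensity Z projection (identical to the full-stack mean).
    ``single_plane_roi``: mean over the ROI pixels of one z-plane
    (default: the central plane).
    """
    img = stack.channel(channel)
    if mode == MODE_WHOLE_IMAGE:
        return float(img.mean(axis=0).mean())
    if mode == MODE_SINGLE_PLANE:
        z = img.shape[0] // 2 if plane is None else plane
        if not 0 <= z < img.shape[0]:
            raise ValueError(f"plane {z} outside stack of {img.shape[0]} slices")
        sl = img[z]
        if roi is None:
            raise ValueError("single_plane_roi mode needs an ROI")
        roi_arr = roi.data if isinstance(roi, Mask2D) else np.asarray(roi, bool)
        if roi_arr.shape != sl.shape:
            raise ValueError("ROI shape does not match the plane")
        if not roi_arr.any():
            raise ValueError("empty ROI")
        return float(sl[roi_arr].mean())
    raise ValueError(f"unknown mode {mode!r}")


def _per_cell_means(labels: LabelVolume, channel: np.ndarray) -> np.ndarray:
    ids = labels.labels
    if channel.shape != labels.data.shape:
        raise ValueError("channel and label volume shapes differ")
    return np.asarray(ndi.mean(channel, labels.data, ids), dtype=float)


def count_positive_cells(labels: LabelVolume, reporter: np.ndarray,
                         background_mask: Optional[np.ndarray] = None,
                         k: float = DEFAULT_POSITIVITY_K) -> int:
    """Number of cells whose mean reporter intensity exceeds
    background mean + k × background SD.

    ``background_mask`` defaults to all unlabelled voxels; it must be
    disjoint from the cells.
    """
    if background_mask is None:
        background_mask = labels.data == 0
    else:
        background_mask = np.asarray(background_mask, bool)
        if (background_mask & (labels.data > 0)).any():
            raise ValueError("background ROI overlaps labelled cells")
    if not background_mask.any():
        raise ValueError("empty background ROI")
    bg = reporter[background_mask]
    thr = float(bg.mean()) + k * float(bg.std())
    means = _per_cell_means(labels, reporter)
    return int((means > thr).sum())


def line_profile(images: dict[str, np.ndarray],
                 segment: tuple[tuple[float, float], tuple[float, float]],
                 width_px: int = DEFAULT_PROFILE_WIDTH_PX,
                 n_stations: int = DEFAULT_PROFILE_STATIONS) -> ProfileCurve:
    """Band-averaged intensity profile along a 2D segment.

    ``images`` maps channel name → 2D array; ``segment`` is ((y0, x0),
    (y1, x1)) in pixel coordinates.  At ``n_stations`` evenly spaced points
    the mean over a perpendicular band of ``width_px`` pixels is taken;
    station positions are expressed as relative distance in [0, 1] and each
    channel is normalized to its own maximum along the profile.
    """
    (y0, x0), (y1, x1) = segment
    length = math.hypot(y1 - y0, x1 - x0)
    if length == 0:
        raise ValueError("zero-length profile segment")
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    t = np.linspace(0.0, 1.0, n_stations)
    uy, ux = (y1 - y0) / length, (x1 - x0) / length
    ny, nx = -ux, uy  # unit normal
    offsets = np.arange(width_px, dtype=float) - (width_px - 1) / 2.0

    ys = y0 + t[:, None] * (y1 - y0) + offsets[None, :] * ny
    xs = x0 + t[:, None] * (x1 - x0) + offsets[None, :] * nx
    coords = np.stack([ys.ravel(), xs.ravel()])

    values: dict[str, np.ndarray] = {}
    for name, img in images.items():
        img = np.asarray(img, dtype=float)
        if img.ndim != 2:
            raise ValueError(f"channel {name!r} is not 2D")
        samples = ndi.map_coordinates(img, coords, order=1, mode="nearest")
        prof = samples.reshape(n_stations, width_px).mean(axis=1)
        peak = prof.max()
        if peak <= 0:
            raise UndefinedStatisticError(
                f"channel {name!r} has no signal along the profile")
        values[name] = prof / peak
    return ProfileCurve(relative_distance=t, values=values, width_px=width_px)


def midpoint_normalized_intensity(profile: ProfileCurve, target_channel: str,
                                  ref_channel: str) -> float:
    """Target/reference ratio of the normalized profiles at relative
    distance 0.5 (linear interpolation)."""
    for ch in (target_channel, ref_channel):
        if ch not in profile.values:
            raise KeyError(f"channel {ch!r} not on the profile")
    d = profile.relative_distance
    if not (d[0] <= 0.5 <= d[-1]):
        raise ValueError("profile does not cover relative distance 0.5")
    target = float(np.interp(0.5, d, profile.values[target_channel]))
    ref = float(np.interp(0.5, d, profile.values[ref_channel]))
    if ref == 0:
        raise UndefinedStatisticError("reference channel is 0 at the midpoint")
    return target / ref


def edu_counts(labels: LabelVolume, edu_channel: np.ndarray,
               k: float = DEFAULT_POSITIVITY_K,
               background_mask: Optional[np.ndarray] = None
               ) -> tuple[int, int, Optional[float]]:
    """(n_positive, n_total, ratio) of EdU-positive cells.

    Positivity uses the same background + k·SD rule as reporter counting;
    the ratio is ``None`` (undefined) when there are no cells.
    """
    n_total = int(labels.n_labels)
    if n_total == 0:
        return 0, 0, None
    n_pos = count_positive_cells(labels, edu_channel,
                                 background_mask=background_mask, k=k)
    return n_pos, n_total, n_pos / n_total
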