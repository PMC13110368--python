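"""Locate, orient and crop the primordium before 3D segmentation.

The pre-processing mirrors the classic projection-based recipe: maximum
Z-projection → Gaussian blur → bimodal-histogram ("Minimum") auto-threshold →
largest component mask → second-moment ellipse → in-plane rotation that puts
the long axis horizontal → crop in Y/X to the mask bounding box (+margin) and
in Z to slices with in-mask signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .exceptions import BimodalSeparationError, DegenerateMaskError, EmptyMaskError
from .types import EllipseFit, LabelVolume, Mask2D, VoxelStack

DEFAULT_BLUR_SIGMA_UM = 2.0
DEFAULT_MARGIN_UM = 5.0
_MAX_SMOOTH_ITER = 10000


def minimum_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Bimodal-histogram minimum threshold (the ImageJ "Minimum" method).

    The 256-bin histogram is repeatedly smoothed with a length-3 running mean
    until exactly two local maxima remain; the threshold is the histogram
    minimum between them, mapped back to intensity units.

    Raises
    ------
    BimodalSeparationError
        if the histogram never reaches a two-peak state (e.g. uniform input).
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0 or v.min() == v.max():
        raise BimodalSeparationError("no bimodal separation: constant image")
    hist, edges = np.histogram(v, bins=nbins)
    h = hist.astype(float)

    def local_maxima(a: np.ndarray) -> np.ndarray:
        pad = np.concatenate([[-np.inf], a, [-np.inf]])
        return np.flatnonzero((pad[1:-1] > pad[:-2]) & (pad[1:-1] > pad[2:]))

    for _ in range(_MAX_SMOOTH_ITER):
        if local_maxima(h).size == 2:
            break
        h = np.convolve(h, np.ones(3) / 3.0, mode="same")
    else:
        raise BimodalSeparationError(
            "no bimodal separation after maximum smoothing iterations")

    peaks = local_maxima(h)
    if peaks.size < 2:
        raise BimodalSeparationError("histogram degenerated to one peak")
    lo, hi = int(peaks[0]), int(peaks[-1])
    valley = lo + int(np.argmin(h[lo:hi + 1]))
    centers = (edges[:-1] + edges[1:]) / 2.0
    return float(centers[valley])


def project_and_mask(stack: VoxelStack, channel: str = "membrane",
                     blur_sigma_um: float = DEFAULT_BLUR_SIGMA_UM) -> Mask2D:
    """Maximum Z-projection → blur → minimum threshold → largest component."""
    if blur_sigma_um < 0:
        raise ValueError("blur_sigma_um must be >= 0")
    img = stack.channel(channel)
    _, dy, dx = stack.spacing_um
    proj = img.max(axis=0)
    if blur_sigma_um > 0:
        proj = ndi.gaussian_filter(proj, (blur_sigma_um / dy, blur_sigma_um / dx))
    thr = minimum_threshold(proj)
    fg = proj > thr
    if not fg.any():
        raise EmptyMaskError("threshold produced an empty mask")
    lab, n = ndi.label(fg)
    if n > 1:
        sizes = np.bincount(lab.ravel())[1:]
        fg = lab == (int(np.argmax(sizes)) + 1)
    return Mask2D(fg, (dy, dx))


def fit_ellipse(mask: Mask2D) -> EllipseFit:
    """Second-central-moment ellipse of the mask, in physical coordinates.

    Axis lengths follow the moment-ellipse convention (length = 4·√eigenvalue
    of the coordinate covariance); the angle is that of the principal
    eigenvector against the +x axis in array coordinates, in (−90, 90].
    """
    ys, xs = np.nonzero(mask.data)
    if ys.size == 0:
        raise EmptyMaskError("cannot fit an ellipse to an empty mask")
    if ys.size < 4:
        raise DegenerateMaskError(f"mask of {ys.size} px is degenerate for a fit")
    dy, dx = mask.spacing_um
    y = ys * dy
    x = xs * dx
    cy, cx = float(y.mean()), float(x.mean())
    # pixel-extent correction: a pixel is a dy×dx square, not a point
    cov = np.cov(np.stack([y - cy, x - cx]), bias=True)
    cov[0, 0] += dy * dy / 12.0
    cov[1, 1] += dx * dx / 12.0
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] <= 0:
        raise DegenerateMaskError("degenerate (collinear) mask")
    major = 4.0 * math.sqrt(evals[1])
    minor = 4.0 * math.sqrt(evals[0])
    vy, vx = evecs[:, 1]
    angle = math.degrees(math.atan2(vy, vx))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    return EllipseFit(centroid_um=(cy, cx), major_axis_um=major,
                      minor_axis_um=minor, angle_deg=angle)


@dataclass(frozen=True)
class RegistrationTransform:
    """In-plane rotation + crop computed by :func:`register_stack`.

    Reusable on a ground-truth :class:`LabelVolume` via
    :func:`transform_labels` (nearest-neighbour interpolation).
    """

    angle_deg: float
    z_slice: tuple[int, int]
    y_slice: tuple[int, int]
    x_slice: tuple[int, int]


def _rotate_volume(vol: np.ndarray, angle_deg: float, order: int) -> np.ndarray:
    """Rotate every z-slice in-plane by −angle about the image centre."""
    if abs(angle_deg) < 1e-9:
        return vol.copy()
    return ndi.rotate(vol, angle_deg, axes=(2, 1), reshape=True, order=order,
                      mode="constant", cval=0.0, prefilter=order > 1)


def register_stack(stack: VoxelStack, fit: EllipseFit,
                   margin_um: float = DEFAULT_MARGIN_UM,
                   channel: str = "membrane") -> VoxelStack:
    """Rotate the stack so the fitted long axis is horizontal, then crop.

    Y/X crop: bounding box of the rotated mask + ``margin_um``.  Z crop:
    keep the contiguous slice range whose in-mask mean intensity exceeds the
    out-of-mask background mean + 2 SD, padded by one slice.  The applied
    transform is stored in ``out.meta['registration']``.
    """
    if margin_um < 0:
        raise ValueError("margin_um must be >= 0")
    dz, dy, dx = stack.spacing_um
    if not math.isclose(dy, dx, rel_tol=1e-6):
        raise ValueError("in-plane rotation requires dy == dx")

    mask = project_and_mask(stack, channel=channel)
    angle = fit.angle_deg
    rot_mask = _rotate_volume(mask.data[None].astype(np.uint8), angle, order=0)[0] > 0
    if not rot_mask.any():
        raise EmptyMaskError("mask vanished under rotation")
    ys, xs = np.nonzero(rot_mask)
    my = int(round(margin_um / dy))
    mx = int(round(margin_um / dx))
    y0, y1 = max(0, ys.min() - my), min(rot_mask.shape[0], ys.max() + 1 + my)
    x0, x1 = max(0, xs.min() - mx), min(rot_mask.shape[1], xs.max() + 1 + mx)
    if y1 <= y0 or x1 <= x0:
        raise EmptyMaskError("margin produced an empty crop")

    rot_channels = {name: _rotate_volume(arr, angle, order=1)
                    for name, arr in stack.channels.items()}

    # z-crop from in-mask vs out-of-mask intensity of the registration channel
    ref = rot_channels[channel]
    out_vals = ref[:, ~rot_mask]
    bg_mean, bg_sd = float(out_vals.mean()), float(out_vals.std())
    slice_means = np.array([ref[z][rot_mask].mean() for z in range(ref.shape[0])])
    keep = np.flatnonzero(slice_means > bg_mean + 2.0 * bg_sd)
    if keep.size == 0:
        z0, z1 = 0, ref.shape[0]
    else:
        z0 = max(0, int(keep.min()) - 1)
        z1 = min(ref.shape[0], int(keep.max()) + 2)

    out_channels = {name: arr[z0:z1, y0:y1, x0:x1]
                    for name, arr in rot_channels.items()}
    transform = RegistrationTransform(angle_deg=angle, z_slice=(z0, z1),
                                      y_slice=(y0, y1), x_slice=(x0, x1))
    meta = dict(stack.meta)
    meta["registration"] = transform
    return VoxelStack(out_channels, stack.spacing_um, origin_um=stack.origin_um,
                      meta=meta)


def transform_labels(labels: LabelVolume,
                     transform: RegistrationTransform) -> LabelVolume:
    """Apply a stack's registration transform to its ground-truth labels."""
    rot = _rotate_volume(labels.data, transform.angle_deg, order=0)
    z0, z1 = transform.z_slice
    y0, y1 = transform.y_slice
    x0, x1 = transform.x_slice
    out = rot[z0:z1, y0:y1, x0:x1]
    return LabelVolume(out.astype(labels.data.dtype), labels.spacing_um,
                       meta=dict(labels.meta))
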