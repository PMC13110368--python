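"""Single-cell 3D segmentation of the membrane channel and per-cell measurement.

The membrane image, after an anisotropy-corrected 3D Gaussian blur, is treated
as a topographic relief: shallow minima are suppressed with an h-minima
transform, the remaining minima seed a marker-controlled watershed, and the
region connected to the lateral stack border through low-intensity space is
the background.  Per-label physical measurements (volume, exposed-face surface
area, centroid, per-channel mean intensities) follow, and a robust
median±MAD fence on volume and surface/volume ratio flags cells that are
unlikely to belong to the primordium (e.g. wrongly segmented skin cells).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import morphology, segmentation as skseg

from .exceptions import SegmentationEmptyError
from .types import (CELL_COLUMNS, CellTable, FLAG_KEPT, FLAG_OUTLIER_SV,
                    FLAG_OUTLIER_VOLUME, LabelVolume, VoxelStack)

DEFAULT_SIGMA_UM = 0.75
DEFAULT_H_DEPTH = 0.05
DEFAULT_V_MIN_UM3 = 30.0
DEFAULT_V_MAX_UM3 = 3000.0
DEFAULT_FENCE_K = 3.5

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def segment_cells(stack: VoxelStack, channel: str = "membrane",
                  sigma_um: float = DEFAULT_SIGMA_UM,
                  h_depth: float = DEFAULT_H_DEPTH,
                  markers: np.ndarray | None = None) -> LabelVolume:
    """Marker-controlled watershed on the blurred membrane relief.

    Parameters
    ----------
    sigma_um : physical Gaussian blur, corrected per axis for anisotropy.
    h_depth : minimum depth a regional minimum must have to seed a cell,
        on the nominal [0, 1] intensity scale.
    markers : optional pre-labelled marker volume (e.g. ground-truth seeds);
        bypasses the h-minima step when given.
    """
    if sigma_um < 0:
        raise ValueError("sigma_um must be >= 0")
    if h_depth <= 0:
        raise ValueError("h_depth must be > 0")
    img = stack.channel(channel).astype(np.float32)
    spacing = np.asarray(stack.spacing_um)
    if sigma_um > 0:
        img = ndi.gaussian_filter(img, sigma_um / spacing)

    external_markers = markers is not None
    if markers is None:
        minima = morphology.h_minima(img, h_depth)
        markers, n_markers = ndi.label(minima, structure=_CONN26)
        if n_markers == 0:
            raise SegmentationEmptyError("flat relief: no watershed markers found")
    else:
        markers = np.asarray(markers)
        if markers.shape != img.shape:
            raise ValueError("marker volume shape mismatch")

    ws = skseg.watershed(img, markers=markers)

    # background = region(s) reaching the lateral (y/x) stack border
    border = np.zeros(ws.shape, dtype=bool)
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    bg_ids = np.unique(ws[border])
    out = np.where(np.isin(ws, bg_ids), 0, ws)
    if not out.any():
        raise SegmentationEmptyError("all regions classified as background")
    if external_markers:  # caller-supplied ids are meaningful: keep them
        relabeled = out
    else:
        relabeled, _, _ = skseg.relabel_sequential(out)
    return LabelVolume(relabeled.astype(np.int32), stack.spacing_um,
                       meta={"sigma_um": sigma_um, "h_depth": h_depth,
                             "channel": channel})


def filter_segments(labels: LabelVolume,
                    v_min_um3: float = DEFAULT_V_MIN_UM3,
                    v_max_um3: float = DEFAULT_V_MAX_UM3) -> LabelVolume:
    """Drop labels with physical volume outside [v_min, v_max] and trim
    blank Z-slices at either stack end.

    Removed labels are recorded in ``out.meta['volume_filtered']`` and the
    z-trim in ``out.meta['z_trim']`` so an aligned intensity stack can be
    cropped identically.
    """
    if not v_min_um3 < v_max_um3:
        raise ValueError("need v_min < v_max")
    data = labels.data
    vox = labels.voxel_volume_um3
    counts = np.bincount(data.ravel())
    vols = counts * vox
    bad = np.flatnonzero((vols < v_min_um3) | (vols > v_max_um3))
    bad = bad[(bad > 0) & (counts[bad] > 0)]
    out = np.where(np.isin(data, bad), 0, data)
    if not out.any():
        raise SegmentationEmptyError("volume filter removed every label")

    fg = out.any(axis=(1, 2))
    z0 = int(np.argmax(fg))
    z1 = int(len(fg) - np.argmax(fg[::-1]))
    out = out[z0:z1]

    relabeled, _, _ = skseg.relabel_sequential(out)
    meta = dict(labels.meta)
    meta["volume_filtered"] = [
        {"label": int(b), "volume_um3": float(vols[b]), "flag": "volume_filtered"}
        for b in bad
    ]
    meta["z_trim"] = (z0, z1)
    return LabelVolume(relabeled.astype(np.int32), labels.spacing_um, meta=meta)


def _surface_areas(data: np.ndarray, spacing: tuple[float, float, float],
                   n_labels: int) -> np.ndarray:
    """Exposed-face surface area per label: faces between a label voxel and
    any differing voxel (or the stack edge), weighted by physical face area."""
    dz, dy, dx = spacing
    face_area = (dy * dx, dz * dx, dz * dy)  # faces normal to z, y, x
    padded = np.pad(data, 1)
    areas = np.zeros(n_labels + 1, dtype=float)
    for ax, fa in enumerate(face_area):
        lo = [slice(1, -1)] * 3
        hi = [slice(1, -1)] * 3
        lo[ax] = slice(0, -1)
        hi[ax] = slice(1, None)
        a, b = padded[tuple(lo)], padded[tuple(hi)]
        diff = a != b
        for side in (a[diff], b[diff]):
            side = side[side > 0]
            if side.size:
                areas += fa * np.bincount(side, minlength=n_labels + 1)
    return areas


def measure_cells(labels: LabelVolume, stack: VoxelStack,
                  provenance: dict | None = None) -> CellTable:
    """Per-cell volume, surface, centroid and per-channel mean intensities."""
    if labels.data.shape != stack.shape:
        raise ValueError(
            f"label volume {labels.data.shape} does not match stack {stack.shape}")
    data = labels.data
    ids = labels.labels
    if ids.size == 0:
        raise SegmentationEmptyError("no labels to measure")
    n_max = int(ids.max())
    dz, dy, dx = labels.spacing_um
    vox = labels.voxel_volume_um3

    counts = np.bincount(data.ravel(), minlength=n_max + 1)
    volumes = counts * vox
    surfaces = _surface_areas(data, labels.spacing_um, n_max)
    centroids = ndi.center_of_mass(np.ones_like(data, dtype=np.uint8), data, ids)
    centroids = np.asarray(centroids, dtype=float) * np.array([dz, dy, dx])

    rows = {
        "label": ids.astype(int),
        "volume_um3": volumes[ids],
        "surface_um2": surfaces[ids],
        "sv_ratio_per_um": surfaces[ids] / volumes[ids],
        "centroid_z_um": centroids[:, 0],
        "centroid_y_um": centroids[:, 1],
        "centroid_x_um": centroids[:, 2],
        "flag": FLAG_KEPT,
    }
    df = pd.DataFrame(rows)
    for name, chan in stack.channels.items():
        df[f"mean_{name}"] = ndi.mean(chan, data, ids)
    return CellTable(df[CELL_COLUMNS + [c for c in df.columns
                                        if c not in CELL_COLUMNS]],
                     provenance=provenance or {})


def remove_outlier_cells(cells: CellTable,
                         fence_k: float = DEFAULT_FENCE_K) -> CellTable:
    """Flag cells whose volume or surface/volume ratio falls outside robust
    median ± fence_k × (scaled MAD) fences.

    With fewer than 4 kept cells the table is returned unchanged.  A
    degenerate (zero) MAD falls back to Tukey 1.5·IQR fences; if the IQR is
    also zero the feature is skipped (homogeneous cells → no removals).
    Flagged rows keep their record but switch flag to ``outlier_volume`` or
    ``outlier_sv``; volume outliers take precedence when both apply.
    """
    df = cells.df.copy()
    kept = df["flag"] == FLAG_KEPT
    if kept.sum() < 4:
        return CellTable(df, provenance=dict(cells.provenance))

    def fences(values: np.ndarray) -> tuple[float, float] | None:
        med = float(np.median(values))
        mad = 1.4826 * float(np.median(np.abs(values - med)))
        if mad > 0:
            return med - fence_k * mad, med + fence_k * mad
        q1, q3 = np.percentile(values, [25, 75])
        iqr = q3 - q1
        if iqr > 0:
            return q1 - 1.5 * iqr, q3 + 1.5 * iqr
        return None

    for feature, flag in (("volume_um3", FLAG_OUTLIER_VOLUME),
                          ("sv_ratio_per_um", FLAG_OUTLIER_SV)):
        vals = df.loc[kept, feature].to_numpy(dtype=float)
        f = fences(vals)
        if f is None:
            continue
        lo, hi = f
        out = kept & ((df[feature] < lo) | (df[feature] > hi))
        df.loc[out, "flag"] = flag
        kept = df["flag"] == FLAG_KEPT

    prov = dict(cells.provenance)
    prov["fence_k"] = fence_k
    return CellTable(df, provenance=prov)
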