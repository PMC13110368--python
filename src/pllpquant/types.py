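"""Core data containers shared by every stage of the pipeline.

Conventions, used everywhere without exception:

* axis order is ``(z, y, x)``, indices are 0-based, crop intervals half-open;
* all physical quantities are micrometres (µm), volumes µm³, surfaces µm²;
* intensities live on a nominal ``[0, 1]`` scale before noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class VoxelStack:
    """A multi-channel 3D intensity grid with physical voxel spacing.

    ``channels`` maps channel name -> float array of shape (nz, ny, nx);
    all channels share one shape.  ``spacing_um`` is (dz, dy, dx).
    """

    channels: dict[str, np.ndarray]
    spacing_um: tuple[float, float, float]
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("VoxelStack needs at least one channel")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"non-positive voxel spacing {self.spacing_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not in stack (have {sorted(self.channels)})"
            ) from None

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing_um
        return dz * dy * dx


@dataclass
class LabelVolume:
    """Integer-labelled 3D segmentation; 0 is background, labels start at 1."""

    data: np.ndarray
    spacing_um: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("LabelVolume must be 3D")
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"non-positive voxel spacing {self.spacing_um}")

    @property
    def labels(self) -> np.ndarray:
        """Sorted nonzero label ids present in the volume."""
        ids = np.unique(self.data)
        return ids[ids > 0]

    @property
    def n_labels(self) -> int:
        return int(self.labels.size)

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing_um
        return dz * dy * dx

    def volumes_um3(self) -> dict[int, float]:
        counts = np.bincount(self.data.ravel())
        vox = self.voxel_volume_um3
        return {int(i): float(c) * vox for i, c in enumerate(counts) if i > 0 and c > 0}


@dataclass
class Mask2D:
    """Binary 2D mask with pixel spacing (dy, dx) in µm."""

    data: np.ndarray
    spacing_um: tuple[float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("Mask2D must be 2D")
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"non-positive pixel spacing {self.spacing_um}")

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    @property
    def pixel_area_um2(self) -> float:
        return self.spacing_um[0] * self.spacing_um[1]


@dataclass(frozen=True)
class EllipseFit:
    """Second-moment ellipse of a 2D mask, physical units.

    ``angle_deg`` is the angle of the long axis against the +x (horizontal)
    image axis, in array coordinates (y grows downward), folded to (−90, 90].
    """

    centroid_um: tuple[float, float]  # (y, x)
    major_axis_um: float
    minor_axis_um: float
    angle_deg: float

    def __post_init__(self) -> None:
        if not (self.major_axis_um >= self.minor_axis_um > 0):
            raise ValueError("ellipse axes must satisfy major >= minor > 0")

    @property
    def aspect_ratio(self) -> float:
        return self.major_axis_um / self.minor_axis_um


# flag states a cell can carry; exactly one per record
FLAG_KEPT = "kept"
FLAG_OUTLIER_VOLUME = "outlier_volume"
FLAG_OUTLIER_SV = "outlier_sv"
FLAG_VOLUME_FILTERED = "volume_filtered"

CELL_COLUMNS = ["label", "volume_um3", "surface_um2", "sv_ratio_per_um",
                "centroid_z_um", "centroid_y_um", "centroid_x_um", "flag"]


@dataclass
class CellTable:
    """Per-cell 3D measurements (one row per segmented cell).

    ``df`` carries at least :data:`CELL_COLUMNS`; per-channel mean
    intensities appear as ``mean_<channel>`` columns.  ``provenance``
    records stack id and the parameter hash of the run that produced it.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CELL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"CellTable missing columns {missing}")
        if self.df["label"].duplicated().any():
            raise ValueError("CellTable labels must be unique")

    @property
    def kept(self) -> pd.DataFrame:
        return self.df[self.df["flag"] == FLAG_KEPT]

    @property
    def n_kept(self) -> int:
        return int((self.df["flag"] == FLAG_KEPT).sum())

    @property
    def total_kept_volume_um3(self) -> float:
        return float(self.kept["volume_um3"].sum())


@dataclass
class RosetteDetection:
    """One rosette candidate on the 2D projection."""

    center_um: tuple[float, float]  # (y, x)
    radius_um: float
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


@dataclass
class PrimordiumSummary:
    """One embryo's morphometric readout."""

    cell_count: int
    total_volume_um3: float
    aspect_ratio: Optional[float] = None
    circularity: Optional[float] = None
    roundness: Optional[float] = None
    solidity: Optional[float] = None
    n_rosette_detections: int = 0
    rosettiness: Optional[float] = None
    diving: Optional[bool] = None


@dataclass
class DepositionPattern:
    """Neuromast cluster positions along the AP axis, ganglion at 0."""

    positions_um: list[float]
    n_neuromasts: int

    def __post_init__(self) -> None:
        if not self.positions_um or self.positions_um[0] != 0.0:
            raise ValueError("first normalized position must be 0")
        if any(b < a for a, b in zip(self.positions_um, self.positions_um[1:])):
            raise ValueError("positions must be non-decreasing")


@dataclass
class ProfileCurve:
    """Intensity line profile: per-channel values over relative distance.

    Each channel is normalized to its own maximum along the profile,
    so values lie in [0, 1] with max exactly 1.
    """

    relative_distance: np.ndarray
    values: dict[str, np.ndarray]
    width_px: int

    def __post_init__(self) -> None:
        d = np.asarray(self.relative_distance, dtype=float)
        if d.ndim != 1 or d.size < 2 or np.any(np.diff(d) <= 0):
            raise ValueError("relative_distance must be strictly increasing")
        self.relative_distance = d


@dataclass(frozen=True)
class TestResult:
    """Two-tailed Mann–Whitney result."""

    statistic_U: float
    p_two_tailed: float
    n_x: int
    n_y: int
    method: str  # "exact" | "normal_approx_tie_corrected"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_two_tailed <= 1.0:
            raise ValueError("p outside [0, 1]")
        if not 0.0 <= self.statistic_U <= self.n_x * self.n_y:
            raise ValueError("U outside [0, n_x*n_y]")


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float
    sem: float
    dispersion_mode: str = "SD"  # or "SEM"
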