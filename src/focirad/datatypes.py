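"""Core in-memory containers shared across modules.

Conventions
-----------
* Voxel grids are indexed ``(z, y, x)``, 0-based; bounding boxes are
  half-open slices in the same order.
* Physical confocal quantities are in micrometres (µm), SMLM coordinates in
  nanometres (nm), time post-irradiation in minutes, dose in gray (Gy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHANNEL_ROLES = ("gH2AX", "p53BP1", "chromatin")
FOCUS_CHANNELS = ("gH2AX", "p53BP1")


@dataclass
class ConfocalStack:
    """Multi-channel 3D intensity grid with physical voxel sizes.

    Parameters
    ----------
    channels:
        Mapping from channel role (``gH2AX``, ``p53BP1``, ``chromatin``) to a
        3D ``(z, y, x)`` array of non-negative intensities.
    voxel_size_um:
        ``(dz, dy, dx)`` in µm.
    meta:
        Free-form acquisition metadata (dose_gy, t_pi_min, treatment, ...).
    """

    channels: dict[str, np.ndarray]
    voxel_size_um: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("stack needs at least one channel")
        shapes = {c: a.shape for c, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for role in self.channels:
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be three positive numbers (dz, dy, dx)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def require(self, role: str) -> np.ndarray:
        if role not in self.channels:
            raise KeyError(
                f"stack is missing the {role!r} channel; present: {sorted(self.channels)}"
            )
        return self.channels[role]

    def rescaled(self, factor: float) -> "ConfocalStack":
        """Return a copy with every channel multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValueError("rescale factor must be positive")
        return ConfocalStack(
            {c: a * factor for c, a in self.channels.items()},
            self.voxel_size_um,
            dict(self.meta),
        )


@dataclass
class NucleusLabelMap:
    """Labeled nucleus voxel grid plus tight per-label bounding boxes."""

    labels: np.ndarray  # int array, 0 = background
    bboxes: dict[int, tuple[slice, slice, slice]]

    @property
    def ids(self) -> list[int]:
        return sorted(self.bboxes)

    def mask(self, nucleus_id: int) -> np.ndarray:
        if nucleus_id not in self.bboxes:
            raise KeyError(f"nucleus id {nucleus_id} not present")
        return self.labels == nucleus_id


@dataclass
class FocusCandidate:
    """A connected 3D region proposed by the MSER detector (pre-classifier)."""

    voxels: np.ndarray  # (n, 3) int array of (z, y, x) indices, absolute
    centroid_um: tuple[float, float, float]  # (z, y, x)
    volume_voxels: int
    area_pixels: int  # max-projection footprint size
    mean_intensity: float
    stability: float  # MSER variation score (lower = more stable)
    channel: str
    nucleus_id: int


@dataclass
class FocusCall(FocusCandidate):
    """A candidate with a classifier decision attached."""

    margin: float = 0.0
    accepted: bool = False


@dataclass
class DsbCall:
    """One colocalized γH2AX/53BP1 pair scored as a double-strand break."""

    gh2ax_index: int
    p53bp1_index: int
    distance_um: float
    overlap_fraction: float  # |intersection| / min(volumes)


@dataclass
class LocalizationSet:
    """SMLM point table inside a rectangular window.

    ``x_nm``/``y_nm`` are localization coordinates, ``frame`` the camera frame
    of the blink, ``precision_nm`` the localization precision. The window is
    ``(width, height)`` in nm, half-open, origin at (0, 0).
    """

    x_nm: np.ndarray
    y_nm: np.ndarray
    frame: np.ndarray
    precision_nm: np.ndarray
    window_nm: tuple[float, float]

    def __post_init__(self) -> None:
        n = len(self.x_nm)
        for name in ("y_nm", "frame", "precision_nm"):
            if len(getattr(self, name)) != n:
                raise ValueError("localization columns have unequal lengths")
        w, h = self.window_nm
        if w <= 0 or h <= 0:
            raise ValueError("window must have positive width and height")
        if n and (np.any(self.precision_nm <= 0)):
            raise ValueError("localization precisions must be positive")
        if n and (
            np.any(self.x_nm < 0)
            or np.any(self.x_nm >= w)
            or np.any(self.y_nm < 0)
            or np.any(self.y_nm >= h)
        ):
            raise ValueError("localizations must lie inside the window")

    def __len__(self) -> int:
        return len(self.x_nm)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x_nm, self.y_nm])

    @property
    def area_nm2(self) -> float:
        return float(self.window_nm[0]) * float(self.window_nm[1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_nm": self.x_nm,
                "y_nm": self.y_nm,
                "frame": self.frame.astype(int),
                "precision_nm": self.precision_nm,
            }
        )


COUNT_COLUMNS = [
    "nucleus_id",
    "cell_line",
    "dose_gy",
    "t_pi_min",
    "treatment",
    "dsb_count",
    "focus_areas_px",
]


def make_count_record(
    nucleus_id,
    dsb_count: int,
    focus_areas_px: list,
    *,
    cell_line: str = "U87",
    dose_gy: float = 0.0,
    t_pi_min: float = 0.0,
    treatment: str = "none",
) -> dict:
    """Build one per-nucleus count record (the row type of kinetics stats)."""
    if dsb_count < 0:
        raise ValueError("dsb_count must be non-negative")
    return {
        "nucleus_id": nucleus_id,
        "cell_line": cell_line,
        "dose_gy": float(dose_gy),
        "t_pi_min": float(t_pi_min),
        "treatment": treatment,
        "dsb_count": int(dsb_count),
        "focus_areas_px": list(focus_areas_px),
    }
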