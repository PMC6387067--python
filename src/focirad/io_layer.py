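"""Readers and writers for on-disk artifacts.

Formats
-------
* Confocal stacks: one multi-page TIFF per channel (plane order z-major,
  16-bit) plus a sidecar JSON recording voxel sizes, the channel-role ->
  file mapping and acquisition metadata.
* Localization tables: CSV with mandatory header
  ``x_nm,y_nm,frame,precision_nm`` (extra columns preserved on read).
* Count records: CSV with ``focus_areas_px`` serialized as a
  semicolon-joined list.

All readers validate before returning; round trips are lossless (16-bit
intensities bit-identical, localization coordinates to 1e-6 nm).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from focirad.datatypes import CHANNEL_ROLES, ConfocalStack, LocalizationSet

SIDECAR_SUFFIX = ".json"
LOC_COLUMNS = ["x_nm", "y_nm", "frame", "precision_nm"]


# ---------------------------------------------------------------------------
# Confocal stacks
# ---------------------------------------------------------------------------

def write_stack(stack: ConfocalStack, base_path) -> Path:
    """Write a stack as per-channel TIFFs plus a sidecar JSON.

    ``base_path`` is the sidecar path without extension; returns the sidecar
    path (``<base>.json``; channel files are ``<base>_<role>.tif``).
    """
    base = Path(base_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    files = {}
    for role, arr in stack.channels.items():
        path = base.with_name(f"{base.name}_{role}.tif")
        tifffile.imwrite(path, np.asarray(arr, dtype=np.uint16))
        files[role] = path.name
    sidecar = base.with_suffix(SIDECAR_SUFFIX)
    payload = {
        "voxel_size_um": list(stack.voxel_size_um),
        "channels": files,
        "meta": {
            k: (v.item() if isinstance(v, np.generic) else v)
            for k, v in stack.meta.items()
        },
    }
    sidecar.write_text(json.dumps(payload, indent=2))
    return sidecar


def read_stack(sidecar_path) -> ConfocalStack:
    """Read a stack bundle back from its sidecar JSON."""
    sidecar = Path(sidecar_path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"sidecar {sidecar} not found; pass the JSON written by write_stack "
            "(channel TIFFs alone are not self-describing)"
        )
    payload = json.loads(sidecar.read_text())
    voxel = tuple(float(v) for v in payload["voxel_size_um"])
    if len(voxel) != 3 or any(v <= 0 for v in voxel):
        raise ValueError(f"invalid voxel sizes in {sidecar}: {voxel}")
    channels = {}
    for role, fname in payload["channels"].items():
        if role not in CHANNEL_ROLES:
            raise ValueError(f"unknown channel role {role!r} in {sidecar}")
        path = sidecar.with_name(fname)
        if not path.exists():
            raise FileNotFoundError(f"channel file {path} referenced by {sidecar} is missing")
        channels[role] = tifffile.imread(path)
    shapes = {r: a.shape for r, a in channels.items()}
    if len(set(shapes.values())) > 1:
        raise ValueError(f"channel shape mismatch in {sidecar}: {shapes}")
    return ConfocalStack(channels, voxel, meta=dict(payload.get("meta", {})))


# ---------------------------------------------------------------------------
# Localization tables
# ---------------------------------------------------------------------------

def write_locs(locs: LocalizationSet, path) -> Path:
    """Write a localization set as CSV (window recorded in a header comment)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# window_nm={locs.window_nm[0]:.6f}x{locs.window_nm[1]:.6f}\n")
        locs.to_frame().to_csv(fh, index=False, float_format="%.6f")
    return path


def read_locs(path, window_nm: tuple[float, float] | None = None) -> LocalizationSet:
    """Read and validate a localization CSV.

    The window is taken from the ``# window_nm=WxH`` comment if present,
    else from ``window_nm``, else from the data extent. Malformed rows are
    rejected with their (1-based, data) row numbers.
    """
    path = Path(path)
    header_window = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# window_nm="):
        w, h = first.strip().removeprefix("# window_nm=").split("x")
        header_window = (float(w), float(h))
    df = pd.read_csv(path, comment="#")
    missing = [c for c in LOC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    numeric = df[LOC_COLUMNS].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) | ~np.isfinite(numeric).all(axis=1)
    if bad.any():
        rows = [int(i) + 1 for i in np.nonzero(bad.to_numpy())[0][:10]]
        raise ValueError(f"{path}: malformed row(s) at data line(s) {rows}")
    frame = numeric["frame"].to_numpy()
    if np.any(frame < 0) or np.any(frame != np.round(frame)):
        rows = [int(i) + 1 for i in np.nonzero((frame < 0) | (frame != np.round(frame)))[0][:10]]
        raise ValueError(f"{path}: frame must be a non-negative integer (row(s) {rows})")
    window = header_window or window_nm
    if window is None:
        window = (
            float(numeric["x_nm"].max()) + 1.0,
            float(numeric["y_nm"].max()) + 1.0,
        )
    return LocalizationSet(
        numeric["x_nm"].to_numpy(),
        numeric["y_nm"].to_numpy(),
        frame.astype(int),
        numeric["precision_nm"].to_numpy(),
        window,
    )


# ---------------------------------------------------------------------------
# Count-record tables
# ---------------------------------------------------------------------------

def write_counts(records: pd.DataFrame, path) -> Path:
    """Write count records as CSV; focus areas join with ';'."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = records.copy()
    if "focus_areas_px" in out.columns:
        out["focus_areas_px"] = out["focus_areas_px"].map(
            lambda v: ";".join(str(int(a)) for a in v) if isinstance(v, (list, tuple, np.ndarray)) else v
        )
    out.to_csv(path, index=False)
    return path


def read_counts(path) -> pd.DataFrame:
    """Read a count-record CSV, decoding the focus-area lists."""
    df = pd.read_csv(path)
    required = {"nucleus_id", "t_pi_min", "dsb_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    if "focus_areas_px" in df.columns:
        df["focus_areas_px"] = df["focus_areas_px"].map(
            lambda v: [int(x) for x in str(v).split(";") if x not in ("", "nan")]
            if pd.notna(v)
            else []
        )
    return df
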