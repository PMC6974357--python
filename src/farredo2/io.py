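"""File I/O: spectral cubes, image maps, optode frames and calibration models.

Cubes travel as multi-page TIFF (one page per band) with an ENVI-style
plain-text sidecar header (``<stem>.hdr``) listing the band-center
wavelengths in nm. Optode frame series are directories of TIFF/PNG files
plus a CSV manifest (filename, t_minutes, light_state). Calibration models
are JSON; scalar maps go out as 32-bit float TIFF and optionally CSV.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .types import CalibrationModel, O2Image, RGBFrame, ScalarImage, SpectralCube

__all__ = [
    "save_cube",
    "load_cube",
    "save_scalar_tiff",
    "load_scalar_tiff",
    "save_rgb_png",
    "save_frames",
    "load_frames",
    "save_calibration",
    "load_calibration",
    "load_roi_masks",
    "save_o2_series",
    "load_o2_series",
]


def _hdr_path(tif_path: Path) -> Path:
    return tif_path.with_suffix(".hdr")


def save_cube(path, cube: SpectralCube) -> None:
    """Write a cube as multi-page TIFF plus an ENVI-style wavelength header."""
    path = Path(path)
    tifffile.imwrite(path, cube.data.astype(np.float32), photometric="minisblack")
    wl = ", ".join(f"{w:g}" for w in cube.wavelengths)
    _hdr_path(path).write_text(
        "ENVI\n"
        f"bands = {cube.n_bands}\n"
        f"kind = {cube.kind}\n"
        "wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
    )


def load_cube(path, kind: str | None = None) -> SpectralCube:
    """Read a multi-page TIFF cube and its wavelength sidecar header.

    Validates that the header lists exactly one wavelength per TIFF page.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    text = _hdr_path(path).read_text()
    m = re.search(r"wavelength\s*=\s*\{([^}]*)\}", text, flags=re.S)
    if not m:
        raise ValueError(f"no wavelength list in header {_hdr_path(path)}")
    wl = np.array([float(tok) for tok in re.split(r"[,\s]+", m.group(1).strip()) if tok])
    if len(wl) != data.shape[0]:
        raise ValueError(
            f"header lists {len(wl)} wavelengths but TIFF has {data.shape[0]} pages"
        )
    if kind is None:
        km = re.search(r"^kind\s*=\s*(\w+)", text, flags=re.M)
        kind = km.group(1) if km else "raw"
    return SpectralCube(wl, data, kind=kind)


def save_scalar_tiff(path, img, csv: bool = False) -> None:
    """Scalar map as float32 TIFF (NaN = masked); optional CSV alongside."""
    path = Path(path)
    data = img.data if isinstance(img, (ScalarImage, O2Image)) else np.asarray(img)
    tifffile.imwrite(path, data.astype(np.float32))
    if csv:
        pd.DataFrame(data).to_csv(path.with_suffix(".csv"), index=False, header=False)


def load_scalar_tiff(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(float)


def save_rgb_png(path, frame: RGBFrame) -> None:
    """8-bit PNG of a display composite (channels assumed in [0, 1])."""
    arr = np.clip(frame.stack(), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255).round().astype(np.uint8))


def save_frames(outdir, frames: list[RGBFrame], fmt: str = "tiff") -> Path:
    """Write optode frames plus a manifest CSV; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, f in enumerate(frames):
        name = f"frame_{k:04d}.{ 'tif' if fmt == 'tiff' else 'png'}"
        arr = f.stack()
        if fmt == "tiff":
            tifffile.imwrite(outdir / name, arr.astype(np.float32), photometric="rgb")
        else:
            iio.imwrite(outdir / name, np.clip(arr, 0, 255).astype(np.uint8))
        rows.append({"filename": name, "t_minutes": f.t, "light_state": f.light})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_frames(manifest_path) -> list[RGBFrame]:
    """Load an optode frame series from its manifest CSV."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"filename", "t_minutes", "light_state"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    frames = []
    for _, row in df.iterrows():
        p = manifest_path.parent / str(row["filename"])
        arr = tifffile.imread(p) if p.suffix.lower() in (".tif", ".tiff") else iio.imread(p)
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 3 or arr.shape[-1] < 3:
            raise ValueError(f"{p} is not a 3-channel image")
        frames.append(
            RGBFrame(arr[..., 0], arr[..., 1], arr[..., 2],
                     t=float(row["t_minutes"]), light=str(row["light_state"]))
        )
    frames.sort(key=lambda f: f.t)
    return frames


def save_calibration(path, model: CalibrationModel) -> None:
    Path(path).write_text(
        json.dumps({"a": model.a, "b": model.b, "rss": model.rss, "n": model.n}, indent=2)
    )


def load_calibration(path) -> CalibrationModel:
    d = json.loads(Path(path).read_text())
    return CalibrationModel(a=d["a"], b=d["b"], rss=d.get("rss", 0.0), n=d.get("n", 0))


def load_roi_masks(path) -> list[np.ndarray]:
    """Boolean ROI masks from a labeled image (0 = background)."""
    p = Path(path)
    arr = tifffile.imread(p) if p.suffix.lower() in (".tif", ".tiff") else iio.imread(p)
    if arr.ndim == 3:
        arr = arr[..., 0]
    labels = sorted(int(v) for v in np.unique(arr) if v != 0)
    if not labels:
        raise ValueError(f"no labeled ROIs in {path}")
    return [arr == lab for lab in labels]


def save_o2_series(outdir, images: list[O2Image]) -> Path:
    """Write calibrated O2 images (float32 TIFF) plus a manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, img in enumerate(images):
        name = f"o2_{k:04d}.tif"
        data = img.data.copy()
        data[img.mask] = np.nan
        tifffile.imwrite(outdir / name, data.astype(np.float32))
        rows.append({"filename": name, "t_minutes": img.t, "light_state": img.light})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_o2_series(manifest_path) -> list[O2Image]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    images = []
    for _, row in df.iterrows():
        data = tifffile.imread(manifest_path.parent / str(row["filename"])).astype(float)
        images.append(
            O2Image(data, mask=~np.isfinite(data),
                    t=float(row["t_minutes"]), light=str(row["light_state"]))
        )
    images.sort(key=lambda f: f.t)
    return images
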