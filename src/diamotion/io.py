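"""Readers and writers for cine clips, contour annotations and results.

Physical calibration is mandatory everywhere: a clip without pixel spacing
is rejected, never guessed, because every reported quantity is in cm/mm/cm².
Contour JSON stores physical (cm) coordinates so annotations survive image
resampling.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
import tifffile
import yaml

from .geometry import Contour
from .measurement import CineClip

__all__ = [
    "read_cine",
    "write_cine",
    "read_contours",
    "write_contours",
    "write_results",
    "write_manifest",
]

_STACK_EXTENSIONS = (".tif", ".tiff", ".png")


def _to_unit_scale(frames: np.ndarray) -> np.ndarray:
    """Common intensity scale: integer dtypes normalized by their max."""
    if np.issubdtype(frames.dtype, np.integer):
        return frames.astype(np.float32) / np.iinfo(frames.dtype).max
    return frames.astype(np.float32)


def _read_sidecar(path: Path) -> tuple[tuple[float, float], float]:
    if not path.exists():
        raise ValueError(
            f"missing sidecar {path.name}: pixel spacing is required and is "
            "never guessed"
        )
    meta = yaml.safe_load(path.read_text())
    try:
        spacing = tuple(float(v) for v in meta["spacing_cm_per_px"])
        period = float(meta["frame_period_s"])
    except (KeyError, TypeError) as exc:
        raise ValueError(
            f"sidecar {path.name} must define spacing_cm_per_px "
            "[depth, lateral] and frame_period_s"
        ) from exc
    if len(spacing) != 2:
        raise ValueError("spacing_cm_per_px must be a [depth, lateral] pair")
    return spacing, period


def _read_dicom(path: Path) -> CineClip:
    ds = pydicom.dcmread(str(path))
    frames = ds.pixel_array
    if frames.ndim == 2:
        raise ValueError("DICOM file holds a single frame, not a cine loop")

    spacing = None
    # ultrasound regions carry PhysicalDeltaX/Y in cm (preferred)
    regions = getattr(ds, "SequenceOfUltrasoundRegions", None)
    if regions:
        r = regions[0]
        dx, dy = abs(float(r.PhysicalDeltaX)), abs(float(r.PhysicalDeltaY))
        spacing = (dy, dx)
    elif getattr(ds, "PixelSpacing", None):
        row_mm, col_mm = (float(v) for v in ds.PixelSpacing)
        spacing = (row_mm / 10.0, col_mm / 10.0)  # mm -> cm
    if spacing is None:
        raise ValueError(
            f"{path.name}: no pixel spacing metadata (PhysicalDeltaX/Y or "
            "PixelSpacing); physical calibration is required"
        )

    if getattr(ds, "FrameTime", None):
        period = float(ds.FrameTime) / 1000.0
    elif getattr(ds, "CineRate", None):
        period = 1.0 / float(ds.CineRate)
    else:
        period = 1.0
    return CineClip(frames=_to_unit_scale(frames), spacing=spacing,
                    frame_period=period)


def _read_stack_dir(path: Path) -> CineClip:
    import imageio.v3 as iio

    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in _STACK_EXTENSIONS
    )
    if not files:
        raise ValueError(f"no image frames found in {path}")
    spacing, period = _read_sidecar(path / "meta.yaml")
    frames = []
    for i, f in enumerate(files):
        try:
            frames.append(np.asarray(iio.imread(f)))
        except Exception as exc:
            raise ValueError(f"corrupt frame {i} ({f.name}): {exc}") from exc
    shapes = {fr.shape for fr in frames}
    if len(shapes) != 1:
        raise ValueError(f"mixed frame shapes in stack: {sorted(shapes)}")
    return CineClip(frames=_to_unit_scale(np.stack(frames)), spacing=spacing,
                    frame_period=period)


def _read_tiff_stack(path: Path) -> CineClip:
    frames = tifffile.imread(str(path))
    if frames.ndim == 2:
        raise ValueError(f"{path.name} holds a single frame, not a cine loop")
    spacing, period = _read_sidecar(path.with_suffix(".yaml"))
    return CineClip(frames=_to_unit_scale(frames), spacing=spacing,
                    frame_period=period)


def read_cine(path: str | Path) -> CineClip:
    """Read a cine loop from multi-frame DICOM, a multi-page TIFF with a YAML
    sidecar, or a directory of TIFF/PNG frames with a ``meta.yaml`` sidecar.

    The sidecar schema is ``spacing_cm_per_px: [depth, lateral]`` and
    ``frame_period_s``.  Missing spacing metadata and mixed frame shapes are
    rejected; a corrupt frame is reported with its index.
    """
    path = Path(path)
    if path.is_dir():
        return _read_stack_dir(path)
    if path.suffix.lower() in (".dcm", ".dicom") or path.suffix == "":
        return _read_dicom(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _read_tiff_stack(path)
    raise ValueError(f"unsupported cine format: {path.suffix!r}")


def write_cine(clip: CineClip, path: str | Path) -> Path:
    """Write a clip as multi-page TIFF plus YAML sidecar; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = np.clip(clip.frames, 0.0, None)
    peak = frames.max() or 1.0
    tifffile.imwrite(
        str(path), (frames / peak * 65535).astype(np.uint16)
    )
    sidecar = {
        "spacing_cm_per_px": [float(s) for s in clip.spacing],
        "frame_period_s": float(clip.frame_period),
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))
    return path


def write_contours(contours: list[Contour], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "units": "cm",
        "contours": [
            {
                "frame_index": int(c.frame_index),
                "points": np.round(c.points, 6).tolist(),
                "extrapolated": np.asarray(c.extrapolated, dtype=bool).tolist(),
            }
            for c in contours
        ],
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_contours(path: str | Path) -> list[Contour]:
    payload = json.loads(Path(path).read_text())
    if payload.get("units", "cm") != "cm":
        raise ValueError("contour files must be in cm")
    out = []
    for entry in payload["contours"]:
        out.append(
            Contour(
                points=np.asarray(entry["points"], dtype=float),
                frame_index=int(entry["frame_index"]),
                extrapolated=np.asarray(
                    entry.get("extrapolated", []), dtype=bool
                ) if entry.get("extrapolated") else None,
            )
        )
    return out


def write_results(rows: list[dict], path: str | Path) -> Path:
    """One CSV row per (clip, method): clip_id, method, value, units,
    frame_max, frame_min."""
    import pandas as pd

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ["clip_id", "method", "value", "units", "frame_max", "frame_min"]
    pd.DataFrame(rows).reindex(columns=cols).to_csv(path, index=False)
    return path


def write_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return path
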