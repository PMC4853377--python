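"""Readers and writers: NIfTI volumes, TIFF/PNG slice directories, sidecars.

Slice directories hold equally-sized 2D images whose order follows
zero-padded numeric filename order, plus a YAML sidecar ``spacing.yaml`` with
``spacing_mm: [sx, sy, sz]``.  Spacing is never guessed: a missing sidecar or
NIfTI header is a hard error.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional, Tuple, Union

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import tifffile
import yaml

from .geometry import Image2D, ImageVolume, LabelVolume, SectionStack

__all__ = [
    "read_volume",
    "read_label_volume",
    "write_volume",
    "write_label_volume",
    "read_stack",
    "write_stack",
    "read_landmarks",
    "write_landmarks",
]

_SIDECAR = "spacing.yaml"
_IMG_EXT = {".tif", ".tiff", ".png"}


def _nifti_to_array(path: Path) -> Tuple[np.ndarray, tuple]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: NIfTI header carries no usable voxel spacing")
    data = np.asanyarray(img.dataobj)
    # NIfTI arrays are indexed (x, y, z); internal layout is (z, y, x).
    return np.transpose(data, (2, 1, 0)), tuple(float(z) for z in zooms)


def _read_slice_dir(path: Path) -> Tuple[np.ndarray, tuple]:
    sidecar = path / _SIDECAR
    if not sidecar.exists():
        raise FileNotFoundError(
            f"{path}: missing {_SIDECAR} sidecar with 'spacing_mm: [sx, sy, sz]'; spacing is never guessed"
        )
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    if not meta or "spacing_mm" not in meta:
        raise ValueError(f"{sidecar}: sidecar must define 'spacing_mm'")
    spacing = tuple(float(v) for v in meta["spacing_mm"])
    if len(spacing) != 3:
        raise ValueError(f"{sidecar}: 'spacing_mm' must have three components")

    files = sorted(
        (p for p in path.iterdir() if p.suffix.lower() in _IMG_EXT),
        key=lambda p: (_numeric_key(p.stem), p.name),
    )
    if not files:
        raise FileNotFoundError(f"{path}: no TIFF/PNG slices found")
    slices = []
    for p in files:
        arr = tifffile.imread(p) if p.suffix.lower() in (".tif", ".tiff") else iio.imread(p)
        if slices and arr.shape != slices[0].shape:
            raise ValueError(f"{p.name}: slice shape {arr.shape} deviates from {slices[0].shape}")
        slices.append(np.asarray(arr))
    return np.stack(slices, axis=0), spacing


def _numeric_key(stem: str) -> int:
    m = re.search(r"(\d+)", stem)
    return int(m.group(1)) if m else -1


def read_volume(
    path: Union[str, Path], labels_path: Optional[Union[str, Path]] = None
) -> Tuple[ImageVolume, Optional[LabelVolume]]:
    """Read an intensity volume (NIfTI file or slice directory), optionally with labels."""
    path = Path(path)
    if path.is_dir():
        data, spacing = _read_slice_dir(path)
    else:
        data, spacing = _nifti_to_array(path)
    vol = ImageVolume(data, spacing)
    labels = read_label_volume(labels_path) if labels_path is not None else None
    if labels is not None and labels.shape_xyz != vol.shape_xyz:
        raise ValueError("label volume geometry does not match the intensity volume")
    return vol, labels


def read_label_volume(path: Union[str, Path]) -> LabelVolume:
    data, spacing = _nifti_to_array(Path(path))
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded):
            raise ValueError(f"{path}: label volume holds non-integer values")
        data = rounded.astype(np.int32)
    return LabelVolume(data, spacing)


def _write_nifti(data_xyz: np.ndarray, spacing: tuple, path: Path) -> None:
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    img = nib.Nifti1Image(data_xyz, affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def write_volume(volume: ImageVolume, path: Union[str, Path]) -> None:
    _write_nifti(np.transpose(volume.voxels, (2, 1, 0)), volume.spacing, Path(path))


def write_label_volume(labels: LabelVolume, path: Union[str, Path]) -> None:
    _write_nifti(np.transpose(labels.labels, (2, 1, 0)).astype(np.int32), labels.spacing, Path(path))


# ---------------------------------------------------------------------------
# Section stacks
# ---------------------------------------------------------------------------

def write_stack(stack: SectionStack, out_dir: Union[str, Path]) -> None:
    """Write a stack as per-slice TIFFs plus ``stack.yaml`` metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, im in enumerate(stack.slices):
        tifffile.imwrite(out / f"slice_{i:04d}.tif", im.pixels.astype(np.float32))
    meta = {
        "modality": stack.modality,
        "spacing_mm": [stack.spacing[0], stack.spacing[1], stack.sz],
        "indices": [m["index"] for m in stack.meta],
    }
    with open(out / "stack.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
    with open(out / _SIDECAR, "w") as fh:
        yaml.safe_dump({"spacing_mm": meta["spacing_mm"]}, fh)


def read_stack(path: Union[str, Path]) -> SectionStack:
    path = Path(path)
    meta_file = path / "stack.yaml"
    if not meta_file.exists():
        raise FileNotFoundError(f"{path}: missing stack.yaml")
    with open(meta_file) as fh:
        meta = yaml.safe_load(fh)
    spacing = meta["spacing_mm"]
    data, _ = _read_slice_dir(path)
    slices = [Image2D(sl, (spacing[0], spacing[1])) for sl in data]
    stack_meta = [{"index": int(i)} for i in meta.get("indices", range(len(slices)))]
    return SectionStack(slices=slices, modality=meta.get("modality", "unknown"), sz=float(spacing[2]), meta=stack_meta)


def write_landmarks(landmarks: dict, path: Union[str, Path]) -> None:
    """Landmark JSON: list of {slice, pairs: [[xs, ys, xb, yb], ...]} in mm."""
    payload = [{"slice": int(k), "pairs": np.asarray(v, dtype=float).tolist()} for k, v in sorted(landmarks.items())]
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_landmarks(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    out = {}
    for entry in payload:
        pairs = np.asarray(entry["pairs"], dtype=float)
        if pairs.ndim != 2 or pairs.shape[1] != 4 or pairs.shape[0] < 2:
            raise ValueError(f"slice {entry['slice']}: landmarks need >= 2 pairs of [xs, ys, xb, yb]")
        out[int(entry["slice"])] = pairs
    return out
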