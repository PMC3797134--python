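"""Reading and writing of image stacks, schedules, ROI tables and manifests.

Conventions: image stacks are stored as one 3-D volume per animal, NIfTI
(.nii / .nii.gz, written via nibabel) or multi-page TIFF (via tifffile),
float32, with one page/volume per scheduled offset in schedule order
followed by the unsaturated S0 image when the schedule includes one.  Pixel
coordinates are 0-based row/col (row-major); offsets in schedule files are
listed high-to-low (+6 ... -6 ppm) as acquired and normalized on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .params import AcquisitionSchedule
from .spectra import ROI, ImageStack

NIFTI_SUFFIXES = (".nii", ".nii.gz")
TIFF_SUFFIXES = (".tif", ".tiff")


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(NIFTI_SUFFIXES)


def write_schedule(path, schedule: AcquisitionSchedule) -> None:
    """Offset schedule as CSV (columns: index, offset_ppm), schedule order."""
    df = pd.DataFrame({"index": np.arange(len(schedule)),
                       "offset_ppm": schedule.offsets})
    df.to_csv(path, index=False)


def read_schedule(path, includes_s0: bool = True) -> AcquisitionSchedule:
    df = pd.read_csv(path)
    offsets = tuple(float(x) for x in
                    df.sort_values("index")["offset_ppm"].to_numpy())
    return AcquisitionSchedule(offsets=offsets, includes_s0=includes_s0)


def write_stack(path, stack: ImageStack) -> None:
    """Write saturation images plus trailing S0 as float32 NIfTI or TIFF."""
    path = Path(path)
    images = np.concatenate([stack.sat_images,
                             stack.s0_image[None]], axis=0).astype(np.float32)
    if _is_nifti(path):
        affine = np.diag([stack.pixel_size_mm, stack.pixel_size_mm, 1.0, 1.0])
        # NIfTI stores (row, col, image index); transposed back on read
        nib.save(nib.Nifti1Image(np.transpose(images, (1, 2, 0)), affine),
                 str(path))
    elif path.suffix.lower() in TIFF_SUFFIXES:
        tifffile.imwrite(path, images,
                         metadata={"pixel_size_mm": stack.pixel_size_mm})
    else:
        raise ValueError(f"unsupported stack format: {path.name}")


def read_stack(path, schedule: AcquisitionSchedule,
               pixel_size_mm: float | None = None) -> ImageStack:
    """Read a stack written by :func:`write_stack`.

    The image count must equal the schedule length plus one when the
    schedule includes an S0 acquisition (identified as the last image).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    if _is_nifti(path):
        img = nib.load(str(path))
        images = np.transpose(np.asarray(img.dataobj, dtype=np.float64),
                              (2, 0, 1))
        if pixel_size_mm is None:
            pixel_size_mm = float(img.affine[0, 0])
    elif path.suffix.lower() in TIFF_SUFFIXES:
        images = tifffile.imread(path).astype(np.float64)
        if pixel_size_mm is None:
            with tifffile.TiffFile(path) as tf:
                meta = tf.shaped_metadata or ({},)
                pixel_size_mm = float(meta[0].get("pixel_size_mm", 1.0))
    else:
        raise ValueError(f"unsupported stack format: {path.name}")
    expected = len(schedule) + (1 if schedule.includes_s0 else 0)
    if images.shape[0] != expected:
        raise ValueError(
            f"{path.name}: {images.shape[0]} images for a schedule of "
            f"{len(schedule)} offsets"
            + (" plus S0" if schedule.includes_s0 else ""))
    if schedule.includes_s0:
        sat, s0 = images[:-1], images[-1]
    else:
        sat, s0 = images, np.ones_like(images[0])
    return ImageStack(sat_images=sat, s0_image=s0, schedule=schedule,
                      pixel_size_mm=pixel_size_mm)


def write_rois(path, rois: list[ROI]) -> None:
    pd.DataFrame([{"label": r.label, "center_row": r.center_row,
                   "center_col": r.center_col, "area_mm2": r.area_mm2,
                   "animal_id": r.animal_id or "", "group": r.group or ""}
                  for r in rois]).to_csv(path, index=False)


def read_rois(path) -> list[ROI]:
    df = pd.read_csv(path, dtype={"label": str})
    required = {"label", "center_row", "center_col", "area_mm2"}
    if not required.issubset(df.columns):
        raise ValueError(f"ROI file must have columns {sorted(required)}")
    rois = []
    for _, row in df.iterrows():
        rois.append(ROI(label=str(row["label"]),
                        center_row=float(row["center_row"]),
                        center_col=float(row["center_col"]),
                        area_mm2=float(row["area_mm2"]),
                        animal_id=(str(row["animal_id"]) or None)
                        if "animal_id" in df.columns and pd.notna(row.get("animal_id")) else None,
                        group=(str(row["group"]) or None)
                        if "group" in df.columns and pd.notna(row.get("group")) else None))
    return rois


def write_map(path, image: np.ndarray, pixel_size_mm: float = 1.0) -> None:
    """Single 2-D float map as NIfTI or TIFF."""
    path = Path(path)
    data = np.asarray(image, dtype=np.float32)
    if _is_nifti(path):
        affine = np.diag([pixel_size_mm, pixel_size_mm, 1.0, 1.0])
        nib.save(nib.Nifti1Image(data, affine), str(path))
    elif path.suffix.lower() in TIFF_SUFFIXES:
        tifffile.imwrite(path, data)
    else:
        raise ValueError(f"unsupported map format: {path.name}")


def write_manifest(path, animals: list[dict], schedule_path: str) -> None:
    """Cohort manifest: YAML listing stack path, ROI file, animal id, group."""
    payload = {"schedule": str(schedule_path),
               "animals": [{"id": a["id"], "group": a["group"],
                            "stack": str(a["stack"]), "rois": str(a["rois"])}
                           for a in animals]}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_manifest(path) -> dict:
    payload = yaml.safe_load(Path(path).read_text())
    if "animals" not in payload or "schedule" not in payload:
        raise ValueError("manifest must define 'schedule' and 'animals'")
    return payload


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
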