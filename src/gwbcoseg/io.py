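"""Readers/writers for the formats the pipeline touches.

Volumes and label volumes use NIfTI (via nibabel) in the MSD-style layout:
an image volume plus an integer label volume with 0 = background,
1 = pancreas, 2 = tumor.  2-D fixtures use PNG: images on a 0–255 scale,
label maps with raw values {0,1,2}, binary masks binarized at > 0 on read.
Metric tables are tab-separated text; configs and run manifests are YAML.

All writes are atomic (write to a temporary sibling, then rename), so an
interrupted run never leaves a half-written checkpoint or table behind.
The coordinate convention is row-major, origin top-left, 0-based indices,
and is echoed into every manifest.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantom import PhantomCase
from .unet import split_label_map

COORDINATE_CONVENTION = "row-major, origin top-left, 0-based indices"


@dataclass
class CaseRecord:
    case_id: str
    image_path: str
    label_path: str
    split: str | None = None
    provenance: str | None = None


# ---------------------------------------------------------------------------
# atomic write helpers
# ---------------------------------------------------------------------------

def atomic_write_bytes(path: Path, data: bytes) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_text(path: Path, text: str) -> None:
    atomic_write_bytes(path, text.encode())


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def write_volume(path: Path, volume: np.ndarray) -> None:
    """Write a (H, W, L) stack as NIfTI; a 2-D array becomes a single slice."""
    volume = np.asarray(volume)
    if volume.ndim == 2:
        volume = volume[:, :, None]
    img = nib.Nifti1Image(volume.astype(np.float64), affine=np.eye(4))
    tmp = path.with_name(f".{path.name}.tmp.nii")
    nib.save(img, tmp)
    os.replace(tmp, path)


def write_label_volume(path: Path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.ndim == 2:
        labels = labels[:, :, None]
    img = nib.Nifti1Image(labels.astype(np.int16), affine=np.eye(4))
    tmp = path.with_name(f".{path.name}.tmp.nii")
    nib.save(img, tmp)
    os.replace(tmp, path)


def read_volume(path: Path) -> tuple[np.ndarray, dict]:
    """Load a NIfTI volume as a (H, W, L) array plus light metadata.

    Intensities are returned untouched; normalization is a pipeline stage,
    not an I/O concern.  Slices iterate along the last axis (axial order)."""
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:
        raise IOError(f"cannot read NIfTI volume at {path}: {exc}") from exc
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    meta = {"affine": img.affine, "shape": data.shape, "path": str(path)}
    return data, meta


def read_label_volume(path: Path, pancreas_includes_tumor: bool = True
                      ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-slice (pancreas_mask, tumor_mask) pairs from a {0,1,2} label volume."""
    data, _ = read_volume(path)
    return [split_label_map(data[:, :, k].astype(np.int64),
                            pancreas_includes_tumor)
            for k in range(data.shape[2])]


# ---------------------------------------------------------------------------
# PNG fixtures
# ---------------------------------------------------------------------------

def write_image_png(path: Path, image: np.ndarray) -> None:
    """Store a [0,1] image on the 0–255 scale."""
    arr = np.clip(np.asarray(image, float), 0.0, 1.0)
    atomic_write_bytes(path, iio.imwrite("<bytes>", np.round(arr * 255).astype(np.uint8),
                                         extension=".png"))


def read_image_png(path: Path) -> np.ndarray:
    return np.asarray(iio.imread(path), dtype=float) / 255.0


def write_label_png(path: Path, labels: np.ndarray) -> None:
    """Store a {0,1,2} label map with raw values."""
    atomic_write_bytes(path, iio.imwrite("<bytes>", np.asarray(labels).astype(np.uint8),
                                         extension=".png"))


def read_label_png(path: Path) -> np.ndarray:
    return np.asarray(iio.imread(path), dtype=np.uint8)


def read_mask_png(path: Path) -> np.ndarray:
    """Binary mask: any nonzero pixel counts as foreground."""
    return (np.asarray(iio.imread(path)) > 0).astype(np.uint8)


# ---------------------------------------------------------------------------
# dataset export / import
# ---------------------------------------------------------------------------

def export_dataset(cases: list[PhantomCase], outdir: Path,
                   fmt: str = "png", manifest_extra: dict | None = None) -> list[CaseRecord]:
    """Write cases as image + {0,1,2} label pairs (PNG or single-slice NIfTI)
    plus a manifest; returns the records."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for case in cases:
        labels = np.zeros_like(case.pancreas_mask, dtype=np.uint8)
        labels[case.pancreas_mask > 0] = 1
        labels[case.tumor_mask > 0] = 2
        if fmt == "png":
            ipath = outdir / f"{case.case_id}_image.png"
            lpath = outdir / f"{case.case_id}_label.png"
            write_image_png(ipath, case.image)
            write_label_png(lpath, labels)
        elif fmt == "nifti":
            ipath = outdir / f"{case.case_id}_image.nii"
            lpath = outdir / f"{case.case_id}_label.nii"
            write_volume(ipath, case.image)
            write_label_volume(lpath, labels)
        else:
            raise ValueError(f"unknown format {fmt!r}; use 'png' or 'nifti'")
        records.append(CaseRecord(case_id=case.case_id, image_path=ipath.name,
                                  label_path=lpath.name,
                                  provenance=f"synthetic seed {case.seed}"))
    manifest = {
        "cases": [r.__dict__ for r in records],
        "format": fmt,
        **(manifest_extra or {}),
    }
    write_manifest(outdir / "manifest.yaml", manifest)
    return records


def load_dataset(directory: Path) -> list[PhantomCase]:
    """Read a dataset directory written by :func:`export_dataset`."""
    directory = Path(directory)
    manifest = read_manifest(directory / "manifest.yaml")
    fmt = manifest["format"]
    cases = []
    for rec in manifest["cases"]:
        ipath = directory / rec["image_path"]
        lpath = directory / rec["label_path"]
        for p in (ipath, lpath):
            if not p.exists():
                raise FileNotFoundError(f"manifest references missing file {p}")
        if fmt == "png":
            image = read_image_png(ipath)
            labels = read_label_png(lpath)
        else:
            vol, _ = read_volume(ipath)
            image = vol[:, :, 0]
            lvol, _ = read_volume(lpath)
            labels = lvol[:, :, 0].astype(np.int64)
        pancreas, tumor = split_label_map(labels)
        cases.append(PhantomCase(image=image, pancreas_mask=pancreas,
                                 tumor_mask=tumor, case_id=rec["case_id"]))
    return cases


# ---------------------------------------------------------------------------
# manifests and tables
# ---------------------------------------------------------------------------

def _package_version() -> str:
    from . import __version__
    return __version__


def make_run_manifest(seed: int, configs: dict | None = None,
                      extra: dict | None = None) -> dict:
    return {
        "software": "gwbcoseg",
        "version": _package_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "coordinate_convention": COORDINATE_CONVENTION,
        "seed": seed,
        "configs": configs or {},
        **(extra or {}),
    }


def write_manifest(path: Path, manifest: dict) -> None:
    atomic_write_text(Path(path), yaml.safe_dump(manifest, sort_keys=False))


def read_manifest(path: Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_metric_table(df: pd.DataFrame, path: Path) -> None:
    atomic_write_text(Path(path), df.to_csv(sep="\t", index=False))


def write_history_table(history: list[dict], path: Path) -> None:
    write_metric_table(pd.DataFrame(history), path)
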