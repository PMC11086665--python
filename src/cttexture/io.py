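"""Readers and writers for stacks, spectra, and patches.

Stacks can come from TIFF files (multi-page or 3-D), DICOM series (slices
ordered by position along the scan axis), or a plain ``.npy`` array with a
JSON sidecar carrying the pixel spacing.  1-D spectra are stored as
two-column CSV with a comment header recording spacing and normalization.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import DimensionError, InsufficientDataError
from .nps_core import NPS1D, ImageStack
from .nps_synthesis import NoisePatch

__all__ = [
    "read_tiff_stack",
    "write_tiff_stack",
    "read_dicom_series",
    "read_array_stack",
    "write_array_stack",
    "read_nps_csv",
    "write_nps_csv",
    "write_patch_png",
]


def read_tiff_stack(path, pixel_spacing_cm: float) -> ImageStack:
    """Read a multi-page (or 3-D) TIFF as an image stack."""
    import tifffile

    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    return ImageStack(np.asarray(data, dtype=float), pixel_spacing_cm,
                      metadata={"source": str(path)})


def write_tiff_stack(path, stack: ImageStack) -> None:
    import tifffile

    tifffile.imwrite(str(path), stack.data.astype(np.float32))


def read_dicom_series(directory) -> ImageStack:
    """Read a directory of single-frame DICOM slices, ordered by position.

    Slices are sorted by ImagePositionPatient along the slice axis (falling
    back to InstanceNumber); rescale slope/intercept are applied so values
    are in HU.  Pixel spacing is taken from the first slice (mm -> cm).
    """
    import pydicom

    files = sorted(Path(directory).glob("*.dcm")) or sorted(
        p for p in Path(directory).iterdir() if p.is_file())
    if not files:
        raise InsufficientDataError(f"no DICOM files in {directory}")
    datasets = [pydicom.dcmread(str(f)) for f in files]

    def order_key(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=order_key)
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise DimensionError("DICOM slices have inconsistent shapes")
    spacing_mm = float(datasets[0].PixelSpacing[0])
    return ImageStack(np.stack(slices), spacing_mm / 10.0,
                      metadata={"source": str(directory)})


def read_array_stack(path) -> ImageStack:
    """Read a ``.npy`` stack with a ``.json`` sidecar holding the spacing."""
    path = Path(path)
    data = np.load(path)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    return ImageStack(data, float(meta["pixel_spacing_cm"]), metadata=meta)


def write_array_stack(path, stack: ImageStack) -> None:
    path = Path(path)
    np.save(path, stack.data)
    meta = {"pixel_spacing_cm": stack.pixel_spacing_cm, **{
        k: v for k, v in stack.metadata.items()
        if isinstance(v, (int, float, str, bool))}}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def write_nps_csv(path, nps: NPS1D) -> None:
    header = (f"# pixel_spacing_cm={nps.pixel_spacing_cm:g} "
              f"normalized={nps.normalized}\n"
              "frequency_lp_per_cm,value\n")
    lines = [f"{f:.9g},{v:.9g}" for f, v in zip(nps.frequencies, nps.values)]
    Path(path).write_text(header + "\n".join(lines) + "\n")


def read_nps_csv(path) -> NPS1D:
    text = Path(path).read_text().splitlines()
    spacing = None
    normalized = False
    rows = []
    for line in text:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line[1:].split():
                if tok.startswith("pixel_spacing_cm="):
                    spacing = float(tok.split("=", 1)[1])
                elif tok.startswith("normalized="):
                    normalized = tok.split("=", 1)[1] == "True"
            continue
        if line.startswith("frequency"):
            continue
        f, v = line.split(",")
        rows.append((float(f), float(v)))
    arr = np.asarray(rows)
    if spacing is None:
        spacing = 1.0 / (2.0 * arr[-1, 0])
    return NPS1D(arr[:, 0], arr[:, 1], spacing, normalized=normalized)


def write_patch_png(path, patch: NoisePatch) -> None:
    """8-bit PNG export, windowed at level mu and width 10 * SD."""
    import imageio.v3 as iio

    lo = patch.mean_target - 5.0 * patch.sd_target
    hi = patch.mean_target + 5.0 * patch.sd_target
    img = np.clip((patch.values - lo) / (hi - lo), 0.0, 1.0)
    iio.imwrite(str(path), (img * 255).astype(np.uint8))
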