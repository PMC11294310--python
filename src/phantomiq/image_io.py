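"""Image and manifest I/O.

Simulated slices can be exported as 32-bit float TIFF (with the pixel
spacing in the resolution tags and a JSON description) or as DICOM
secondary-capture objects (16-bit signed HU, PixelSpacing set), and any
2D slice in either format can be loaded back for analysis — including
real scanner exports, which makes the edge-metrics chain usable beyond
the simulator.  Sweep provenance is collected in a flat CSV manifest.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pydicom
import tifffile
from pydicom.dataset import FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from .phantom_sim import ImageGrid

__all__ = [
    "save_tiff",
    "load_tiff",
    "save_dicom",
    "load_dicom",
    "load_image",
    "write_manifest",
    "provenance_record",
]


def provenance_record(image: ImageGrid) -> dict:
    """Flatten image provenance into JSON-serialisable scalars."""
    prov = image.provenance
    rec: dict = {"pixel_spacing_mm": image.pixel_spacing, "size_px": image.size}
    phantom = prov.get("phantom")
    if phantom is not None:
        rec.update(
            inner_diameter_mm=phantom.inner_diameter,
            wall_thickness_mm=phantom.wall_thickness,
            iodine_mg_per_ml=phantom.iodine_concentration,
            hu_silicone=phantom.hu_silicone,
            hu_per_mg_iodine=phantom.hu_per_mg_iodine,
        )
    kernel = prov.get("kernel")
    if kernel is not None:
        rec.update(kernel=kernel.name, rho50=kernel.rho50, rho10=kernel.rho10)
    acq = prov.get("acquisition")
    if acq is not None:
        rec.update(ctdi_mgy=acq.ctdi, qir_level=acq.qir_level, kev=acq.keV_label)
    if "seed" in prov:
        rec["seed"] = prov["seed"]
    if "noise_sd_target" in prov:
        rec["noise_sd_target_hu"] = prov["noise_sd_target"]
    return rec


def save_tiff(image: ImageGrid, path: str | Path) -> None:
    """Write a slice as 32-bit float TIFF with spacing and provenance."""
    description = json.dumps(provenance_record(image))
    px_per_cm = 10.0 / image.pixel_spacing
    tifffile.imwrite(
        path,
        image.values.astype(np.float32),
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        description=description,
    )


def load_tiff(path: str | Path) -> ImageGrid:
    """Load a 2D TIFF; pixel spacing from the description or resolution tags."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        spacing = None
        desc = page.tags.get("ImageDescription")
        if desc is not None:
            try:
                spacing = float(json.loads(desc.value).get("pixel_spacing_mm"))
            except (ValueError, TypeError, json.JSONDecodeError):
                spacing = None
        if spacing is None:
            xres = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if xres is None:
                raise ValueError(f"{path}: no pixel spacing information found")
            num, den = xres.value
            px_per_unit = num / den
            unit_mm = {2: 25.4, 3: 10.0}.get(getattr(unit.value, "value", unit.value) if unit else 3, 10.0)
            spacing = unit_mm / px_per_unit
    return ImageGrid(values=np.asarray(values, dtype=float), pixel_spacing=spacing,
                     provenance={"source": str(path)})


def save_dicom(image: ImageGrid, path: str | Path) -> None:
    """Write a slice as a DICOM secondary-capture object (signed 16-bit HU)."""
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = pydicom.Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.Rows, ds.Columns = image.values.shape
    ds.PixelSpacing = [f"{image.pixel_spacing:.6f}", f"{image.pixel_spacing:.6f}"]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1  # signed, HU can be negative
    ds.RescaleIntercept = "0"
    ds.RescaleSlope = "1"
    ds.ImageComments = json.dumps(provenance_record(image))[:1024]
    pixels = np.clip(np.rint(image.values), -(2**15), 2**15 - 1).astype(np.int16)
    ds.PixelData = pixels.tobytes()
    ds.save_as(path, enforce_file_format=True)


def load_dicom(path: str | Path) -> ImageGrid:
    """Load a 2D DICOM slice, applying the rescale slope/intercept."""
    ds = pydicom.dcmread(path)
    values = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    values = values * slope + intercept
    spacing = float(ds.PixelSpacing[0])
    return ImageGrid(values=values, pixel_spacing=spacing, provenance={"source": str(path)})


def load_image(path: str | Path) -> ImageGrid:
    """Load a slice by file extension (.tif/.tiff or .dcm)."""
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        return load_tiff(path)
    if suffix in (".dcm", ".dicom"):
        return load_dicom(path)
    raise ValueError(f"unsupported image format: {suffix!r}")


def write_manifest(images: Iterable[ImageGrid | Mapping], path: str | Path) -> pd.DataFrame:
    """Write a provenance manifest CSV for a collection of slices."""
    rows = [
        provenance_record(img) if isinstance(img, ImageGrid) else dict(img)
        for img in images
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
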