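"""File formats: the HDF5 k-space container, NIfTI, DICOM and PNG export.

The k-space container is this package's own documented schema (version 1):

    /samples                complex128, (n_coils, M)
    /trajectory/coords      float64, (M, 2), radians in [-pi, pi)
    /trajectory/blade_index int32, (M,)
    /trajectory/line_index  int32, (M,)
    /trajectory attrs       blade-geometry fields when known
    / attrs                 format_version = 1

Images are exported as NIfTI-1 (magnitude and phase volumes), 16-bit
uncompressed grayscale DICOM secondary capture (the scale factor from
floating-point magnitude to stored integers is recorded in the series
description), and 8-bit PNG previews.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import h5py
import numpy as np

from .containers import KSpaceData, SensitivityMaps
from .geometry import BladeSpec, KTrajectory

__all__ = [
    "save_kspace",
    "load_kspace",
    "save_maps",
    "load_maps",
    "save_nifti",
    "save_dicom_series",
    "save_png",
]

FORMAT_VERSION = 1
_SPEC_FIELDS = (
    "n_readout",
    "n_lines",
    "n_blades",
    "matrix_size",
    "sense_factor",
    "rotation_offset",
    "interleave_offsets",
)


def _write_trajectory(group: h5py.Group, traj: KTrajectory) -> None:
    group.create_dataset("coords", data=traj.coords, dtype=np.float64)
    group.create_dataset("blade_index", data=traj.blade_index, dtype=np.int32)
    group.create_dataset("line_index", data=traj.line_index, dtype=np.int32)
    if traj.spec is not None:
        for name in _SPEC_FIELDS:
            group.attrs[name] = getattr(traj.spec, name)


def _read_trajectory(group: h5py.Group) -> KTrajectory:
    spec = None
    if "n_readout" in group.attrs:
        spec = BladeSpec(
            n_readout=int(group.attrs["n_readout"]),
            n_lines=int(group.attrs["n_lines"]),
            n_blades=int(group.attrs["n_blades"]),
            matrix_size=int(group.attrs["matrix_size"]),
            sense_factor=int(group.attrs["sense_factor"]),
            rotation_offset=float(group.attrs["rotation_offset"]),
            interleave_offsets=bool(group.attrs["interleave_offsets"]),
        )
    return KTrajectory(
        coords=group["coords"][()],
        blade_index=group["blade_index"][()],
        line_index=group["line_index"][()],
        spec=spec,
    )


def save_kspace(path, data: KSpaceData) -> None:
    """Write a :class:`KSpaceData` container (HDF5, schema above)."""
    with h5py.File(path, "w") as h5:
        h5.attrs["format_version"] = FORMAT_VERSION
        h5.create_dataset("samples", data=data.samples, dtype=np.complex128)
        _write_trajectory(h5.create_group("trajectory"), data.traj)


def load_kspace(path) -> KSpaceData:
    """Read a k-space container written by :func:`save_kspace`."""
    with h5py.File(path, "r") as h5:
        version = int(h5.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise ValueError(f"unsupported container version {version}")
        samples = h5["samples"][()]
        traj = _read_trajectory(h5["trajectory"])
    return KSpaceData(samples=samples, traj=traj)


def save_maps(path, maps: SensitivityMaps) -> None:
    """Write sensitivity maps (complex128 + boolean support mask)."""
    with h5py.File(path, "w") as h5:
        h5.attrs["format_version"] = FORMAT_VERSION
        h5.create_dataset("maps", data=maps.maps, dtype=np.complex128)
        h5.create_dataset("support", data=maps.support)


def load_maps(path) -> SensitivityMaps:
    with h5py.File(path, "r") as h5:
        return SensitivityMaps(maps=h5["maps"][()], support=h5["support"][()])


def save_nifti(path, img: np.ndarray, pixel_spacing: float = 1.0) -> None:
    """Write a real-valued image (e.g. magnitude or phase) as NIfTI-1."""
    import nibabel as nib

    img = np.asarray(img, dtype=np.float64)
    affine = np.diag([pixel_spacing, pixel_spacing, 1.0, 1.0])
    nib.save(nib.Nifti1Image(img[..., None], affine), str(path))


def save_dicom_series(
    directory,
    magnitude: np.ndarray,
    series_description: str = "bladerecon",
    randomize_uids: bool = False,
    seed: int = 0,
) -> list:
    """Write a single-slice uncompressed 16-bit grayscale DICOM series.

    The magnitude image is linearly scaled to the full 16-bit range; the
    scale factor is recorded in ``ImageComments``.  With
    ``randomize_uids`` the SOP/series instance UIDs are regenerated from
    the given seed so that exported series carry no information about the
    algorithm that produced them (blinded-reading support).
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mag = np.abs(np.asarray(magnitude, dtype=np.float64))
    scale = 65535.0 / max(mag.max(), np.finfo(float).tiny)
    pixels = np.round(mag * scale).astype(np.uint16)

    rng = np.random.default_rng(seed)

    def make_uid():
        if randomize_uids:
            # a UID numeric component must not have a leading zero
            tail = str(rng.integers(1, 10)) + "".join(
                str(rng.integers(0, 10)) for _ in range(15)
            )
            return f"1.2.826.0.1.3680043.8.498.{tail}"
        return pydicom.uid.generate_uid()

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = make_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    path = directory / "slice_0000.dcm"
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = make_uid()
    ds.StudyInstanceUID = make_uid()
    ds.Modality = "OT"
    ds.SeriesDescription = series_description
    ds.ImageComments = f"magnitude scale factor {scale:.6g}"
    now = datetime.datetime.now()
    ds.ContentDate = now.strftime("%Y%m%d")
    ds.ContentTime = now.strftime("%H%M%S")
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = pixels.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = pixels.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
    return [path]


def save_png(path, img: np.ndarray) -> None:
    """8-bit grayscale PNG preview of a magnitude image."""
    import imageio.v3 as iio

    mag = np.abs(np.asarray(img)).astype(np.float64)
    scaled = np.round(255.0 * mag / max(mag.max(), np.finfo(float).tiny))
    iio.imwrite(str(path), scaled.astype(np.uint8))
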