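"""Container readers/writers and run manifests.

Images travel as NIfTI-1 (a 2D image is stored as a single-slice volume
with the pixel size in the header zooms).  Sinograms and weight maps use a
lossless flat-binary container: one JSON header line (shape, dtype, kind,
geometry) terminated by a newline, followed by the raw little-endian
array bytes.  Traces and metrics are plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .projector import Geometry
from .simulate import AcquisitionSpec, SimulatedDataset

__all__ = [
    "write_image",
    "read_image",
    "write_array",
    "read_array",
    "write_dataset",
    "read_dataset",
    "write_beta_trace",
    "write_manifest",
]

_MAGIC = "bootrecon-array-v1"


def write_image(path: str | Path, img: np.ndarray, pixel_size: float = 1.0) -> None:
    img = np.asarray(img, dtype=np.float64)
    affine = np.diag([pixel_size, pixel_size, 1.0, 1.0])
    nib.save(nib.Nifti1Image(img[:, :, None], affine), str(path))


def read_image(path: str | Path) -> tuple[np.ndarray, float]:
    vol = nib.load(str(path))
    data = np.asarray(vol.dataobj, dtype=np.float64)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    return data, float(vol.header.get_zooms()[0])


def write_array(path: str | Path, arr: np.ndarray, **meta) -> None:
    """Flat binary with a one-line JSON text header."""
    arr = np.ascontiguousarray(arr)
    header = {
        "magic": _MAGIC,
        "shape": list(arr.shape),
        "dtype": arr.dtype.str,
        **meta,
    }
    with open(path, "wb") as fh:
        fh.write((json.dumps(header) + "\n").encode())
        fh.write(arr.tobytes())


def read_array(path: str | Path) -> tuple[np.ndarray, dict]:
    with open(path, "rb") as fh:
        header = json.loads(fh.readline().decode())
        if header.get("magic") != _MAGIC:
            raise ValueError(f"{path} is not a bootrecon array container")
        arr = np.frombuffer(fh.read(), dtype=np.dtype(header["dtype"]))
    return arr.reshape(header["shape"]).copy(), header


def _geom_dict(geom: Geometry) -> dict:
    return {
        "n_angles": geom.n_angles,
        "n_bins": geom.n_bins,
        "bin_size": geom.bin_size,
        "image_shape": list(geom.image_shape),
        "pixel_size": geom.pixel_size,
        "psf_fwhm": geom.psf_fwhm,
    }


def _geom_from_dict(d: dict) -> Geometry:
    return Geometry(
        n_angles=d["n_angles"],
        n_bins=d["n_bins"],
        bin_size=d["bin_size"],
        image_shape=tuple(d["image_shape"]),
        pixel_size=d["pixel_size"],
        psf_fwhm=d.get("psf_fwhm", 0.0),
    )


def write_dataset(outdir: str | Path, ds: SimulatedDataset) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geom = _geom_dict(ds.geom)
    write_array(outdir / "m.sino", ds.m, kind="counts", geometry=geom)
    write_array(outdir / "b.sino", ds.b, kind="mean", geometry=geom)
    write_array(outdir / "true_mean.sino", ds.true_mean, kind="mean", geometry=geom)
    write_image(outdir / "phantom.nii", ds.phantom, ds.geom.pixel_size)
    write_image(outdir / "guide.nii", ds.guide, ds.geom.pixel_size)
    manifest = {
        "geometry": geom,
        "acquisition": asdict(ds.spec) if ds.spec is not None else None,
        "files": ["m.sino", "b.sino", "true_mean.sino", "phantom.nii", "guide.nii"],
    }
    write_manifest(outdir / "manifest.json", manifest)


def read_dataset(indir: str | Path) -> SimulatedDataset:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    geom = _geom_from_dict(manifest["geometry"])
    m, _ = read_array(indir / "m.sino")
    b, _ = read_array(indir / "b.sino")
    true_mean, _ = read_array(indir / "true_mean.sino")
    phantom, _ = read_image(indir / "phantom.nii")
    guide, _ = read_image(indir / "guide.nii")
    spec = (
        AcquisitionSpec(**manifest["acquisition"]) if manifest.get("acquisition") else None
    )
    return SimulatedDataset(
        m=m.astype(np.int64),
        b=b,
        true_mean=true_mean,
        phantom=phantom,
        guide=guide,
        geom=geom,
        spec=spec,
    )


def write_beta_trace(path: str | Path, state) -> None:
    arrays = state.as_arrays()
    n = len(arrays["beta_opt"])
    pd.DataFrame(
        {
            "k": np.arange(1, n + 1),
            "beta_opt": arrays["beta_opt"],
            "beta_use": arrays["beta_use"],
            "lambda": arrays["lambda_k"],
            "beta_cool": arrays["beta_cool"],
            "emof_value": arrays["emof_value"],
        }
    ).to_csv(path, index=False)


def write_manifest(path: str | Path, payload: dict) -> None:
    # deliberately no timestamps: identical config + seed must give
    # byte-identical outputs
    payload = dict(payload)
    from . import __version__

    payload.setdefault("bootrecon_version", __version__)
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
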