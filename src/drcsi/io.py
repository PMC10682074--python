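"""NIfTI-1 input/output with JSON sidecars.

Volumes are stored as 4D NIfTI files (float32 on disk, float64 in memory)
with a JSON sidecar next to each file (same stem, ``.json``) describing the
4th axis: the acquisition protocol and per-volume contrast table for signal
data, or the spectral grid for spectrum fields, plus processing-state flags.
Masks are 3D uint8 volumes.
"""

from __future__ import annotations

import json

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import RawDataset
from .protocol import AcquisitionProtocol, SpectralGrid
from .volumes import SignalVolume, SpectrumField

__all__ = [
    "sidecar_path",
    "save_signal_volume",
    "load_signal_volume",
    "save_spectrum_field",
    "load_spectrum_field",
    "save_raw_dataset",
    "load_raw_dataset",
    "save_mask",
    "load_mask",
    "save_map",
    "load_map",
]

_AFFINE = np.eye(4)


def sidecar_path(path) -> str:
    p = str(path)
    for ext in (".nii.gz", ".nii"):
        if p.endswith(ext):
            return p[: -len(ext)] + ".json"
    return p + ".json"


def _save_nifti(data, path, dtype=np.float32):
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), _AFFINE)
    nib.save(img, str(path))


def _load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)


def _write_sidecar(path, payload: dict):
    with open(sidecar_path(path), "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _read_sidecar(path) -> dict:
    with open(sidecar_path(path)) as fh:
        return json.load(fh)


def save_mask(mask: np.ndarray, path) -> None:
    _save_nifti(np.asarray(mask, dtype=np.uint8), path, dtype=np.uint8)


def load_mask(path) -> np.ndarray:
    return _load_nifti(path) > 0


def save_map(data: np.ndarray, path) -> None:
    """Store a scalar 3D map (fractions, RMSE) as float32 NIfTI."""
    _save_nifti(data, path)


def load_map(path) -> np.ndarray:
    return _load_nifti(path)


def save_signal_volume(sv: SignalVolume, path) -> None:
    _save_nifti(sv.data, path)
    save_mask(sv.mask, _mask_path(path))
    _write_sidecar(
        path,
        {
            "kind": "signal_volume",
            "protocol": sv.protocol.to_dict(),
            "flags": {
                "polarity_corrected": sv.polarity_corrected,
                "powder_averaged": sv.powder_averaged,
                "normalized": sv.normalized,
            },
        },
    )


def _mask_path(path) -> str:
    p = str(path)
    for ext in (".nii.gz", ".nii"):
        if p.endswith(ext):
            return p[: -len(ext)] + "_mask" + ext
    return p + "_mask.nii.gz"


def load_signal_volume(path) -> SignalVolume:
    meta = _read_sidecar(path)
    if meta.get("kind") != "signal_volume":
        raise ValueError(f"{path} is not a signal volume (sidecar kind mismatch)")
    flags = meta["flags"]
    return SignalVolume(
        data=_load_nifti(path),
        mask=load_mask(_mask_path(path)),
        protocol=AcquisitionProtocol.from_dict(meta["protocol"]),
        polarity_corrected=flags["polarity_corrected"],
        powder_averaged=flags["powder_averaged"],
        normalized=flags["normalized"],
    )


def save_spectrum_field(F: SpectrumField, path) -> None:
    _save_nifti(F.data, path)
    save_mask(F.mask, _mask_path(path))
    _write_sidecar(path, {"kind": "spectrum_field", "grid": F.grid.to_dict()})


def load_spectrum_field(path) -> SpectrumField:
    meta = _read_sidecar(path)
    if meta.get("kind") != "spectrum_field":
        raise ValueError(f"{path} is not a spectrum field (sidecar kind mismatch)")
    return SpectrumField(
        data=_load_nifti(path),
        mask=load_mask(_mask_path(path)),
        grid=SpectralGrid.from_dict(meta["grid"]),
    )


def save_raw_dataset(raw: RawDataset, path) -> None:
    _save_nifti(raw.data, path)
    save_mask(raw.mask, _mask_path(path))
    _write_sidecar(
        path,
        {
            "kind": "raw_dataset",
            "protocol": raw.protocol.to_dict(),
            "volumes": raw.volumes.where(pd.notna(raw.volumes), None).to_dict(
                orient="records"
            ),
        },
    )


def load_raw_dataset(path) -> RawDataset:
    meta = _read_sidecar(path)
    if meta.get("kind") != "raw_dataset":
        raise ValueError(f"{path} is not a raw dataset (sidecar kind mismatch)")
    vols = pd.DataFrame(meta["volumes"]).astype(
        {"volume": int, "contrast": int, "direction": int}
    )
    vols["TI_ms"] = vols["TI_ms"].astype(float)
    return RawDataset(
        data=_load_nifti(path),
        volumes=vols,
        protocol=AcquisitionProtocol.from_dict(meta["protocol"]),
        mask=load_mask(_mask_path(path)),
    )
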