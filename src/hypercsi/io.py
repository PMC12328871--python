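"""File I/O and provenance: HDF5 tensors, NIfTI images, YAML configs,
CSV tables, and run manifests for exact replay."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .core import AcquisitionProtocol, CsiTensor
from .phantom import GuideImage

__all__ = ["save_csi", "load_csi", "save_nifti", "load_nifti", "save_guide",
           "load_guide", "load_config", "save_config", "RunManifest",
           "sha256_file"]


def _protocol_to_dict(p: AcquisitionProtocol) -> dict:
    d = dataclasses.asdict(p)
    d["matrix_size"] = list(d["matrix_size"])
    d["fov_mm"] = list(d["fov_mm"])
    return d


def _protocol_from_dict(d: dict) -> AcquisitionProtocol:
    d = dict(d)
    d["matrix_size"] = tuple(d["matrix_size"])
    d["fov_mm"] = tuple(d["fov_mm"])
    return AcquisitionProtocol(**d)


def save_csi(path, tensor: CsiTensor) -> None:
    """Write a CsiTensor to HDF5: complex128 ``/data``, ppm axis, JSON meta."""
    meta = {
        "spatial_domain": tensor.spatial_domain,
        "spectral_domain": tensor.spectral_domain,
        "protocol": (_protocol_to_dict(tensor.protocol)
                     if tensor.protocol else None),
    }
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=tensor.data.astype(np.complex128))
        if tensor.ppm_axis is not None:
            f.create_dataset("axes/ppm", data=tensor.ppm_axis)
        f.attrs["meta"] = json.dumps(meta)


def load_csi(path) -> CsiTensor:
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise ValueError(f"{path}: missing dataset 'data'")
        if "meta" not in f.attrs:
            raise ValueError(f"{path}: missing 'meta' attribute")
        meta = json.loads(f.attrs["meta"])
        data = f["data"][()]
        ppm = f["axes/ppm"][()] if "axes/ppm" in f else None
    proto = meta.get("protocol")
    return CsiTensor(data, spatial_domain=meta["spatial_domain"],
                     spectral_domain=meta["spectral_domain"],
                     protocol=_protocol_from_dict(proto) if proto else None,
                     ppm_axis=ppm)


def save_nifti(path, image: np.ndarray, voxel_mm: tuple[float, float] = (1.0, 1.0)
               ) -> None:
    affine = np.diag([voxel_mm[0], voxel_mm[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(image, dtype=np.float64), affine),
             str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_guide(path, guide: GuideImage) -> None:
    vox = (guide.fov_mm[0] / guide.grid, guide.fov_mm[1] / guide.grid)
    save_nifti(path, guide.pixels, voxel_mm=vox)


def load_guide(path, fov_mm: tuple[float, float] = (32.0, 32.0)) -> GuideImage:
    data, _ = load_nifti(path)
    data = np.squeeze(data)
    return GuideImage(pixels=data, grid=data.shape[0], fov_mm=fov_mm)


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def save_config(path, cfg: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=True)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for block in iter(lambda: f.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Provenance of one pipeline run, sufficient for exact replay."""

    config: dict
    config_hash: str
    seed: int
    stages: list = dataclasses.field(default_factory=list)
    outputs: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def start(cls, config: dict, seed: int) -> "RunManifest":
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        return cls(config=config, config_hash=hashlib.sha256(blob).hexdigest(),
                   seed=seed)

    def record_stage(self, name: str, **params) -> None:
        self.stages.append({"stage": name, "params": params})

    def record_output(self, path) -> None:
        p = Path(path)
        self.outputs[p.name] = sha256_file(p)

    def save(self, path) -> None:
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=2, default=str)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as f:
            return cls(**json.load(f))
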