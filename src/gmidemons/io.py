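"""Readers/writers and the end-to-end pipeline orchestrator.

Supported image formats:

* NIfTI (``.nii`` / ``.nii.gz``) through nibabel; voxel spacing is stored in
  the header zooms and the origin in the affine translation.
* A portable raw format: little-endian float32 array (``.raw``) with a JSON
  sidecar (same stem, ``.json``) holding ``{"shape", "spacing", "origin"}``.

Displacement fields are stored as multi-component volumes (the last axis
indexes the vector component).  Point sets are plain-text coordinate tables;
transforms and run manifests are JSON.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__
from .driver import register
from .image_model import (
    DisplacementField,
    RegistrationConfig,
    ScalarImage,
    warp_image,
)
from .metrics import PointSet, image_feature_distance
from .mi import estimate_joint_density, mutual_information
from .rigid import RigidTransform, apply_rigid

logger = logging.getLogger("gmidemons")

__all__ = [
    "read_image",
    "write_image",
    "read_field",
    "write_field",
    "read_points",
    "write_points",
    "read_transform",
    "write_transform",
    "RunManifest",
    "run_pipeline",
]


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _sidecar(path: Path) -> Path:
    name = path.name
    if name.lower().endswith(".raw"):
        name = name[: -len(".raw")]
    return path.with_name(name + ".json")


def _read_nifti_array(path: Path):
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    zooms = img.header.get_zooms()
    origin = img.affine[: data.ndim, 3] if img.affine is not None else None
    return data, zooms, origin


def read_image(path) -> ScalarImage:
    """Read a scalar image from NIfTI or the raw+JSON portable format."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    if _is_nifti(path):
        data, zooms, origin = _read_nifti_array(path)
        spacing = tuple(float(z) for z in zooms[: data.ndim])
        origin = tuple(float(o) for o in origin) if origin is not None else None
        return ScalarImage(data, spacing or None, origin)
    if path.suffix.lower() == ".raw":
        side = _sidecar(path)
        if not side.exists():
            raise IOError(f"missing JSON sidecar {side} for raw image {path}")
        try:
            meta = json.loads(side.read_text())
            shape = tuple(int(n) for n in meta["shape"])
        except (ValueError, KeyError) as exc:
            raise IOError(f"corrupt sidecar {side}: {exc}") from exc
        raw = np.fromfile(path, dtype="<f4")
        expected = int(np.prod(shape))
        if raw.size != expected:
            raise IOError(
                f"truncated or corrupt raw file {path}: holds {raw.size} "
                f"float32 values, header promises {expected}"
            )
        return ScalarImage(
            raw.reshape(shape).astype(np.float64),
            tuple(meta.get("spacing") or ()) or None,
            tuple(meta.get("origin") or ()) or None,
        )
    raise IOError(f"unsupported image format: {path} (use .nii, .nii.gz or .raw)")


def write_image(img: ScalarImage, path) -> None:
    """Write a scalar image; format chosen from the file extension."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        affine = np.eye(4)
        for a, s in enumerate(img.spacing):
            affine[a, a] = s
        affine[: img.ndim, 3] = img.origin
        out = nib.Nifti1Image(img.data.astype(np.float32), affine)
        out.header.set_zooms(img.spacing)
        nib.save(out, str(path))
    elif path.suffix.lower() == ".raw":
        img.data.astype("<f4").tofile(path)
        _sidecar(path).write_text(
            json.dumps(
                {
                    "shape": list(img.shape),
                    "spacing": list(img.spacing),
                    "origin": list(img.origin),
                    "dtype": "<f4",
                }
            )
        )
    else:
        raise IOError(f"unsupported image format: {path} (use .nii, .nii.gz or .raw)")


def write_field(field: DisplacementField, path) -> None:
    """Store a displacement field as a multi-component volume.

    The last axis of the stored array indexes the vector component.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(field.vectors.astype(np.float32), np.eye(4)), str(path))
    elif path.suffix.lower() == ".raw":
        field.vectors.astype("<f4").tofile(path)
        _sidecar(path).write_text(
            json.dumps({"shape": list(field.vectors.shape), "dtype": "<f4"})
        )
    else:
        raise IOError(f"unsupported field format: {path}")


def read_field(path) -> DisplacementField:
    """Read a displacement field written by :func:`write_field`."""
    path = Path(path)
    if _is_nifti(path):
        data, _, _ = _read_nifti_array(path)
    elif path.suffix.lower() == ".raw":
        side = _sidecar(path)
        if not side.exists():
            raise IOError(f"missing JSON sidecar {side} for raw field {path}")
        meta = json.loads(side.read_text())
        shape = tuple(int(n) for n in meta["shape"])
        raw = np.fromfile(path, dtype="<f4")
        if raw.size != int(np.prod(shape)):
            raise IOError(f"truncated or corrupt raw field file {path}")
        data = raw.reshape(shape).astype(np.float64)
    else:
        raise IOError(f"unsupported field format: {path}")
    return DisplacementField(data)


def read_points(path) -> PointSet:
    """Read a whitespace/comma separated coordinate table."""
    try:
        pts = np.loadtxt(path, delimiter=None, ndmin=2)
    except ValueError:
        pts = np.loadtxt(path, delimiter=",", ndmin=2)
    return PointSet(pts)


def write_points(points: PointSet, path) -> None:
    np.savetxt(path, points.points, fmt="%.6f", delimiter=",")


def write_transform(t: RigidTransform, path) -> None:
    Path(path).write_text(json.dumps(t.to_dict(), indent=2))


def read_transform(path) -> RigidTransform:
    try:
        return RigidTransform.from_dict(json.loads(Path(path).read_text()))
    except (ValueError, KeyError) as exc:
        raise IOError(f"corrupt transform file {path}: {exc}") from exc


def _checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline run: effective config, inputs, stage metrics."""

    config: dict
    inputs: dict
    metrics: dict
    iterations_used: list
    converged: list
    version: str = __version__
    timestamp: str = ""

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))

    def equivalent(self, other: "RunManifest") -> bool:
        """Equality of everything that a rerun should reproduce
        (the timestamp is excluded)."""
        a, b = self.to_dict(), other.to_dict()
        a.pop("timestamp"), b.pop("timestamp")
        return a == b


def _mi_of(reference: ScalarImage, other: ScalarImage, cfg: RegistrationConfig) -> float:
    jd = estimate_joint_density(
        reference.normalized(),
        other.normalized(),
        delta=cfg.parzen_delta,
        lattice_size=cfg.lattice_size,
    )
    return mutual_information(jd)


def run_pipeline(
    reference_path,
    floating_path,
    cfg: RegistrationConfig = None,
    out_dir=None,
) -> RunManifest:
    """Global rigid alignment, deformable GMI demons, and evaluation.

    Reads the two images, runs :func:`gmidemons.driver.register`, computes
    MI and M-HD at every stage (before registration, after the global rigid
    stage, after the deformable stage), and — when ``out_dir`` is given —
    writes the warped floating image, displacement field, rigid transform
    and the JSON manifest there.
    """
    if cfg is None:
        cfg = RegistrationConfig()
    stage = "reading inputs"
    try:
        reference = read_image(reference_path)
        floating = read_image(floating_path)
        stage = "registration"
        result = register(reference, floating, cfg)
        stage = "evaluation"
        flo_rigid = apply_rigid(floating, result.global_transform, pad=cfg.pad)
        warped = warp_image(flo_rigid, result.field, pad=cfg.pad, pad_value=cfg.pad_value)
        mhd_before = image_feature_distance(reference, floating)
        mhd_global = image_feature_distance(reference, flo_rigid)
        mhd_deform = image_feature_distance(reference, warped)
        metrics = {
            "mi_before": _mi_of(reference, floating, cfg),
            "mi_after_global": _mi_of(reference, flo_rigid, cfg),
            "mi_after_deformable": _mi_of(reference, warped, cfg),
            "mhd_before": mhd_before["modified_hausdorff"],
            "mhd_after_global": mhd_global["modified_hausdorff"],
            "mhd_after_deformable": mhd_deform["modified_hausdorff"],
            "mhd_unit": mhd_before["unit"],
            "global_transform": result.global_transform.to_dict(),
            "max_field_magnitude": float(result.field.magnitudes().max()),
        }
        manifest = RunManifest(
            config=asdict(cfg),
            inputs={
                "reference": str(reference_path),
                "floating": str(floating_path),
                "reference_sha256": _checksum(reference_path),
                "floating_sha256": _checksum(floating_path),
            },
            metrics=metrics,
            iterations_used=list(result.iterations_used),
            converged=list(result.converged),
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        )
        if out_dir is not None:
            stage = "writing outputs"
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_image(warped, out / "warped.nii")
            write_field(result.field, out / "field.nii")
            write_transform(result.global_transform, out / "global_transform.json")
            (out / "manifest.json").write_text(manifest.to_json())
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed during {stage}: {exc}") from exc
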