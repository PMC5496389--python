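"""Study-level file formats: NIfTI volumes plus JSON sidecars.

Arrays are written to NIfTI-1 in their native ``(slice, row, col[, echo])``
memory order with a diagonal affine of ``(dz, dy, dx)``; the sidecar
records the semantic voxel size so round-trips are lossless.  Masks are
stored as unsigned bytes, maps and series as float64.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from ..core import ImageSeries
from ..errors import DataError
from ..relaxometry import ParameterMap

__all__ = [
    "StudyBundle",
    "save_series",
    "load_series",
    "save_mask",
    "load_mask",
    "save_map",
    "load_map",
]


def _affine(voxel_size) -> np.ndarray:
    dx, dy, dz = voxel_size
    return np.diag([dz, dy, dx, 1.0])


def _write_nifti(path: Path, array: np.ndarray, voxel_size, dtype) -> None:
    img = nib.Nifti1Image(np.asarray(array, dtype=dtype), _affine(voxel_size))
    nib.save(img, str(path))


def _read_nifti(path: Path) -> np.ndarray:
    if not Path(path).exists():
        raise DataError(f"missing file: {path}")
    try:
        return np.asarray(nib.load(str(path)).get_fdata())
    except Exception as exc:  # truncated/corrupt files surface with the path
        raise DataError(f"cannot read NIfTI {path}: {exc}") from exc


def save_series(directory: Path, name: str, series: ImageSeries) -> dict:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nii = directory / f"{name}.nii"
    sidecar = directory / f"{name}.json"
    _write_nifti(nii, series.data, series.voxel_size, np.float64)
    meta = {
        "contrast_kind": series.contrast_kind,
        "times_ms": list(series.times),
        "voxel_size_mm": list(series.voxel_size),
        **{k: v for k, v in series.meta.items() if isinstance(v, (int, float, str))},
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return {"nii": nii.name, "sidecar": sidecar.name}


def load_series(directory: Path, name: str) -> ImageSeries:
    directory = Path(directory)
    sidecar = directory / f"{name}.json"
    if not sidecar.exists():
        raise DataError(f"missing sidecar: {sidecar}")
    meta = json.loads(sidecar.read_text())
    data = _read_nifti(directory / f"{name}.nii")
    if data.ndim == 3:
        data = data[..., None]
    if data.shape[-1] != len(meta["times_ms"]):
        raise DataError(
            f"{name}: sidecar lists {len(meta['times_ms'])} times but the image "
            f"has {data.shape[-1]} frames"
        )
    extra = {
        k: v
        for k, v in meta.items()
        if k not in ("contrast_kind", "times_ms", "voxel_size_mm")
    }
    return ImageSeries(
        data,
        tuple(meta["times_ms"]),
        meta["contrast_kind"],
        tuple(meta["voxel_size_mm"]),
        meta=extra,
    )


def save_mask(directory: Path, name: str, mask: np.ndarray, voxel_size) -> dict:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _write_nifti(directory / f"{name}.nii", mask.astype(np.uint8), voxel_size, np.uint8)
    return {"nii": f"{name}.nii"}


def load_mask(directory: Path, name: str) -> np.ndarray:
    return _read_nifti(Path(directory) / f"{name}.nii") > 0.5


def save_map(directory: Path, name: str, pmap: ParameterMap, voxel_size) -> dict:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _write_nifti(directory / f"{name}_time.nii", pmap.relaxation_time, voxel_size, np.float64)
    _write_nifti(directory / f"{name}_amplitude.nii", pmap.amplitude, voxel_size, np.float64)
    _write_nifti(directory / f"{name}_residual.nii", pmap.residual_norm, voxel_size, np.float64)
    _write_nifti(directory / f"{name}_reason.nii", pmap.reason, voxel_size, np.uint8)
    (directory / f"{name}.json").write_text(
        json.dumps({"contrast_kind": pmap.contrast_kind, "cap_ms": pmap.cap_ms}, indent=2)
    )
    return {"stem": name}


def load_map(directory: Path, name: str) -> ParameterMap:
    directory = Path(directory)
    meta = json.loads((directory / f"{name}.json").read_text())
    time = _read_nifti(directory / f"{name}_time.nii")
    amp = _read_nifti(directory / f"{name}_amplitude.nii")
    res = _read_nifti(directory / f"{name}_residual.nii")
    reason = _read_nifti(directory / f"{name}_reason.nii").astype(np.uint8)
    return ParameterMap(
        relaxation_time=time,
        amplitude=amp,
        residual_norm=res,
        valid=reason == 0,
        reason=reason,
        contrast_kind=meta["contrast_kind"],
        cap_ms=meta["cap_ms"],
    )


@dataclass
class StudyBundle:
    """One subject x time point: file pointers plus the seed registry."""

    subject_id: str
    arm: str
    timepoint: str  # baseline | 24h
    root: Path
    files: dict[str, str] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)
    spec: dict = field(default_factory=dict)

    MANIFEST = "manifest.json"

    def write_manifest(self) -> None:
        root = Path(self.root)
        root.mkdir(parents=True, exist_ok=True)
        (root / self.MANIFEST).write_text(
            json.dumps(
                {
                    "subject_id": self.subject_id,
                    "arm": self.arm,
                    "timepoint": self.timepoint,
                    "files": self.files,
                    "seeds": self.seeds,
                    "spec": self.spec,
                },
                indent=2,
                sort_keys=True,
            )
        )

    @classmethod
    def read(cls, root: Path) -> "StudyBundle":
        root = Path(root)
        manifest = root / cls.MANIFEST
        if not manifest.exists():
            raise DataError(f"no study manifest at {manifest}")
        d = json.loads(manifest.read_text())
        bundle = cls(
            subject_id=d["subject_id"],
            arm=d["arm"],
            timepoint=d["timepoint"],
            root=root,
            files=d.get("files", {}),
            seeds=d.get("seeds", {}),
            spec=d.get("spec", {}),
        )
        bundle.validate()
        return bundle

    def validate(self) -> None:
        """Check referenced files exist and grids are mutually consistent."""
        root = Path(self.root)
        shapes = {}
        for key, fname in self.files.items():
            path = root / fname
            if not path.exists():
                raise DataError(f"study file missing: {path}")
            if fname.endswith(".nii"):
                arr = _read_nifti(path)
                shapes[key] = arr.shape[:3]
        if len(set(shapes.values())) > 1:
            raise DataError(f"inconsistent grids across study files: {shapes}")
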