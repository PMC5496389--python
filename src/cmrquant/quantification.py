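"""Reported measurements: volumetrics, region statistics, cardiac function."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import voxel_volume_ml
from .errors import DataError, DimensionError
from .phantom import ANTEROSEPTAL_CENTER_DEG, in_sector, polar_grid
from .relaxometry import ParameterMap, map_summary
from .segmentation import LesionMask

__all__ = [
    "DEFAULT_MYOCARDIAL_DENSITY",
    "LabelVolume",
    "VolumeReport",
    "RegionStats",
    "FunctionReport",
    "compute_volumes",
    "extract_region_stats",
    "cardiac_function",
    "mid_ventricular_slice",
]

#: Standard myocardial tissue density (g/mL); configurable in every call.
DEFAULT_MYOCARDIAL_DENSITY = 1.05


@dataclass(frozen=True)
class LabelVolume:
    voxel_count: int
    volume_ml: float
    mass_g: float
    percent_lv: float


@dataclass(frozen=True)
class VolumeReport:
    labels: dict[str, LabelVolume]
    lv_voxel_count: int
    lv_volume_ml: float
    lv_mass_g: float
    voxel_size: tuple[float, float, float]
    density_g_per_ml: float

    def to_dict(self) -> dict:
        out = {
            "lv_voxel_count": self.lv_voxel_count,
            "lv_volume_ml": self.lv_volume_ml,
            "lv_mass_g": self.lv_mass_g,
            "voxel_size_mm": list(self.voxel_size),
            "density_g_per_ml": self.density_g_per_ml,
        }
        for name, lv in self.labels.items():
            out[name] = {
                "voxel_count": lv.voxel_count,
                "volume_ml": lv.volume_ml,
                "mass_g": lv.mass_g,
                "percent_lv": lv.percent_lv,
            }
        return out


@dataclass(frozen=True)
class RegionStats:
    infarct_t2_mean: float
    infarct_t2_sd: float
    infarct_t2star_mean: float
    infarct_t2star_sd: float
    remote_t2_mean: float
    remote_t2_sd: float
    remote_t2star_mean: float
    remote_t2star_sd: float
    slice_index: int
    used_fallback_sector: bool
    baseline: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FunctionReport:
    ef_percent: float
    edv_ml: float
    esv_ml: float
    lv_mass_g: float


def _as_mask(m) -> np.ndarray:
    if isinstance(m, LesionMask):
        m = m.mask
    return np.asarray(m, dtype=bool)


def compute_volumes(
    masks: Mapping[str, np.ndarray | LesionMask],
    myocardium_mask: np.ndarray,
    voxel_size: tuple[float, float, float],
    density_g_per_ml: float = DEFAULT_MYOCARDIAL_DENSITY,
) -> VolumeReport:
    """Voxel-count volumetrics: mL, grams and percent of the LV myocardium.

    Every label is clipped to the myocardium, so percentages cannot
    exceed 100.  ``mass = volume * density`` exactly.
    """
    myocardium_mask = _as_mask(myocardium_mask)
    lv_count = int(myocardium_mask.sum())
    if lv_count == 0:
        raise DataError("empty myocardium mask; percent of LV volume is undefined")
    vox_ml = voxel_volume_ml(voxel_size)
    labels: dict[str, LabelVolume] = {}
    for name, mask in masks.items():
        arr = _as_mask(mask)
        if arr.shape != myocardium_mask.shape:
            raise DimensionError(f"mask {name!r} grid does not match the myocardium")
        count = int((arr & myocardium_mask).sum())
        vol = count * vox_ml
        labels[name] = LabelVolume(
            voxel_count=count,
            volume_ml=vol,
            mass_g=vol * density_g_per_ml,
            percent_lv=100.0 * count / lv_count,
        )
    lv_vol = lv_count * vox_ml
    return VolumeReport(
        labels=labels,
        lv_voxel_count=lv_count,
        lv_volume_ml=lv_vol,
        lv_mass_g=lv_vol * density_g_per_ml,
        voxel_size=tuple(voxel_size),
        density_g_per_ml=density_g_per_ml,
    )


def mid_ventricular_slice(myocardium_mask: np.ndarray) -> int:
    """Median index of slices containing myocardium; even counts take the lower index."""
    slices = np.flatnonzero(_as_mask(myocardium_mask).any(axis=(1, 2)))
    if slices.size == 0:
        raise DataError("empty myocardium mask")
    return int(slices[(slices.size - 1) // 2])


def extract_region_stats(
    t2_map: ParameterMap,
    t2star_map: ParameterMap,
    infarct_mask: np.ndarray | LesionMask,
    remote_mask: np.ndarray,
    myocardium_mask: np.ndarray,
    fallback_sector: tuple[float, float] = (ANTEROSEPTAL_CENTER_DEG, 60.0),
    voxel_size: tuple[float, float, float] = (1.9, 1.9, 5.0),
    center_rc: tuple[float, float] | None = None,
    baseline: dict | None = None,
) -> RegionStats:
    """Infarct-zone and remote T2/T2* statistics on one mid-ventricular slice.

    The infarct ROI is copied from the LGE segmentation onto the maps;
    when no enhancement exists (empty infarct on the chosen slice) a
    configured anteroseptal sector is used instead.
    """
    if t2_map.grid_shape != t2star_map.grid_shape:
        raise DimensionError("T2 and T2* maps live on different grids")
    myocardium_mask = _as_mask(myocardium_mask)
    infarct = _as_mask(infarct_mask)
    remote = _as_mask(remote_mask)
    mid = mid_ventricular_slice(myocardium_mask)

    roi = np.zeros_like(myocardium_mask)
    roi[mid] = infarct[mid]
    used_fallback = False
    if not roi.any():
        used_fallback = True
        S, R, C = myocardium_mask.shape
        if center_rc is None:
            idx = np.argwhere(myocardium_mask)
            center_rc = (float(idx[:, 1].mean()), float(idx[:, 2].mean()))
        _, theta = polar_grid((R, C), center_rc, voxel_size)
        sector = in_sector(theta, fallback_sector[0], fallback_sector[1])
        roi[mid] = myocardium_mask[mid] & sector
    if not roi.any():
        raise DataError(
            f"both the infarct mask and the fallback sector are empty on slice {mid}"
        )
    it2_m, it2_sd, _ = map_summary(t2_map, roi)
    it2s_m, it2s_sd, _ = map_summary(t2star_map, roi)
    rt2_m, rt2_sd, _ = map_summary(t2_map, remote)
    rt2s_m, rt2s_sd, _ = map_summary(t2star_map, remote)
    return RegionStats(
        infarct_t2_mean=it2_m,
        infarct_t2_sd=it2_sd,
        infarct_t2star_mean=it2s_m,
        infarct_t2star_sd=it2s_sd,
        remote_t2_mean=rt2_m,
        remote_t2_sd=rt2_sd,
        remote_t2star_mean=rt2s_m,
        remote_t2star_sd=rt2s_sd,
        slice_index=mid,
        used_fallback_sector=used_fallback,
        baseline=baseline or {},
    )


def cardiac_function(
    cavity_masks: Sequence[np.ndarray],
    myocardium_masks: Sequence[np.ndarray],
    voxel_size: tuple[float, float, float],
    density_g_per_ml: float = DEFAULT_MYOCARDIAL_DENSITY,
) -> FunctionReport:
    """EF/EDV/ESV/LV-mass from per-phase cavity and myocardium masks.

    EDV is the largest phase cavity volume, ESV the smallest; LV mass is
    the myocardial volume at the EDV phase times density.
    """
    if len(cavity_masks) < 1 or len(cavity_masks) != len(myocardium_masks):
        raise DataError("need >= 1 phase with matching cavity and myocardium masks")
    vox_ml = voxel_volume_ml(voxel_size)
    cav = np.array([int(_as_mask(m).sum()) for m in cavity_masks], dtype=float) * vox_ml
    edv_phase = int(np.argmax(cav))
    edv, esv = float(cav.max()), float(cav.min())
    if edv == 0:
        raise DataError("end-diastolic volume is zero; ejection fraction undefined")
    ef = 100.0 * (edv - esv) / edv
    myo_ml = float(_as_mask(myocardium_masks[edv_phase]).sum()) * vox_ml
    return FunctionReport(
        ef_percent=ef, edv_ml=edv, esv_ml=esv, lv_mass_g=myo_ml * density_g_per_ml
    )
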