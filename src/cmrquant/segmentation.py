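"""Lesion segmentation from parameter maps and LGE images.

Criteria implemented:

* hemorrhage — valid T2* strictly below 20 ms inside the myocardium;
* edema — T2 strictly above remote mean + 2 SD, plus hypointense cores
  (hemorrhage/MVO) recovered by the shared enclosed-region growing;
* infarct — full-width-half-maximum: intensity at least half the
  reference maximum, with a remote-noise floor guard for arms without
  any enhancement;
* MVO — hypoenhanced region enclosed by the infarct, grown by front
  propagation from a seed (or the darkest enclosed voxel).

All connected-component and growing operations use 6-connectivity in
3-D.  Components smaller than ``min_component_size`` voxels (default 3)
are discarded to suppress single-voxel noise islands; every threshold
actually applied is recorded in the mask provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DataError, DimensionError
from .phantom import in_sector, polar_grid
from .relaxometry import ParameterMap, map_summary

__all__ = [
    "LesionMask",
    "RemoteReference",
    "select_remote",
    "segment_hemorrhage",
    "segment_edema",
    "segment_infarct_fwhm",
    "segment_mvo",
]

SIX_CONN = ndimage.generate_binary_structure(3, 1)
DEFAULT_MIN_COMPONENT = 3
DEFAULT_HEMORRHAGE_THRESHOLD_MS = 20.0
DEFAULT_REMOTE_WIDTH_DEG = 60.0
DEFAULT_ENHANCEMENT_FLOOR_SD = 5.0


@dataclass(frozen=True)
class LesionMask:
    """A labeled boolean voxel set plus the criterion that produced it."""

    label: str  # hemorrhage | edema | infarct | mvo
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class RemoteReference:
    """Remote-sector mask with its summary relaxation statistics."""

    mask: np.ndarray
    mean_t2: float = float("nan")
    sd_t2: float = float("nan")
    mean_t2star: float = float("nan")
    sd_t2star: float = float("nan")

    @classmethod
    def from_maps(
        cls,
        mask: np.ndarray,
        t2_map: ParameterMap | None = None,
        t2star_map: ParameterMap | None = None,
    ) -> "RemoteReference":
        kw: dict = {}
        if t2_map is not None:
            m, sd, _ = map_summary(t2_map, mask)
            kw.update(mean_t2=m, sd_t2=sd)
        if t2star_map is not None:
            m, sd, _ = map_summary(t2star_map, mask)
            kw.update(mean_t2star=m, sd_t2star=sd)
        return cls(mask=np.asarray(mask, dtype=bool), **kw)


# --------------------------------------------------------------------------- #
# helpers
# --------------------------------------------------------------------------- #


def _min_size_filter(mask: np.ndarray, min_size: int) -> np.ndarray:
    if min_size <= 1 or not mask.any():
        return mask
    labels, n = ndimage.label(mask, structure=SIX_CONN)
    counts = np.bincount(labels.ravel())
    keep = counts >= min_size
    keep[0] = False
    return keep[labels]


def _enclosed_components(candidates: np.ndarray, barrier: np.ndarray) -> np.ndarray:
    """Union of candidate components whose entire 6-neighbor exterior lies in ``barrier``.

    Components touching the array boundary are open to the outside and
    therefore never enclosed.
    """
    out = np.zeros_like(candidates)
    if not candidates.any():
        return out
    labels, n = ndimage.label(candidates, structure=SIX_CONN)
    border_labels = set()
    for axis in range(3):
        for face in (0, -1):
            border_labels |= set(np.unique(np.take(labels, face, axis=axis)))
    bad = ~(barrier | candidates)
    for i in range(1, n + 1):
        if i in border_labels:
            continue
        comp = labels == i
        exterior = ndimage.binary_dilation(comp, structure=SIX_CONN) & ~comp
        if not (exterior & bad).any():
            out |= comp
    return out


def _lesion_centroid_angle(lesion_mask: np.ndarray, theta: np.ndarray) -> float:
    """Circular-mean angle (deg) of lesion voxels, robust to 0/360 wrap."""
    ang = np.deg2rad(theta[None, ...].repeat(lesion_mask.shape[0], axis=0)[lesion_mask])
    if ang.size == 0:
        raise DataError("lesion mask is empty; cannot locate a remote sector")
    return float(np.degrees(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())) % 360.0)


# --------------------------------------------------------------------------- #
# operations
# --------------------------------------------------------------------------- #


def select_remote(
    myocardium_mask: np.ndarray,
    lesion_sector,
    width_deg: float = DEFAULT_REMOTE_WIDTH_DEG,
    voxel_size: tuple[float, float, float] = (1.9, 1.9, 5.0),
    center_rc: tuple[float, float] | None = None,
) -> np.ndarray:
    """Myocardial sector antipodal to the lesion, on every slice.

    ``lesion_sector`` is either ``(center_deg, width_deg)`` or a lesion
    mask whose circular centroid defines the lesion direction.
    """
    myocardium_mask = np.asarray(myocardium_mask, dtype=bool)
    if not myocardium_mask.any():
        raise DataError("empty myocardium mask")
    S, R, C = myocardium_mask.shape
    if center_rc is None:
        idx = np.argwhere(myocardium_mask)
        center_rc = (float(idx[:, 1].mean()), float(idx[:, 2].mean()))
    _, theta = polar_grid((R, C), center_rc, voxel_size)

    if isinstance(lesion_sector, np.ndarray):
        lesion_center = _lesion_centroid_angle(np.asarray(lesion_sector, dtype=bool), theta)
        lesion_width = None
    else:
        lesion_center, lesion_width = float(lesion_sector[0]), float(lesion_sector[1])
    if not (0.0 < width_deg < 360.0):
        raise ConfigurationError(f"remote width must lie in (0, 360); got {width_deg}")
    if lesion_width is not None and width_deg + lesion_width > 360.0:
        raise ConfigurationError(
            f"remote width {width_deg} deg would overlap a lesion sector of "
            f"{lesion_width} deg on the opposite side"
        )
    remote_center = (lesion_center + 180.0) % 360.0
    sector = in_sector(theta, remote_center, width_deg)
    return myocardium_mask & sector[None, ...]


def segment_hemorrhage(
    t2star_map: ParameterMap,
    myocardium_mask: np.ndarray,
    threshold_ms: float = DEFAULT_HEMORRHAGE_THRESHOLD_MS,
    min_component_size: int = DEFAULT_MIN_COMPONENT,
) -> LesionMask:
    """Voxels with valid T2* strictly below ``threshold_ms``, inside the myocardium."""
    myocardium_mask = np.asarray(myocardium_mask, dtype=bool)
    if myocardium_mask.shape != t2star_map.grid_shape:
        raise DimensionError("myocardium mask grid does not match the T2* map")
    core = myocardium_mask & t2star_map.valid & (t2star_map.relaxation_time < threshold_ms)
    mask = _min_size_filter(core, min_component_size)
    return LesionMask(
        "hemorrhage",
        mask,
        provenance={
            "criterion": "t2star_below_threshold",
            "threshold_ms": float(threshold_ms),
            "strict_inequality": True,
            "min_component_size": int(min_component_size),
            "raw_voxels": int(core.sum()),
        },
    )


def segment_edema(
    t2_map: ParameterMap,
    myocardium_mask: np.ndarray,
    remote: RemoteReference,
    companion_cores: tuple = (),
    min_component_size: int = DEFAULT_MIN_COMPONENT,
    sd_multiplier: float = 2.0,
) -> LesionMask:
    """Elevated-T2 voxels plus enclosed/known hypointense cores.

    The threshold component takes valid T2 strictly above
    ``remote.mean_t2 + sd_multiplier * remote.sd_t2``.  Hypointense
    voxels (below the remote mean) are folded in when they belong to a
    supplied hemorrhage/MVO mask or form a region enclosed by the
    threshold component, using the same enclosed-region growing as MVO
    segmentation.
    """
    myocardium_mask = np.asarray(myocardium_mask, dtype=bool)
    if myocardium_mask.shape != t2_map.grid_shape:
        raise DimensionError("myocardium mask grid does not match the T2 map")
    if not (np.isfinite(remote.mean_t2) and np.isfinite(remote.sd_t2)):
        raise ConfigurationError(
            "remote T2 statistics are undefined; build a RemoteReference via "
            "select_remote + RemoteReference.from_maps first"
        )
    cutoff = remote.mean_t2 + sd_multiplier * remote.sd_t2
    threshold_comp = myocardium_mask & t2_map.valid & (t2_map.relaxation_time > cutoff)

    companion = np.zeros_like(myocardium_mask)
    for core in companion_cores:
        arr = core.mask if isinstance(core, LesionMask) else np.asarray(core, dtype=bool)
        if arr.shape != myocardium_mask.shape:
            raise DimensionError("companion core grid does not match the T2 map")
        companion |= arr
    companion &= myocardium_mask

    hypo = (
        myocardium_mask
        & t2_map.valid
        & (t2_map.relaxation_time < remote.mean_t2)
        & ~threshold_comp
    )
    fill = _enclosed_components(hypo & ~companion, threshold_comp | companion) | companion
    mask = _min_size_filter(threshold_comp | fill, min_component_size)
    return LesionMask(
        "edema",
        mask,
        provenance={
            "criterion": "t2_above_remote_plus_sd",
            "remote_mean_ms": float(remote.mean_t2),
            "remote_sd_ms": float(remote.sd_t2),
            "sd_multiplier": float(sd_multiplier),
            "cutoff_ms": float(cutoff),
            "threshold_voxels": int(threshold_comp.sum()),
            "core_fill_voxels": int((fill & ~threshold_comp).sum()),
            "min_component_size": int(min_component_size),
        },
    )


def _lge_array(lge) -> np.ndarray:
    # accept an ImageSeries (single frame) or a bare 3-D array
    if hasattr(lge, "frame"):
        return lge.frame(0)
    arr = np.asarray(lge, dtype=float)
    if arr.ndim == 4:
        arr = arr[..., 0]
    return arr


def segment_infarct_fwhm(
    lge,
    myocardium_mask: np.ndarray,
    seed_region: np.ndarray | None = None,
    remote_mask: np.ndarray | None = None,
    floor_sd_multiple: float = DEFAULT_ENHANCEMENT_FLOOR_SD,
    min_component_size: int = DEFAULT_MIN_COMPONENT,
) -> LesionMask:
    """Full-width-half-maximum infarct segmentation on one LGE volume.

    The reference maximum is taken over the whole myocardium (or over
    ``seed_region`` when an operator supplies one) for the 3-D volume.
    When remote statistics are available and the reference maximum does
    not exceed ``remote mean + floor_sd_multiple * SD``, the volume is
    declared non-enhancing and an empty mask is returned (the +HEM
    pathway).  Enclosed hypoenhanced voxels are *not* added here; that
    is :func:`segment_mvo`'s job.
    """
    img = _lge_array(lge)
    myocardium_mask = np.asarray(myocardium_mask, dtype=bool)
    if myocardium_mask.shape != img.shape:
        raise DimensionError("myocardium mask grid does not match the LGE image")
    if not myocardium_mask.any():
        raise DataError("empty myocardium mask")
    search = myocardium_mask if seed_region is None else (myocardium_mask & np.asarray(seed_region, dtype=bool))
    if not search.any():
        raise ConfigurationError("seed region does not intersect the myocardium")
    reference_max = float(img[search].max())

    prov: dict = {
        "criterion": "full_width_half_maximum",
        "reference_max": reference_max,
        "half_max": reference_max / 2.0,
        "seeded": seed_region is not None,
        "floor_sd_multiple": float(floor_sd_multiple),
        "min_component_size": int(min_component_size),
    }
    if remote_mask is not None:
        rm = np.asarray(remote_mask, dtype=bool) & myocardium_mask
        if rm.any():
            rmean = float(img[rm].mean())
            rsd = float(img[rm].std(ddof=1)) if rm.sum() > 1 else 0.0
            prov.update(remote_mean=rmean, remote_sd=rsd)
            if reference_max <= rmean + floor_sd_multiple * rsd:
                prov["note"] = "below_enhancement_floor"
                return LesionMask("infarct", np.zeros_like(myocardium_mask), prov)
    mask = _min_size_filter(myocardium_mask & (img >= reference_max / 2.0), min_component_size)
    return LesionMask("infarct", mask, prov)


def segment_mvo(
    lge,
    infarct_mask: np.ndarray,
    seed_point: tuple[int, int, int] | None = None,
    min_component_size: int = DEFAULT_MIN_COMPONENT,
) -> LesionMask:
    """Hypoenhanced core enclosed by the infarct, by constrained front growth.

    Candidate voxels fall below half the infarct's reference maximum and
    do not belong to the infarct; the front propagates through them with
    6-connectivity and stops at the infarct rim.  Regions whose exterior
    touches anything other than infarct (e.g. the LV cavity) are not
    enclosed and are discarded.
    """
    img = _lge_array(lge)
    infarct_mask = np.asarray(infarct_mask, dtype=bool)
    if infarct_mask.shape != img.shape:
        raise DimensionError("infarct mask grid does not match the LGE image")
    if not infarct_mask.any():
        raise DataError("segment_mvo needs a non-empty infarct mask")
    reference_max = float(img[infarct_mask].max())
    threshold = reference_max / 2.0
    candidates = ~infarct_mask & (img < threshold)
    enclosed = _enclosed_components(candidates, infarct_mask)

    prov: dict = {
        "criterion": "enclosed_hypoenhancement_growth",
        "reference_max": reference_max,
        "threshold": threshold,
        "min_component_size": int(min_component_size),
    }
    if seed_point is not None:
        seed_point = tuple(int(v) for v in seed_point)
        bbox = tuple(
            (int(idx.min()), int(idx.max())) for idx in np.nonzero(infarct_mask)
        )
        if any(not (lo <= p <= hi) for p, (lo, hi) in zip(seed_point, bbox)):
            raise ConfigurationError(
                f"seed point {seed_point} lies outside the infarct bounding region {bbox}"
            )
        prov["seed_point"] = seed_point
        if not enclosed[seed_point]:
            return LesionMask("mvo", np.zeros_like(infarct_mask), prov)
        source = seed_point
    else:
        if not enclosed.any():
            return LesionMask("mvo", np.zeros_like(infarct_mask), prov)
        flat = np.where(enclosed.ravel(), img.ravel(), np.inf)
        source = np.unravel_index(int(np.argmin(flat)), img.shape)
        prov["seed_point"] = tuple(int(v) for v in source)
    labels, _ = ndimage.label(enclosed, structure=SIX_CONN)
    grown = labels == labels[source]
    mask = _min_size_filter(grown, min_component_size)
    return LesionMask("mvo", mask, prov)
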