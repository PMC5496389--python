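"""Synthetic LV short-axis phantom with known relaxation ground truth.

The phantom emulates a left-ventricular short-axis stack: the myocardium
is an annulus per slice, and an anteroseptal lesion occupies a
configurable angular sector.  The lesion is composed of up to four
components whose presence is dictated by the experimental arm:

========  ==========================================================
arm       components
========  ==========================================================
healthy   none
+HEM      edema shell + hemorrhagic core (no infarct, no MVO)
I-HEM     edema shell + hyperenhancing infarct (no hemorrhage/MVO)
I+HEM     edema + hemorrhage + infarct, MVO optional
========  ==========================================================

Geometry is rasterized by testing voxel centers against the analytic
annulus/sector; the angular interval is half-open ``[theta0, theta1)``
so sector boundaries are never double-labeled.  Geometry carries no
randomness — only signal noise is random, driven by the spec seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import ImageSeries
from .errors import ConfigurationError, DimensionError, ProtocolError

__all__ = [
    "ARMS",
    "T2PREP_TES",
    "GRE_TES",
    "ANTEROSEPTAL_CENTER_DEG",
    "AcquisitionProtocol",
    "Geometry",
    "Tissue",
    "Noise",
    "Cine",
    "PhantomSpec",
    "PhantomGroundTruth",
    "build_phantom",
    "simulate_t2prep_series",
    "simulate_gre_series",
    "simulate_lge_image",
    "simulate_cine_masks",
]

ARMS = ("healthy", "+HEM", "I-HEM", "I+HEM")

#: T2-preparation times of the mapping sequence (ms).
T2PREP_TES: tuple[float, ...] = (2.9, 24.3, 45.6, 88.2, 184.2)

#: Multi-echo gradient-echo times: 8 echoes evenly spanning 1.4-15.8 ms.
GRE_TES: tuple[float, ...] = tuple(
    round(float(t), 3) for t in np.linspace(1.4, 15.8, 8)
)

#: Supported echo-time window of the gradient-echo sequence (ms).
GRE_TE_WINDOW = (1.0, 20.0)

#: Angular convention: theta = atan2(row - cr, col - cc) in degrees, mod 360,
#: measured in voxel-index space.  The default lesion sits at 120 deg
#: ("anteroseptal" by convention of this package).
ANTEROSEPTAL_CENTER_DEG = 120.0

_SIX_CONN = ndimage.generate_binary_structure(3, 1)


# --------------------------------------------------------------------------- #
# spec dataclasses
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Echo/preparation-time schedule plus slice geometry for one contrast."""

    contrast_kind: str
    echo_times: tuple[float, ...]
    voxel_size: tuple[float, float, float] = (1.9, 1.9, 5.0)
    n_slices: int = 10
    matrix: tuple[int, int] = (128, 128)

    def __post_init__(self) -> None:
        if self.contrast_kind not in ("t2prep", "me_gre", "lge", "cine"):
            raise ProtocolError(f"unknown contrast kind {self.contrast_kind!r}")
        t = np.asarray(self.echo_times, dtype=float)
        if self.contrast_kind in ("t2prep", "me_gre"):
            if t.size == 0:
                raise ProtocolError(f"{self.contrast_kind} needs a non-empty echo schedule")
        if self.contrast_kind == "lge" and t.size > 1:
            raise ProtocolError("lge protocol takes at most one (inversion) time")
        if t.size and (np.any(t <= 0) or np.any(np.diff(t) <= 0)):
            raise ProtocolError(f"echo_times must be strictly increasing, > 0; got {tuple(t)}")
        if any(v <= 0 for v in self.voxel_size):
            raise ProtocolError(f"voxel_size must be > 0; got {self.voxel_size}")
        if self.n_slices < 1:
            raise ProtocolError("n_slices must be >= 1")
        object.__setattr__(self, "echo_times", tuple(float(x) for x in t))

    @classmethod
    def t2prep(cls, **kw) -> "AcquisitionProtocol":
        return cls("t2prep", T2PREP_TES, **kw)

    @classmethod
    def me_gre(cls, echo_times: tuple[float, ...] = GRE_TES, **kw) -> "AcquisitionProtocol":
        t = np.asarray(echo_times, dtype=float)
        lo, hi = GRE_TE_WINDOW
        if t.size and (t.min() < lo or t.max() > hi):
            raise ProtocolError(
                f"gradient-echo times must lie within {GRE_TE_WINDOW} ms; got {tuple(t)}"
            )
        return cls("me_gre", tuple(t), **kw)

    @classmethod
    def lge(cls, inversion_time_ms: float, **kw) -> "AcquisitionProtocol":
        return cls("lge", (float(inversion_time_ms),), **kw)


@dataclass(frozen=True)
class Geometry:
    """Annulus + lesion-sector geometry, all lengths in mm, angles in degrees."""

    endo_radius_mm: float = 12.0
    epi_radius_mm: float = 22.0
    center_rc: tuple[float, float] | None = None  # default: grid center
    lesion_theta_center_deg: float = ANTEROSEPTAL_CENTER_DEG
    lesion_theta_width_deg: float = 90.0
    edema_slices: tuple[int, int] = (2, 7)  # inclusive slice range
    edema_transmurality: float = 1.0
    infarct_width_frac: float = 0.7
    infarct_transmurality: float = 0.7
    infarct_slices: tuple[int, int] | None = None  # default: edema_slices
    # band bounds sit >= one in-plane voxel away from endo/epi so the core
    # stays 6-enclosed by edematous myocardium after rasterization
    hemorrhage_width_frac: float = 0.45
    hemorrhage_radial_band: tuple[float, float] = (0.2, 0.6)
    hemorrhage_slices: tuple[int, int] | None = None  # default: interior of edema
    mvo_fraction: float = 0.0


@dataclass(frozen=True)
class Tissue:
    """True tissue parameters (ms except the dimensionless amplitude).

    LGE compartments are parameterized by a static effective T1 only; the
    defaults are documented modelling assumptions, not values calibrated
    to any measurement.
    """

    remote_t2_ms: float = 38.0
    remote_t2star_ms: float = 35.0
    edema_t2_ms: float = 50.0
    hemorrhage_t2star_ms: float = 14.0
    hemorrhage_t2_ms: float = 28.0
    t1_remote_ms: float = 400.0
    t1_infarct_ms: float = 120.0
    t1_mvo_ms: float = 520.0
    amplitude: float = 100.0


@dataclass(frozen=True)
class Noise:
    model: str = "rician"  # rician | gaussian | none
    snr: float = 20.0

    def __post_init__(self) -> None:
        if self.model not in ("rician", "gaussian", "none"):
            raise ConfigurationError(f"unknown noise model {self.model!r}")
        if self.model != "none" and not self.snr > 0:
            raise ConfigurationError("noise SNR must be > 0")


@dataclass(frozen=True)
class Cine:
    edv_ml: float = 60.0
    esv_ml: float = 30.0
    n_phases: int = 20


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic study."""

    arm: str = "healthy"
    matrix: tuple[int, int] = (128, 128)
    n_slices: int = 10
    voxel_size: tuple[float, float, float] = (1.9, 1.9, 5.0)
    geometry: Geometry = field(default_factory=Geometry)
    tissue: Tissue = field(default_factory=Tissue)
    noise: Noise = field(default_factory=Noise)
    cine: Cine = field(default_factory=Cine)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.arm not in ARMS:
            raise ConfigurationError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        g, t, c = self.geometry, self.tissue, self.cine
        if not (0 < g.endo_radius_mm < g.epi_radius_mm):
            raise ConfigurationError("need 0 < endo_radius < epi_radius")
        if not (0.0 <= g.lesion_theta_center_deg < 360.0):
            raise ConfigurationError("lesion sector center must lie in [0, 360)")
        if not (0.0 < g.lesion_theta_width_deg < 360.0):
            raise ConfigurationError("lesion sector width must lie in (0, 360)")
        if not (t.edema_t2_ms > t.remote_t2_ms):
            raise ConfigurationError("edema T2 must exceed remote T2")
        if not (t.hemorrhage_t2star_ms < 20.0 <= t.remote_t2star_ms):
            raise ConfigurationError("need hemorrhage T2* < 20 ms <= remote T2*")
        if not (0.0 < t.hemorrhage_t2_ms < t.remote_t2_ms):
            raise ConfigurationError("hemorrhagic-core T2 must be positive and below remote T2")
        if not (0.0 <= g.mvo_fraction < 1.0):
            raise ConfigurationError("mvo_fraction must lie in [0, 1)")
        if g.mvo_fraction > 0 and self.arm != "I+HEM":
            raise ConfigurationError(
                f"arm {self.arm!r} cannot carry MVO (mvo_fraction > 0 is valid for I+HEM only)"
            )
        if not (c.edv_ml > c.esv_ml > 0):
            raise ConfigurationError("cine requires EDV > ESV > 0")
        if c.n_phases < 1:
            raise ConfigurationError("cine n_phases must be >= 1")
        lo, hi = g.edema_slices
        if not (0 <= lo <= hi < self.n_slices):
            raise ConfigurationError(f"edema_slices {g.edema_slices} outside stack of {self.n_slices}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return (self.n_slices, self.matrix[0], self.matrix[1])

    def center_rc(self) -> tuple[float, float]:
        if self.geometry.center_rc is not None:
            return self.geometry.center_rc
        return ((self.matrix[0] - 1) / 2.0, (self.matrix[1] - 1) / 2.0)

    def with_arm(self, arm: str) -> "PhantomSpec":
        """Same study with a different arm (used for baseline = healthy)."""
        g = self.geometry
        if arm != "I+HEM" and g.mvo_fraction > 0:
            g = replace(g, mvo_fraction=0.0)
        return replace(self, arm=arm, geometry=g)


@dataclass(frozen=True)
class PhantomGroundTruth:
    """True parameter maps and component masks; the recovery oracle."""

    true_t2_map: np.ndarray
    true_t2star_map: np.ndarray
    true_t1eff_map: np.ndarray
    amplitude_map: np.ndarray
    myocardium_mask: np.ndarray
    lv_cavity_mask: np.ndarray
    hemorrhage_mask: np.ndarray
    edema_mask: np.ndarray
    infarct_mask: np.ndarray
    mvo_mask: np.ndarray
    spec: PhantomSpec

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.myocardium_mask.shape

    def component_masks(self) -> dict[str, np.ndarray]:
        return {
            "hemorrhage": self.hemorrhage_mask,
            "edema": self.edema_mask,
            "infarct": self.infarct_mask,
            "mvo": self.mvo_mask,
        }


# --------------------------------------------------------------------------- #
# geometry helpers
# --------------------------------------------------------------------------- #


def polar_grid(
    matrix: tuple[int, int],
    center_rc: tuple[float, float],
    voxel_size: tuple[float, float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Radius (mm) and angle (deg, [0, 360)) of each voxel center in one slice."""
    dx, dy = voxel_size[0], voxel_size[1]
    rows = (np.arange(matrix[0]) - center_rc[0])[:, None] * dy
    cols = (np.arange(matrix[1]) - center_rc[1])[None, :] * dx
    r = np.hypot(rows, cols)
    theta = np.degrees(np.arctan2(rows, cols)) % 360.0
    return r, theta


def in_sector(theta_deg: np.ndarray, center_deg: float, width_deg: float) -> np.ndarray:
    """Half-open angular sector [center - w/2, center + w/2)."""
    start = (center_deg - width_deg / 2.0) % 360.0
    return ((theta_deg - start) % 360.0) < width_deg


def _slice_selector(n_slices: int, bounds: tuple[int, int]) -> np.ndarray:
    sel = np.zeros(n_slices, dtype=bool)
    lo, hi = bounds
    sel[lo : hi + 1] = True
    return sel


def _interior_bounds(bounds: tuple[int, int]) -> tuple[int, int]:
    lo, hi = bounds
    if hi - lo >= 2:
        return (lo + 1, hi - 1)
    return bounds


def _select_mvo(
    infarct: np.ndarray, voxel_size: tuple[float, float, float], fraction: float
) -> np.ndarray:
    """Innermost ``fraction`` of infarct voxels, guaranteed 6-enclosed.

    Candidates are the 6-connectivity erosion of the infarct (every
    neighbor inside the infarct), ranked by Euclidean distance to the
    infarct boundary so the core grows from the inside out.
    """
    n = int(infarct.sum())
    k = int(round(fraction * n))
    mvo = np.zeros_like(infarct)
    if k == 0:
        return mvo
    eroded = ndimage.binary_erosion(infarct, structure=_SIX_CONN)
    cand = np.argwhere(eroded)
    if k > len(cand):
        raise ConfigurationError(
            f"mvo_fraction {fraction} needs {k} enclosed voxels but the infarct "
            f"interior only has {len(cand)}; thicken the infarct geometry"
        )
    # distance sampled in mm so anisotropic voxels rank correctly
    edt = ndimage.distance_transform_edt(infarct, sampling=voxel_size[::-1])
    d = edt[tuple(cand.T)]
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], -d))
    chosen = cand[order[:k]]
    mvo[tuple(chosen.T)] = True
    return mvo


# --------------------------------------------------------------------------- #
# phantom construction
# --------------------------------------------------------------------------- #


def build_phantom(spec: PhantomSpec) -> PhantomGroundTruth:
    """Rasterize the ground truth implied by ``spec``.

    Deterministic: geometry carries no randomness.  Lesion components are
    nested so that hemorrhage lies inside the edematous territory, the
    infarct inside the edema sector, and MVO strictly inside the infarct.
    """
    spec.validate()
    g, t = spec.geometry, spec.tissue
    S, R, C = spec.grid_shape
    r, theta = polar_grid(spec.matrix, spec.center_rc(), spec.voxel_size)

    annulus2d = (r >= g.endo_radius_mm) & (r <= g.epi_radius_mm)
    cavity2d = r < g.endo_radius_mm
    myocardium = np.broadcast_to(annulus2d, (S, R, C)).copy()
    cavity = np.broadcast_to(cavity2d, (S, R, C)).copy()

    wall = g.epi_radius_mm - g.endo_radius_mm
    u = np.clip((r - g.endo_radius_mm) / wall, 0.0, 1.0)  # transmural depth

    empty = np.zeros((S, R, C), dtype=bool)
    edema = empty.copy()
    hemorrhage = empty.copy()
    infarct = empty.copy()
    mvo = empty.copy()

    has_edema = spec.arm in ("+HEM", "I-HEM", "I+HEM")
    has_hemorrhage = spec.arm in ("+HEM", "I+HEM")
    has_infarct = spec.arm in ("I-HEM", "I+HEM")

    if has_edema:
        sector = in_sector(theta, g.lesion_theta_center_deg, g.lesion_theta_width_deg)
        shell2d = annulus2d & sector & (u <= g.edema_transmurality)
        sel = _slice_selector(S, g.edema_slices)
        edema[sel] = shell2d

    if has_infarct:
        w = g.lesion_theta_width_deg * g.infarct_width_frac
        sector = in_sector(theta, g.lesion_theta_center_deg, w)
        core2d = annulus2d & sector & (u <= min(g.infarct_transmurality, g.edema_transmurality))
        bounds = g.infarct_slices if g.infarct_slices is not None else g.edema_slices
        sel = _slice_selector(S, bounds) & _slice_selector(S, g.edema_slices)
        infarct[sel] = core2d

    if has_hemorrhage:
        w = g.lesion_theta_width_deg * g.hemorrhage_width_frac
        sector = in_sector(theta, g.lesion_theta_center_deg, w)
        lo, hi = g.hemorrhage_radial_band
        band2d = annulus2d & sector & (u >= lo) & (u <= min(hi, g.edema_transmurality))
        bounds = (
            g.hemorrhage_slices
            if g.hemorrhage_slices is not None
            else _interior_bounds(g.edema_slices)
        )
        sel = _slice_selector(S, bounds) & _slice_selector(S, g.edema_slices)
        hemorrhage[sel] = band2d

    if spec.arm == "I+HEM" and g.mvo_fraction > 0:
        mvo = _select_mvo(infarct, spec.voxel_size, g.mvo_fraction)

    # parameter maps: remote everywhere, lesion values override
    t2 = np.full((S, R, C), t.remote_t2_ms)
    t2[edema] = t.edema_t2_ms
    t2[hemorrhage] = t.hemorrhage_t2_ms
    t2star = np.full((S, R, C), t.remote_t2star_ms)
    t2star[hemorrhage] = t.hemorrhage_t2star_ms
    t1eff = np.full((S, R, C), t.t1_remote_ms)
    t1eff[infarct] = t.t1_infarct_ms
    t1eff[mvo] = t.t1_mvo_ms
    amplitude = np.where(myocardium, t.amplitude, 0.0)

    gt = PhantomGroundTruth(
        true_t2_map=t2,
        true_t2star_map=t2star,
        true_t1eff_map=t1eff,
        amplitude_map=amplitude,
        myocardium_mask=myocardium,
        lv_cavity_mask=cavity,
        hemorrhage_mask=hemorrhage,
        edema_mask=edema,
        infarct_mask=infarct,
        mvo_mask=mvo,
        spec=spec,
    )
    _check_ground_truth(gt)
    return gt


def _check_ground_truth(gt: PhantomGroundTruth) -> None:
    myo = gt.myocardium_mask
    for name, mask in gt.component_masks().items():
        if np.any(mask & ~myo):
            raise ConfigurationError(f"{name} mask escapes the myocardium")
    if np.any(gt.mvo_mask & ~gt.infarct_mask):
        raise ConfigurationError("mvo mask escapes the infarct")
    if gt.edema_mask.any() and np.any(gt.hemorrhage_mask & ~gt.edema_mask):
        raise ConfigurationError("hemorrhage mask escapes the edematous territory")
    for name, arr in (
        ("T2", gt.true_t2_map),
        ("T2*", gt.true_t2star_map),
        ("amplitude", gt.amplitude_map),
    ):
        vals = arr[myo]
        if not np.all(np.isfinite(vals)) or not np.all(vals > 0):
            raise ConfigurationError(f"non-finite or non-positive true {name} inside myocardium")


# --------------------------------------------------------------------------- #
# signal simulation
# --------------------------------------------------------------------------- #


def _noise_sigma(spec: PhantomSpec, noise: Noise) -> float:
    # sigma defined against the remote proton-density amplitude
    return 0.0 if noise.model == "none" else spec.tissue.amplitude / noise.snr


def _apply_noise(clean: np.ndarray, noise: Noise, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if noise.model == "none" or sigma == 0.0:
        return clean.copy()
    if noise.model == "gaussian":
        # clipped at zero: outputs emulate magnitude images
        return np.clip(clean + rng.normal(0.0, sigma, clean.shape), 0.0, None)
    re = clean + rng.normal(0.0, sigma, clean.shape)
    im = rng.normal(0.0, sigma, clean.shape)
    return np.hypot(re, im)


def _resolve(gt, protocol, noise, seed, kind, default_protocol):
    if protocol is None:
        protocol = default_protocol
    if protocol.contrast_kind != kind:
        raise ProtocolError(f"expected a {kind} protocol, got {protocol.contrast_kind}")
    shape = (protocol.n_slices, *protocol.matrix)
    if shape != gt.grid_shape:
        raise DimensionError(
            f"protocol grid {shape} does not match phantom grid {gt.grid_shape}"
        )
    noise = gt.spec.noise if noise is None else noise
    seed = gt.spec.seed if seed is None else seed
    return protocol, noise, seed


def _decay_series(gt, tmap, protocol, noise, seed, kind) -> ImageSeries:
    te = np.asarray(protocol.echo_times)
    clean = gt.amplitude_map[..., None] * np.exp(-te / tmap[..., None])
    rng = np.random.default_rng(seed)
    data = _apply_noise(clean, noise, _noise_sigma(gt.spec, noise), rng)
    return ImageSeries(
        data, tuple(te), kind, protocol.voxel_size, meta={"seed": seed, "noise": noise.model}
    )


def simulate_t2prep_series(
    gt: PhantomGroundTruth,
    protocol: AcquisitionProtocol | None = None,
    noise: Noise | None = None,
    seed: int | None = None,
) -> ImageSeries:
    """Mono-exponential T2-prepared series: S(TE) = A exp(-TE/T2) + noise."""
    default = AcquisitionProtocol.t2prep(
        voxel_size=gt.spec.voxel_size, n_slices=gt.spec.n_slices, matrix=gt.spec.matrix
    )
    protocol, noise, seed = _resolve(gt, protocol, noise, seed, "t2prep", default)
    return _decay_series(gt, gt.true_t2_map, protocol, noise, seed, "t2prep")


def simulate_gre_series(
    gt: PhantomGroundTruth,
    protocol: AcquisitionProtocol | None = None,
    noise: Noise | None = None,
    seed: int | None = None,
) -> ImageSeries:
    """Multi-echo gradient-echo series: S(TE) = A exp(-TE/T2*) + noise."""
    default = AcquisitionProtocol.me_gre(
        voxel_size=gt.spec.voxel_size, n_slices=gt.spec.n_slices, matrix=gt.spec.matrix
    )
    protocol, noise, seed = _resolve(gt, protocol, noise, seed, "me_gre", default)
    te = np.asarray(protocol.echo_times)
    lo, hi = GRE_TE_WINDOW
    if te.min() < lo or te.max() > hi:
        raise ProtocolError(
            f"gradient-echo times must lie within {GRE_TE_WINDOW} ms; got {tuple(te)}"
        )
    return _decay_series(gt, gt.true_t2star_map, protocol, noise, seed, "me_gre")


def default_inversion_time(spec: PhantomSpec) -> float:
    """TI that exactly nulls remote myocardium: exp(-TI/T1_remote) = 1/2."""
    return spec.tissue.t1_remote_ms * math.log(2.0)


def simulate_lge_image(
    gt: PhantomGroundTruth,
    inversion_time: float | None = None,
    noise: Noise | None = None,
    seed: int | None = None,
) -> ImageSeries:
    """Magnitude inversion-recovery image: S = A |1 - 2 exp(-TI/T1_eff)|.

    Remote myocardium nulls at the default TI; infarct (short effective
    T1) recovers and appears bright; the MVO core stays near the null
    point and appears dark inside the enhanced infarct.
    """
    if inversion_time is None:
        inversion_time = default_inversion_time(gt.spec)
    if inversion_time <= 0:
        raise ConfigurationError(f"inversion time must be > 0; got {inversion_time}")
    noise = gt.spec.noise if noise is None else noise
    seed = gt.spec.seed if seed is None else seed
    clean = gt.amplitude_map * np.abs(1.0 - 2.0 * np.exp(-inversion_time / gt.true_t1eff_map))
    rng = np.random.default_rng(seed)
    data = _apply_noise(clean, noise, _noise_sigma(gt.spec, noise), rng)
    return ImageSeries(
        data[..., None],
        (float(inversion_time),),
        "lge",
        gt.spec.voxel_size,
        meta={"seed": seed, "noise": noise.model},
    )


# --------------------------------------------------------------------------- #
# cine masks
# --------------------------------------------------------------------------- #


def simulate_cine_masks(
    spec: PhantomSpec, n_phases: int | None = None
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-phase (lv_cavity, myocardium) masks.

    The cavity voxel count is allocated exactly from the target volume —
    phase 0 hits EDV and mid-cycle hits ESV to within half a voxel — by
    taking the nearest voxels to the LV axis in a fixed deterministic
    order.  The myocardium is the next ring of voxels outward with a
    phase-constant count (incompressibility convention).
    """
    if n_phases is None:
        n_phases = spec.cine.n_phases
    if n_phases < 1:
        raise ConfigurationError("n_phases must be >= 1")
    edv, esv = spec.cine.edv_ml, spec.cine.esv_ml
    if not edv > esv > 0:
        raise ConfigurationError(f"cine requires EDV > ESV > 0; got EDV={edv}, ESV={esv}")

    S, R, C = spec.grid_shape
    dx, dy, dz = spec.voxel_size
    vox_ml = dx * dy * dz / 1000.0
    r, _ = polar_grid(spec.matrix, spec.center_rc(), spec.voxel_size)
    flat_order = np.lexsort(
        (np.tile(np.arange(C), R), np.repeat(np.arange(R), C), r.ravel())
    )

    g = spec.geometry
    wall_area = math.pi * (g.epi_radius_mm**2 - g.endo_radius_mm**2)
    myo_per_slice = max(1, int(round(wall_area / (dx * dy))))

    cavity_masks, myo_masks = [], []
    for p in range(n_phases):
        frac = (1.0 + math.cos(2.0 * math.pi * p / n_phases)) / 2.0
        target_ml = esv + (edv - esv) * frac
        k_total = int(round(target_ml / vox_ml))
        base, rem = divmod(k_total, S)
        cavity = np.zeros((S, R, C), dtype=bool)
        myo = np.zeros((S, R, C), dtype=bool)
        for s in range(S):
            k_s = base + (1 if s < rem else 0)
            flat_cav = flat_order[:k_s]
            flat_myo = flat_order[k_s : k_s + myo_per_slice]
            cavity[s].ravel()[flat_cav] = True
            myo[s].ravel()[flat_myo] = True
        cavity_masks.append(cavity)
        myo_masks.append(myo)
    return cavity_masks, myo_masks
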