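"""Per-voxel mono-exponential relaxometry.

Fits ``S(TE) = A exp(-TE/T)`` to every masked voxel of a multi-echo
series by least squares: a closed-form log-linear regression on the
strictly positive samples provides the initial estimate, followed by a
damped Gauss-Newton refinement of the signal-space objective.  The
refinement is vectorized across voxels, so whole-map fits are a handful
of dense 2x2 solves rather than per-voxel optimizer calls.

Voxels whose signal does not decay (non-positive log-linear slope, or a
refined time at/above the cap) are flagged invalid rather than reported
as arbitrarily long times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ImageSeries
from .errors import DimensionError, ProtocolError, UndefinedStatisticsError

__all__ = [
    "REASON_OK",
    "REASON_NON_DECAYING",
    "REASON_UNDERFLOW",
    "REASON_OUTSIDE_MASK",
    "ParameterMap",
    "fit_exponential_map",
    "map_summary",
]

REASON_OK = 0
REASON_NON_DECAYING = 1
REASON_UNDERFLOW = 2
REASON_OUTSIDE_MASK = 3

#: Longest reportable relaxation time (ms); anything slower is flagged.
DEFAULT_CAP_MS = 500.0


@dataclass(frozen=True)
class ParameterMap:
    """Per-voxel fit of a mono-exponential decay.

    ``relaxation_time`` is in ms; invalid voxels carry a reason code
    (non-decaying voxels hold the cap value, underflow/outside-mask
    voxels hold NaN).
    """

    relaxation_time: np.ndarray
    amplitude: np.ndarray
    residual_norm: np.ndarray
    valid: np.ndarray
    reason: np.ndarray
    contrast_kind: str
    cap_ms: float = DEFAULT_CAP_MS

    def __post_init__(self) -> None:
        shape = self.relaxation_time.shape
        for name in ("amplitude", "residual_norm", "valid", "reason"):
            if getattr(self, name).shape != shape:
                raise DimensionError(f"ParameterMap field {name} shape differs from map grid")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.relaxation_time.shape


def _loglinear_init(y: np.ndarray, t: np.ndarray):
    """Weighted linear regression of log(S) on TE over strictly positive samples.

    Returns (slope, intercept, n_positive); entries with < 2 positive
    samples get NaN slope.
    """
    pos = y > 0
    npos = pos.sum(axis=1)
    logy = np.where(pos, np.log(np.where(pos, y, 1.0)), 0.0)
    w = pos.astype(float)
    sw = npos.astype(float)
    sx = (w * t).sum(axis=1)
    sy = logy.sum(axis=1)
    sxx = (w * t * t).sum(axis=1)
    sxy = (logy * t).sum(axis=1)
    den = sw * sxx - sx * sx
    ok = (npos >= 2) & (den > 0)
    slope = np.full(y.shape[0], np.nan)
    intercept = np.full(y.shape[0], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope[ok] = (sw * sxy - sx * sy)[ok] / den[ok]
        intercept[ok] = (sy[ok] - slope[ok] * sx[ok]) / sw[ok]
    return slope, intercept, npos


def _gauss_newton(y, t, A, Rv, tol, max_iter):
    """Damped Gauss-Newton on (A, R=1/T) for S = A exp(-R t), vectorized.

    Levenberg-style per-voxel damping: steps that do not reduce the cost
    are rejected and the damping increased.
    """
    n = y.shape[0]
    lam = np.full(n, 1e-3)
    f = A[:, None] * np.exp(-Rv[:, None] * t)
    cost = ((y - f) ** 2).sum(axis=1)
    active = np.ones(n, dtype=bool)
    tiny = np.finfo(float).tiny
    for _ in range(max_iter):
        if not active.any():
            break
        e = np.exp(-Rv[:, None] * t)
        f = A[:, None] * e
        r = y - f
        ja = e
        jr = -t * f
        a11 = (ja * ja).sum(axis=1)
        a12 = (ja * jr).sum(axis=1)
        a22 = (jr * jr).sum(axis=1)
        g1 = (ja * r).sum(axis=1)
        g2 = (jr * r).sum(axis=1)
        m11 = a11 * (1.0 + lam)
        m22 = a22 * (1.0 + lam)
        det = m11 * m22 - a12 * a12
        solvable = active & (det > tiny)
        dA = np.zeros(n)
        dR = np.zeros(n)
        dA[solvable] = (m22 * g1 - a12 * g2)[solvable] / det[solvable]
        dR[solvable] = (m11 * g2 - a12 * g1)[solvable] / det[solvable]
        A_new = A + dA
        R_new = Rv + dR
        f_new = A_new[:, None] * np.exp(-np.clip(R_new[:, None], 0, None) * t)
        cost_new = ((y - f_new) ** 2).sum(axis=1)
        accept = solvable & (R_new > 0) & (cost_new <= cost)
        A = np.where(accept, A_new, A)
        Rv = np.where(accept, R_new, Rv)
        cost = np.where(accept, cost_new, cost)
        lam = np.where(accept, np.maximum(lam / 3.0, 1e-12), np.minimum(lam * 10.0, 1e12))
        step = np.maximum(
            np.abs(dA) / (np.abs(A) + 1e-30), np.abs(dR) / (np.abs(Rv) + 1e-30)
        )
        converged = accept & (step < tol)
        stuck = active & ~solvable & (lam >= 1e12)
        active = active & ~converged & ~stuck
    return A, Rv, cost


def fit_exponential_map(
    series: ImageSeries,
    mask: np.ndarray | None = None,
    *,
    method: str = "nonlinear",
    cap_ms: float = DEFAULT_CAP_MS,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ParameterMap:
    """Fit A exp(-TE/T) per masked voxel; see module docstring.

    Parameters
    ----------
    series:
        Multi-echo series with at least two echoes.
    mask:
        Boolean 3-D mask of voxels to fit; default fits every voxel.
    method:
        ``"nonlinear"`` (log-linear init + Gauss-Newton refinement,
        default) or ``"loglinear"`` (closed form only).
    """
    if series.n_times < 2:
        raise ProtocolError(f"need >= 2 echoes to fit a decay; got {series.n_times}")
    if method not in ("nonlinear", "loglinear"):
        raise ValueError(f"unknown method {method!r}")
    shape = series.grid_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise DimensionError(f"mask shape {mask.shape} does not match series grid {shape}")

    t = np.asarray(series.times)
    y = series.data[mask]  # (N, E)
    n = y.shape[0]

    slope, intercept, npos = _loglinear_init(y, t)
    underflow = npos < 2
    with np.errstate(invalid="ignore"):
        nondecay = ~underflow & ~(slope < 0)

    T = np.full(n, np.nan)
    A = np.full(n, np.nan)
    fitted = ~underflow & ~nondecay
    T[fitted] = -1.0 / slope[fitted]
    A[fitted] = np.exp(intercept[fitted])
    # log-linear time already at/above cap: treat as non-decaying
    overcap = fitted & (T >= cap_ms)
    nondecay |= overcap
    fitted &= ~overcap

    resid = np.zeros(n)
    if fitted.any():
        if method == "nonlinear":
            Af, Rf, cost = _gauss_newton(
                y[fitted], t, A[fitted], 1.0 / T[fitted], tol, max_iter
            )
            Tf = 1.0 / Rf
            A[fitted] = Af
            T[fitted] = Tf
            resid[fitted] = np.sqrt(cost)
        else:
            model = A[fitted, None] * np.exp(-t / T[fitted, None])
            resid[fitted] = np.sqrt(((y[fitted] - model) ** 2).sum(axis=1))
        overcap = fitted & (T >= cap_ms)
        nondecay |= overcap
        fitted &= ~overcap
        bad_amp = fitted & ~(A > 0)
        underflow |= bad_amp
        fitted &= ~bad_amp

    T = np.where(nondecay, cap_ms, T)
    T = np.where(underflow, np.nan, T)

    reason_flat = np.full(n, REASON_OK, dtype=np.uint8)
    reason_flat[nondecay] = REASON_NON_DECAYING
    reason_flat[underflow] = REASON_UNDERFLOW

    full = lambda fill, dtype=float: np.full(shape, fill, dtype=dtype)  # noqa: E731
    time_map = full(np.nan)
    amp_map = full(np.nan)
    res_map = full(np.nan)
    valid_map = full(False, bool)
    reason_map = full(REASON_OUTSIDE_MASK, np.uint8)
    time_map[mask] = T
    amp_map[mask] = A
    res_map[mask] = resid
    valid_map[mask] = reason_flat == REASON_OK
    reason_map[mask] = reason_flat
    return ParameterMap(
        relaxation_time=time_map,
        amplitude=amp_map,
        residual_norm=res_map,
        valid=valid_map,
        reason=reason_map,
        contrast_kind=series.contrast_kind,
        cap_ms=cap_ms,
    )


def map_summary(pmap: ParameterMap, roi_mask: np.ndarray) -> tuple[float, float, int]:
    """(mean, sample SD, n_valid) of the relaxation time over valid ROI voxels.

    Raises :class:`UndefinedStatisticsError` when the ROI holds no valid
    voxel, so callers cannot mistake an unusable ROI for a zero reading.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != pmap.grid_shape:
        raise DimensionError(
            f"ROI shape {roi_mask.shape} does not match map grid {pmap.grid_shape}"
        )
    vals = pmap.relaxation_time[roi_mask & pmap.valid]
    n = int(vals.size)
    if n == 0:
        raise UndefinedStatisticsError("no valid voxels in ROI; statistics undefined")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return mean, sd, n
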