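"""T2-vs-T2* association by ordinary least squares.

One point per subject (infarct-zone mean T2* on the abscissa, mean T2 on
the ordinate); non-hemorrhagic subjects are excluded from the fit by
default but may still be plotted alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, UndefinedSlopeError

__all__ = ["RegressionResult", "fit_t2_vs_t2star", "DEFAULT_INCLUDE_ARMS"]

DEFAULT_INCLUDE_ARMS = ("+HEM", "I+HEM")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int
    residual_sd: float
    slope_se: float
    included_arms: tuple[str, ...] | None = None

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n": self.n,
            "residual_sd": self.residual_sd,
            "slope_se": self.slope_se,
            "included_arms": list(self.included_arms) if self.included_arms else None,
        }


def fit_t2_vs_t2star(
    t2star,
    t2,
    arms=None,
    include_arms: tuple[str, ...] | None = DEFAULT_INCLUDE_ARMS,
) -> RegressionResult:
    """OLS of T2 on T2* with intercept and goodness of fit.

    Parameters
    ----------
    t2star, t2:
        Per-subject values (same length).
    arms:
        Optional per-subject arm labels.  When given together with
        ``include_arms``, only subjects from the listed arms enter the
        fit (the default keeps the hemorrhagic arms only).
    """
    x = np.asarray(t2star, dtype=float)
    y = np.asarray(t2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("t2star and t2 must be 1-D sequences of equal length")
    if arms is not None and include_arms is not None:
        sel = np.isin(np.asarray(arms), list(include_arms))
        x, y = x[sel], y[sel]
    n = int(x.size)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 pairs for a reportable fit; got {n}")
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    syy = float(((y - ym) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    if sxx == 0.0:
        raise UndefinedSlopeError("zero variance in T2*; slope undefined")
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_res = max(syy - slope * sxy, 0.0)
    r_squared = 1.0 - ss_res / syy if syy > 0 else 0.0
    residual_sd = float(np.sqrt(ss_res / (n - 2))) if n > 2 else 0.0
    slope_se = residual_sd / np.sqrt(sxx)
    return RegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r_squared),
        n=n,
        residual_sd=residual_sd,
        slope_se=float(slope_se),
        included_arms=tuple(include_arms) if (arms is not None and include_arms) else None,
    )
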