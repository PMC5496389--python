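"""Shared containers and array conventions.

All volumes use 0-based voxel indices in ``(slice, row, col)`` order;
multi-contrast series append the echo/phase axis last, giving
``(slice, row, col, echo)``.  Voxel sizes are ``(dx, dy, dz)`` in mm where
``dx`` is the column pitch, ``dy`` the row pitch and ``dz`` the slice
thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError, ProtocolError

__all__ = ["ImageSeries", "voxel_volume_ml"]


def voxel_volume_ml(voxel_size: tuple[float, float, float]) -> float:
    """Volume of one voxel in millilitres."""
    dx, dy, dz = voxel_size
    return dx * dy * dz / 1000.0


@dataclass(frozen=True)
class ImageSeries:
    """A magnitude image stack indexed by echo/preparation/inversion time.

    Parameters
    ----------
    data:
        Array of shape ``(n_slices, n_rows, n_cols, n_times)``.
    times:
        Strictly increasing times in ms, one per frame.
    contrast_kind:
        One of ``t2prep``, ``me_gre``, ``lge``, ``cine``.
    voxel_size:
        ``(dx, dy, dz)`` in mm.
    """

    data: np.ndarray
    times: tuple[float, ...]
    contrast_kind: str
    voxel_size: tuple[float, float, float] = (1.9, 1.9, 5.0)
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        if data.ndim != 4:
            raise DimensionError(
                f"series data must be 4-D (slice, row, col, echo); got shape {data.shape}"
            )
        if data.shape[-1] != len(self.times):
            raise DimensionError(
                f"series has {data.shape[-1]} frames but {len(self.times)} times"
            )
        t = np.asarray(self.times)
        if len(t) == 0 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ProtocolError(f"times must be strictly increasing and > 0; got {self.times}")
        if any(v <= 0 for v in self.voxel_size):
            raise ProtocolError(f"voxel_size components must be > 0; got {self.voxel_size}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_times(self) -> int:
        return len(self.times)

    def frame(self, index: int) -> np.ndarray:
        """Return one 3-D frame ``(slice, row, col)``."""
        return self.data[..., index]


def check_same_grid(shape: tuple[int, int, int], *arrays: np.ndarray) -> None:
    """Raise :class:`DimensionError` unless every array has the given 3-D shape."""
    for a in arrays:
        if a.shape[:3] != tuple(shape):
            raise DimensionError(f"grid mismatch: expected {tuple(shape)}, got {a.shape[:3]}")
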