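"""Shared fixtures: scaled-down phantoms so the suite stays fast."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from cmrquant.phantom import (
    Cine,
    Geometry,
    Noise,
    PhantomSpec,
    Tissue,
    build_phantom,
)

SMALL_GRID = dict(matrix=(64, 64), n_slices=6, voxel_size=(1.9, 1.9, 5.0))


def small_spec(arm: str, *, noise: str = "none", snr: float = 20.0, seed: int = 0, **geo) -> PhantomSpec:
    """A 64x64x6 spec for one arm, noiseless by default."""
    geometry = {
        "healthy": Geometry(edema_slices=(2, 4)),
        "+HEM": Geometry(lesion_theta_width_deg=40.0, edema_slices=(2, 4)),
        "I-HEM": Geometry(
            lesion_theta_width_deg=70.0,
            edema_slices=(1, 4),
            infarct_width_frac=0.6,
            infarct_transmurality=0.6,
            infarct_slices=(2, 3),
        ),
        "I+HEM": Geometry(
            lesion_theta_width_deg=110.0,
            edema_slices=(0, 5),
            infarct_width_frac=0.75,
            infarct_transmurality=0.8,
            infarct_slices=(1, 4),
            hemorrhage_slices=(2, 3),
            mvo_fraction=0.15,
        ),
    }[arm]
    if geo:
        geometry = replace(geometry, **geo)
    tissue = {
        "healthy": Tissue(),
        "+HEM": Tissue(edema_t2_ms=45.2, hemorrhage_t2star_ms=14.0),
        "I-HEM": Tissue(edema_t2_ms=45.6),
        "I+HEM": Tissue(edema_t2_ms=51.3, hemorrhage_t2star_ms=12.0),
    }[arm]
    return PhantomSpec(
        arm=arm,
        geometry=geometry,
        tissue=tissue,
        noise=Noise(model=noise, snr=snr),
        cine=Cine(),
        seed=seed,
        **SMALL_GRID,
    )


@pytest.fixture(scope="session")
def phantoms_noiseless():
    """Ground truth for every arm on the small grid, noiseless."""
    return {arm: build_phantom(small_spec(arm)) for arm in ("healthy", "+HEM", "I-HEM", "I+HEM")}


@pytest.fixture(scope="session")
def iphem_noiseless(phantoms_noiseless):
    return phantoms_noiseless["I+HEM"]


def uniform_series(value_t, tes, n=64, amplitude=100.0, kind="t2prep", noise_sigma=0.0, seed=0):
    """A flat (1, n, 1) series of identical voxels decaying with time value_t."""
    te = np.asarray(tes, dtype=float)
    clean = amplitude * np.exp(-te / value_t) * np.ones((1, n, 1, 1))
    data = clean
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data = np.hypot(
            clean + rng.normal(0, noise_sigma, clean.shape),
            rng.normal(0, noise_sigma, clean.shape),
        )
    from cmrquant.core import ImageSeries

    return ImageSeries(data, tuple(te), kind)
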