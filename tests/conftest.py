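from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gdr.phantom_io import GridSpec, LesionSpec, MotionSpec, make_static_phantom


@pytest.fixture(scope="session")
def default_grid() -> GridSpec:
    return GridSpec()


@pytest.fixture(scope="session")
def clean_lesion() -> LesionSpec:
    """Homogeneous lesion, uptake 8 over background 1."""
    return LesionSpec(
        center_mm=(39.0, 39.0, 39.0), radii_mm=(12.0, 12.0, 12.0), blob_amplitude=0.0
    )


@pytest.fixture(scope="session")
def textured_lesion() -> LesionSpec:
    return LesionSpec(center_mm=(39.0, 39.0, 34.0), radii_mm=(12.0, 11.0, 10.0))


@pytest.fixture(scope="session")
def no_degradation() -> MotionSpec:
    return MotionSpec(noise_cv=0.0, psf_fwhm_mm=0.0)


@pytest.fixture(scope="session")
def default_motion() -> MotionSpec:
    return MotionSpec(amplitude_mm=(0.0, 0.0, 8.0))


@pytest.fixture(scope="session")
def default_phantom(textured_lesion, default_motion, default_grid):
    return make_static_phantom(textured_lesion, default_motion, default_grid, seed=11)


def random_levels(rng: np.random.Generator, max_shape=(8, 8, 4), n_levels=5,
                  mask_fraction=0.8) -> np.ndarray:
    """Random small level grid (0 = outside mask) with a connected-ish mask."""
    shape = tuple(int(rng.integers(2, s + 1)) for s in max_shape)
    levels = rng.integers(1, n_levels + 1, size=shape)
    mask = rng.random(shape) < mask_fraction
    if not mask.any():
        mask.flat[0] = True
    return np.where(mask, levels, 0)


def make_null_feature_table(
    n_patients: int,
    n_features: int,
    K: int = 8,
    seed: int = 0,
    noise_3d: float = 1.0,
    shift_3d: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Feature-level synthetic table: Gaussian phase values, 3D = 4D mean + noise.

    ``shift_3d`` maps feature name -> multiplicative 3D shift (1.2 = +20%).
    """
    rng = np.random.default_rng(seed)
    shift_3d = shift_3d or {}
    rows = []
    for f in range(n_features):
        name = f"feat_{f:02d}"
        mu_f = 50.0 + 10.0 * rng.standard_normal()
        sd_f = 2.0 + rng.random()
        for p in range(n_patients):
            pid = f"P{p:03d}"
            mu = mu_f + 5.0 * rng.standard_normal()
            phases = mu + sd_f * rng.standard_normal(K)
            for k, v in enumerate(phases):
                rows.append((pid, f"pre4d_phase_{k}", "manual", name, v))
            x3d = phases.mean() * shift_3d.get(name, 1.0)
            x3d += noise_3d * rng.standard_normal() * sd_f / np.sqrt(K)
            rows.append((pid, "pre3d", "manual", name, x3d))
            rows.append((pid, "post3d", "manual", name, mu))
    return pd.DataFrame(
        rows,
        columns=["patient_id", "scan_role", "segmentation", "feature_name", "value"],
    )
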