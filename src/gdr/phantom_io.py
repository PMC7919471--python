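"""Core image data model, NIfTI/manifest I/O, and synthetic gated-PET phantoms.

The phantom generator emulates a heterogeneous lung lesion imaged by PET:
an ellipsoidal uptake region textured with smooth Gaussian blobs, blurred
by the scanner point-spread function, degraded by multiplicative noise,
and displaced per respiratory phase by a periodic breathing pattern.
Static (3D) volumes are the time-average over the breathing cycle, so the
gated phases and the static scan reproduce the 4D-vs-3D blurring
relationship seen in gated acquisitions.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

import nibabel as nib

__all__ = [
    "GeometryError",
    "AlignmentError",
    "ManifestError",
    "ImageVolume",
    "RoiMask",
    "PhaseSeries",
    "Outcome",
    "PatientCase",
    "LesionSpec",
    "MotionSpec",
    "GridSpec",
    "FollowupEffect",
    "CohortSpec",
    "make_static_phantom",
    "make_phase_series",
    "simulate_followup",
    "simulate_cohort",
    "write_case",
    "read_case",
    "write_cohort",
    "read_cohort",
]


class GeometryError(ValueError):
    """Lesion/grid geometry is inconsistent (e.g. lesion outside grid)."""


class AlignmentError(ValueError):
    """Volume and mask do not share grid geometry."""


class ManifestError(ValueError):
    """Cohort manifest is incomplete or inconsistent."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageVolume:
    """A 3D SUV grid with physical spacing, axis order (x, y, z).

    World coordinate of voxel (i, j, k) is ``origin + index * spacing``.
    """

    values: np.ndarray  # 3D, SUV in g/mL
    spacing: tuple[float, float, float]  # mm per voxel, per axis
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3 or min(v.shape) < 1:
            raise GeometryError("volume must be 3D with >= 1 voxel per axis")
        if not np.all(np.isfinite(v)):
            raise ValueError("volume contains non-finite values")
        if np.any(v < 0):
            raise ValueError("SUV values must be >= 0")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError("spacing must be three strictly positive values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class RoiMask:
    """Binary region-of-interest grid paired with an :class:`ImageVolume`."""

    values: np.ndarray  # 3D boolean
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise GeometryError("mask must be 3D")
        object.__setattr__(self, "values", v.astype(bool))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    def check_aligned(self, volume: ImageVolume) -> None:
        if self.shape != volume.shape:
            raise AlignmentError(
                f"mask shape {self.shape} != volume shape {volume.shape}"
            )
        if not np.allclose(self.spacing, volume.spacing) or not np.allclose(
            self.origin, volume.origin
        ):
            raise AlignmentError("mask and volume spacing/origin differ")


@dataclass(frozen=True)
class PhaseSeries:
    """Ordered gated-phase (volume, mask) pairs covering one breathing cycle."""

    phases: tuple[tuple[ImageVolume, RoiMask], ...]

    def __post_init__(self) -> None:
        if len(self.phases) < 3:
            raise GeometryError("a phase series needs K >= 3 phases")
        shape0 = self.phases[0][0].shape
        for vol, mask in self.phases:
            if vol.shape != shape0:
                raise AlignmentError("all phases must share grid geometry")
            mask.check_aligned(vol)

    @property
    def K(self) -> int:
        return len(self.phases)


@dataclass(frozen=True)
class Outcome:
    LR: int = 0
    DM: int = 0
    OS_months: float = 0.0
    OS_event: int = 0

    def __post_init__(self) -> None:
        if self.LR not in (0, 1) or self.DM not in (0, 1) or self.OS_event not in (0, 1):
            raise ValueError("binary labels must be 0 or 1")
        if self.OS_months < 0:
            raise ValueError("OS_months must be >= 0")


@dataclass(frozen=True)
class PatientCase:
    patient_id: str
    pre4d: PhaseSeries
    pre3d: tuple[ImageVolume, RoiMask]
    post3d: tuple[ImageVolume, RoiMask]
    outcome: Outcome
    interval_days: float = 0.0


@dataclass(frozen=True)
class LesionSpec:
    """Analytic lesion: textured ellipsoid over a uniform background."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    uptake_mean: float = 8.0
    background: float = 1.0
    blob_count: int = 12
    blob_amplitude: float = 1.5  # SUV sd scale of texture bumps
    blob_scale_mm: float = 6.0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii_mm):
            raise GeometryError("lesion radii must be > 0")
        if not (self.uptake_mean > self.background > 0):
            raise ValueError("require uptake_mean > background > 0")


@dataclass(frozen=True)
class MotionSpec:
    """Periodic respiratory displacement + scanner degradation model."""

    amplitude_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    K: int = 8
    psf_fwhm_mm: float = 4.8
    noise_cv: float = 0.05
    pattern: str = "cos2n"  # displacement weight cos^(2n)(pi*k/K)
    pattern_exponent: int = 1
    irregular_jitter: float = 0.0  # fractional per-phase amplitude jitter

    def __post_init__(self) -> None:
        if self.K < 3:
            raise ValueError("K must be >= 3")
        if any(a < 0 for a in self.amplitude_mm):
            raise ValueError("amplitude must be >= 0")
        if self.psf_fwhm_mm < 0 or self.noise_cv < 0:
            raise ValueError("psf_fwhm_mm and noise_cv must be >= 0")
        if self.pattern not in ("cos2n",):
            raise ValueError(f"unknown breathing pattern {self.pattern!r}")

    def phase_weights(self, rng: np.random.Generator | None = None) -> np.ndarray:
        """Displacement weight in [0, 1] per phase; peak-to-peak span is 1."""
        k = np.arange(self.K)
        w = np.cos(np.pi * k / self.K) ** (2 * self.pattern_exponent)
        if self.irregular_jitter > 0 and rng is not None:
            w = w * (1.0 + self.irregular_jitter * rng.standard_normal(self.K))
        return w


@dataclass(frozen=True)
class GridSpec:
    shape: tuple[int, int, int] = (40, 40, 40)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))


@dataclass(frozen=True)
class FollowupEffect:
    """Planted change applied to the follow-up scan of a lesion."""

    volume_scale: float = 1.0
    homogenization: float = 0.0  # in [0, 1]; shrinks deviations from lesion mean
    uptake_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.homogenization <= 1.0:
            raise ValueError("homogenization must be in [0, 1]")
        if self.volume_scale <= 0 or self.uptake_scale <= 0:
            raise ValueError("scales must be > 0")


# --------------------------------------------------------------------------
# Phantom construction
# --------------------------------------------------------------------------


def _check_fits(lesion: LesionSpec, motion: MotionSpec, grid: GridSpec) -> None:
    margin = 2.0 * motion.psf_fwhm_mm
    for a in range(3):
        lo = lesion.center_mm[a] - lesion.radii_mm[a] - margin
        hi = (
            lesion.center_mm[a]
            + lesion.radii_mm[a]
            + motion.amplitude_mm[a]
            + margin
        )
        g_lo = grid.origin[a]
        g_hi = grid.origin[a] + (grid.shape[a] - 1) * grid.spacing[a]
        if lo < g_lo or hi > g_hi:
            raise GeometryError(
                f"lesion plus motion plus 2*PSF margin exceeds grid on axis {a}"
            )


def _blob_params(lesion: LesionSpec, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded blob centers (lesion frame, unit-ellipsoid coords) and amplitudes."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7E57]))
    n = lesion.blob_count
    # rejection-free: sample inside unit ball then scale to ellipsoid
    u = rng.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = rng.random(n) ** (1 / 3)
    centers = u * r[:, None]  # unit ball
    amps = rng.standard_normal(n) * lesion.blob_amplitude
    return centers, amps


def _preblur_frame(
    lesion: LesionSpec,
    grid: GridSpec,
    displacement_mm: np.ndarray,
    blob_centers: np.ndarray,
    blob_amps: np.ndarray,
    effect: FollowupEffect | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic (pre-blur, pre-noise) frame and ground-truth mask."""
    eff = effect or FollowupEffect()
    radii = np.asarray(lesion.radii_mm, float) * eff.volume_scale ** (1.0 / 3.0)
    center = np.asarray(lesion.center_mm, float) + np.asarray(displacement_mm, float)

    X, Y, Z = grid.coords()
    dx = (X - center[0]) / radii[0]
    dy = (Y - center[1]) / radii[1]
    dz = (Z - center[2]) / radii[2]
    inside = dx * dx + dy * dy + dz * dz <= 1.0

    vol = np.full(grid.shape, float(lesion.background))
    if not inside.any():
        raise GeometryError("lesion covers no voxel of the grid")

    lesion_vals = np.full(int(inside.sum()), float(lesion.uptake_mean))
    if lesion.blob_count > 0 and lesion.blob_amplitude > 0:
        xs = X[inside]
        ys = Y[inside]
        zs = Z[inside]
        s2 = 2.0 * lesion.blob_scale_mm**2
        tex = np.zeros_like(xs)
        for c, a in zip(blob_centers, blob_amps):
            cw = center + c * radii  # blob center in world coords
            d2 = (xs - cw[0]) ** 2 + (ys - cw[1]) ** 2 + (zs - cw[2]) ** 2
            tex += a * np.exp(-d2 / s2)
        lesion_vals = lesion_vals + tex

    if eff.homogenization > 0:
        m = lesion_vals.mean()
        lesion_vals = m + (1.0 - eff.homogenization) * (lesion_vals - m)
    if eff.uptake_scale != 1.0:
        lesion_vals = lesion.background + eff.uptake_scale * (
            lesion_vals - lesion.background
        )

    vol[inside] = lesion_vals
    np.clip(vol, 0.01 * lesion.background, None, out=vol)
    return vol, inside


def _degrade(
    vol: np.ndarray, grid: GridSpec, motion: MotionSpec, rng: np.random.Generator
) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    out = vol
    if motion.psf_fwhm_mm > 0:
        sigma_mm = motion.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        sigma_vox = [sigma_mm / s for s in grid.spacing]
        out = gaussian_filter(out, sigma=sigma_vox, mode="nearest")
    if motion.noise_cv > 0:
        out = out * (1.0 + motion.noise_cv * rng.standard_normal(out.shape))
        out = np.clip(out, 0.0, None)
    return out


def make_static_phantom(
    lesion: LesionSpec,
    motion: MotionSpec,
    grid: GridSpec = GridSpec(),
    seed: int = 0,
    effect: FollowupEffect | None = None,
    noise_seed: int | None = None,
) -> tuple[ImageVolume, RoiMask]:
    """Simulate an ungated (3D) scan: the time-average over the breathing cycle.

    With zero motion amplitude this is a single motionless frame.  The
    returned mask is the ground-truth (pre-blur) lesion at the
    time-averaged displacement.  ``seed`` fixes the lesion texture;
    ``noise_seed`` (default: same as ``seed``) fixes the noise stream, so
    a repeat scan of the same lesion uses the same ``seed`` with a
    different ``noise_seed``.
    """
    _check_fits(lesion, motion, grid)
    centers, amps = _blob_params(lesion, seed)
    if noise_seed is None:
        noise_seed = seed
    amp = np.asarray(motion.amplitude_mm, float)
    weights = MotionSpec.phase_weights(replace(motion, irregular_jitter=0.0))

    acc = np.zeros(grid.shape)
    for w in weights:
        frame, _ = _preblur_frame(lesion, grid, w * amp, centers, amps, effect)
        acc += frame
    acc /= len(weights)
    _, mask = _preblur_frame(
        lesion, grid, float(weights.mean()) * amp, centers, amps, effect
    )

    rng = np.random.default_rng(np.random.SeedSequence([int(noise_seed), 0x57A7]))
    out = _degrade(acc, grid, motion, rng)
    return (
        ImageVolume(out, grid.spacing, grid.origin),
        RoiMask(mask, grid.spacing, grid.origin),
    )


def make_phase_series(
    lesion: LesionSpec,
    motion: MotionSpec,
    grid: GridSpec = GridSpec(),
    seed: int = 0,
) -> PhaseSeries:
    """Simulate the K gated phases of one breathing cycle.

    Phase k displaces the lesion by ``weight(k) * amplitude`` before blur
    and noise; each phase carries its own ground-truth mask and an
    independent noise realization from the seeded stream.
    """
    _check_fits(lesion, motion, grid)
    centers, amps = _blob_params(lesion, seed)
    amp = np.asarray(motion.amplitude_mm, float)
    jitter_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x917]))
    weights = motion.phase_weights(jitter_rng)

    phases = []
    for k, w in enumerate(weights):
        frame, mask = _preblur_frame(lesion, grid, w * amp, centers, amps)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x4D, k]))
        out = _degrade(frame, grid, motion, rng)
        phases.append(
            (
                ImageVolume(out, grid.spacing, grid.origin),
                RoiMask(mask, grid.spacing, grid.origin),
            )
        )
    return PhaseSeries(tuple(phases))


def simulate_followup(
    lesion: LesionSpec,
    motion: MotionSpec,
    effect: FollowupEffect,
    grid: GridSpec = GridSpec(),
    seed: int = 0,
    noise_seed: int | None = None,
) -> tuple[ImageVolume, RoiMask]:
    """Follow-up 3D scan of the same lesion with a planted effect.

    ``homogenization`` shrinks lesion-internal deviations from the lesion
    mean by ``1 - homogenization``; a no-op effect with the same seed
    reproduces the baseline static phantom bit for bit.
    """
    return make_static_phantom(lesion, motion, grid, seed, effect, noise_seed)


# --------------------------------------------------------------------------
# Cohort simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Per-patient sampling distributions around base lesion/motion specs."""

    lesion: LesionSpec = LesionSpec(
        center_mm=(39.0, 39.0, 34.0), radii_mm=(12.0, 11.0, 10.0)
    )
    motion: MotionSpec = MotionSpec(amplitude_mm=(0.0, 0.0, 4.0))
    grid: GridSpec = GridSpec()
    radii_jitter: float = 0.15  # fractional sd on lesion radii
    uptake_jitter: float = 0.15
    amplitude_jitter: float = 0.25
    effect_jitter: float = 0.0  # fractional sd on planted homogenization


def _sample_patient_specs(
    spec: CohortSpec, rng: np.random.Generator
) -> tuple[LesionSpec, MotionSpec]:
    radii = tuple(
        float(r * np.exp(spec.radii_jitter * rng.standard_normal()))
        for r in spec.lesion.radii_mm
    )
    uptake = float(
        spec.lesion.uptake_mean * np.exp(spec.uptake_jitter * rng.standard_normal())
    )
    uptake = max(uptake, 1.5 * spec.lesion.background)
    lesion = replace(spec.lesion, radii_mm=radii, uptake_mean=uptake)
    amp = tuple(
        float(a * np.exp(spec.amplitude_jitter * rng.standard_normal()))
        for a in spec.motion.amplitude_mm
    )
    motion = replace(spec.motion, amplitude_mm=amp)
    return lesion, motion


def simulate_cohort(
    n: int,
    lr_fraction: float,
    effect_lr: FollowupEffect,
    effect_nolr: FollowupEffect,
    spec: CohortSpec = CohortSpec(),
    seed: int = 0,
) -> list[PatientCase]:
    """Simulate ``n`` patients; ``round(n * lr_fraction)`` receive the LR effect.

    Each case gets a gated pre-treatment series, a static pre-treatment
    scan and a follow-up scan carrying its group's planted effect.  Fully
    reproducible per seed.
    """
    if n < 2:
        raise ValueError("cohort needs n >= 2")
    if not 0.0 <= lr_fraction <= 1.0:
        raise ValueError("lr_fraction must be in [0, 1]")

    n_lr = int(round(n * lr_fraction))
    master = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0]))
    labels = np.zeros(n, dtype=int)
    labels[:n_lr] = 1
    master.shuffle(labels)

    cases: list[PatientCase] = []
    for i in range(n):
        prng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC1, i]))
        lesion, motion = _sample_patient_specs(spec, prng)
        base_effect = effect_lr if labels[i] == 1 else effect_nolr
        if spec.effect_jitter > 0 and base_effect.homogenization > 0:
            h = base_effect.homogenization * np.exp(
                spec.effect_jitter * prng.standard_normal()
            )
            base_effect = replace(base_effect, homogenization=float(np.clip(h, 0, 1)))

        case_seed = int(prng.integers(0, 2**31 - 1))
        post_seed = int(prng.integers(0, 2**31 - 1))
        pre4d = make_phase_series(lesion, motion, spec.grid, case_seed)
        pre3d = make_static_phantom(lesion, motion, spec.grid, case_seed)
        # follow-up: same lesion texture, independent noise realization
        post3d = simulate_followup(
            lesion, motion, base_effect, spec.grid, case_seed, noise_seed=post_seed
        )

        outcome = Outcome(
            LR=int(labels[i]),
            DM=int(prng.random() < 0.4),
            OS_months=float(np.round(prng.exponential(36.0), 1)),
            OS_event=int(prng.random() < 0.5),
        )
        cases.append(
            PatientCase(
                patient_id=f"P{i:03d}",
                pre4d=pre4d,
                pre3d=pre3d,
                post3d=post3d,
                outcome=outcome,
                interval_days=float(prng.integers(10, 90)),
            )
        )
    return cases


# --------------------------------------------------------------------------
# NIfTI + manifest I/O
# --------------------------------------------------------------------------

_MANIFEST_COLUMNS = [
    "patient_id",
    "role",
    "volume_path",
    "mask_path",
    "LR",
    "DM",
    "OS_months",
    "OS_event",
    "interval_days",
]


def _affine(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(
        np.asarray(vol.values, dtype=np.float32), _affine(vol.spacing, vol.origin)
    )
    nib.save(img, str(path))


def write_mask(mask: RoiMask, path: str | Path) -> None:
    img = nib.Nifti1Image(
        mask.values.astype(np.uint8), _affine(mask.spacing, mask.origin)
    )
    nib.save(img, str(path))


def read_volume(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    aff = img.affine
    spacing = tuple(float(x) for x in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(x) for x in aff[:3, 3])
    return ImageVolume(np.clip(data, 0.0, None), spacing, origin)


def read_mask(path: str | Path) -> RoiMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    aff = img.affine
    spacing = tuple(float(x) for x in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(x) for x in aff[:3, 3])
    return RoiMask(data > 0, spacing, origin)


def write_case(case: PatientCase, outdir: str | Path) -> pd.DataFrame:
    """Write one case's volumes/masks as NIfTI; return its manifest rows."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []

    def _emit(role: str, vol: ImageVolume, mask: RoiMask) -> None:
        vp = outdir / f"{case.patient_id}_{role}_vol.nii.gz"
        mp = outdir / f"{case.patient_id}_{role}_mask.nii.gz"
        write_volume(vol, vp)
        write_mask(mask, mp)
        rows.append(
            {
                "patient_id": case.patient_id,
                "role": role,
                "volume_path": vp.name,
                "mask_path": mp.name,
                "LR": case.outcome.LR,
                "DM": case.outcome.DM,
                "OS_months": case.outcome.OS_months,
                "OS_event": case.outcome.OS_event,
                "interval_days": case.interval_days,
            }
        )

    _emit("pre3d", *case.pre3d)
    for k, (vol, mask) in enumerate(case.pre4d.phases):
        _emit(f"pre4d_phase_{k}", vol, mask)
    _emit("post3d", *case.post3d)
    return pd.DataFrame(rows, columns=_MANIFEST_COLUMNS)


def read_case(manifest: pd.DataFrame, base_dir: str | Path) -> PatientCase:
    """Rebuild one patient's case from its manifest rows."""
    base = Path(base_dir)
    missing = [c for c in _MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ManifestError(f"manifest missing columns: {missing}")
    pids = manifest["patient_id"].unique()
    if len(pids) != 1:
        raise ManifestError("read_case expects rows for exactly one patient")
    dup = manifest["role"][manifest["role"].duplicated()]
    if not dup.empty:
        raise ManifestError(
            f"duplicate manifest rows for patient {pids[0]!r}: "
            f"{sorted(dup.unique())}"
        )

    def _load(row: pd.Series) -> tuple[ImageVolume, RoiMask]:
        vol = read_volume(base / row["volume_path"])
        mask = read_mask(base / row["mask_path"])
        mask.check_aligned(vol)
        return vol, mask

    by_role = {r["role"]: r for _, r in manifest.iterrows()}
    for slot in ("pre3d", "post3d"):
        if slot not in by_role:
            raise ManifestError(f"manifest lacks required scan role {slot!r}")

    phase_roles = sorted(
        (r for r in by_role if r.startswith("pre4d_phase_")),
        key=lambda r: int(r.rsplit("_", 1)[1]),
    )
    if len(phase_roles) < 3:
        raise ManifestError("manifest must list >= 3 pre4d phase files")
    expected = [f"pre4d_phase_{k}" for k in range(len(phase_roles))]
    if phase_roles != expected:
        raise ManifestError(f"phase roles not contiguous: {phase_roles}")

    row0 = manifest.iloc[0]
    return PatientCase(
        patient_id=str(pids[0]),
        pre4d=PhaseSeries(tuple(_load(by_role[r]) for r in phase_roles)),
        pre3d=_load(by_role["pre3d"]),
        post3d=_load(by_role["post3d"]),
        outcome=Outcome(
            LR=int(row0["LR"]),
            DM=int(row0["DM"]),
            OS_months=float(row0["OS_months"]),
            OS_event=int(row0["OS_event"]),
        ),
        interval_days=float(row0["interval_days"]),
    )


def write_cohort(cases: list[PatientCase], outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = [write_case(c, outdir) for c in cases]
    manifest = pd.concat(frames, ignore_index=True)
    path = outdir / "manifest.csv"
    manifest.to_csv(path, index=False)
    return path


def read_cohort(manifest_path: str | Path) -> list[PatientCase]:
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    base = manifest_path.parent
    cases = []
    for pid, rows in manifest.groupby("patient_id", sort=False):
        cases.append(read_case(rows, base))
    return cases
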