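"""Semi-automatic lesion delineation by a contrast-oriented threshold.

The threshold is a weighted combination of the mean SUV inside the
70%-of-max isocontour (mSUV70) and a local background estimate:

    threshold = a * mSUV70 + b * background

The mask is the largest 26-connected component above threshold inside the
search region.  Externally supplied (manual) masks are accepted as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from gdr.phantom_io import (
    AlignmentError,
    ImageVolume,
    PhaseSeries,
    RoiMask,
    read_mask,
)

__all__ = [
    "SegmentationError",
    "EmptySegmentationError",
    "CoaConfig",
    "CoaResult",
    "coa_segment",
    "load_manual_mask",
    "segment_phase_series",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class SegmentationError(RuntimeError):
    pass


class EmptySegmentationError(SegmentationError):
    pass


@dataclass(frozen=True)
class CoaConfig:
    """Threshold weights and background-shell geometry.

    The clinical calibration constants are not published alongside the
    method description consumed here; a = b = 0.5 is the package default
    and must be reported with every result.
    """

    a: float = 0.5
    b: float = 0.5
    background_shell_voxels: int = 2  # shell thickness, offset by same amount
    min_lesion_voxels: int = 1

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.a + self.b <= 0:
            raise ValueError("require a, b >= 0 and a + b > 0")
        if self.min_lesion_voxels < 1:
            raise ValueError("min_lesion_voxels must be >= 1")


@dataclass(frozen=True)
class CoaResult:
    mask: RoiMask
    threshold_suv: float
    msuv70: float
    background_suv: float
    config: CoaConfig


def _as_region(search_region, volume: ImageVolume) -> np.ndarray:
    """Accept a RoiMask, boolean array, or ((i0,i1),(j0,j1),(k0,k1)) box."""
    if isinstance(search_region, RoiMask):
        search_region.check_aligned(volume)
        return search_region.values
    arr = np.asarray(search_region)
    if arr.shape == volume.shape:
        return arr.astype(bool)
    box = np.asarray(search_region, dtype=int)
    if box.shape != (3, 2):
        raise ValueError("search region must be a mask or a 3x2 index box")
    region = np.zeros(volume.shape, dtype=bool)
    sl = tuple(slice(int(lo), int(hi)) for lo, hi in box)
    region[sl] = True
    return region


def _background_estimate(
    values: np.ndarray, region: np.ndarray, cfg: CoaConfig
) -> float:
    """Mean SUV in a shell offset outside the 40%-isocontour bounding box."""
    suv_max = values[region].max()
    iso40 = region & (values >= 0.4 * suv_max)
    idx = np.argwhere(iso40)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    t = cfg.background_shell_voxels

    def _box(grow: int) -> np.ndarray:
        box = np.zeros(values.shape, dtype=bool)
        sl = tuple(
            slice(max(0, int(l) - grow), min(s, int(h) + grow))
            for l, h, s in zip(lo, hi, values.shape)
        )
        box[sl] = True
        return box

    shell = _box(2 * t) & ~_box(t)
    if not shell.any():  # lesion box touches the grid boundary everywhere
        shell = ~_box(t)
    if not shell.any():
        raise SegmentationError("no voxels available for background estimation")
    return float(values[shell].mean())


def coa_segment(
    volume: ImageVolume, search_region, cfg: CoaConfig = CoaConfig()
) -> CoaResult:
    """Contrast-oriented segmentation inside a search region.

    Raises :class:`EmptySegmentationError` when nothing exceeds the
    threshold and :class:`SegmentationError` when the largest component is
    smaller than ``cfg.min_lesion_voxels``.
    """
    region = _as_region(search_region, volume)
    if not region.any():
        raise ValueError("search region is empty")
    values = np.asarray(volume.values, dtype=float)

    background = _background_estimate(values, region, cfg)
    suv_max = float(values[region].max())
    if suv_max <= background:
        raise EmptySegmentationError(
            "search region holds no voxel above the background estimate"
        )
    iso70 = region & (values >= 0.70 * suv_max)
    msuv70 = float(values[iso70].mean())

    threshold = cfg.a * msuv70 + cfg.b * background
    above = region & (values >= threshold)
    if not above.any():
        raise EmptySegmentationError(
            f"no voxel exceeds threshold {threshold:.3f} SUV"
        )
    labels, n = ndimage.label(above, structure=_STRUCT_26)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    mask = labels == best
    if mask.sum() < cfg.min_lesion_voxels:
        raise SegmentationError(
            f"largest component has {int(mask.sum())} voxels "
            f"(< min_lesion_voxels={cfg.min_lesion_voxels})"
        )
    return CoaResult(
        mask=RoiMask(mask, volume.spacing, volume.origin),
        threshold_suv=float(threshold),
        msuv70=msuv70,
        background_suv=background,
        config=cfg,
    )


def load_manual_mask(path: str | Path, volume: ImageVolume) -> RoiMask:
    """Load an externally drawn contour; geometry must match, may be disconnected."""
    mask = read_mask(path)
    mask.check_aligned(volume)
    if mask.voxel_count == 0:
        raise ValueError(f"manual mask {path} contains no foreground voxel")
    return mask


def segment_phase_series(
    series: PhaseSeries, search_region, cfg: CoaConfig = CoaConfig()
) -> tuple[PhaseSeries, list[CoaResult]]:
    """COA per phase, the search box re-centred on each phase's hot spot.

    The region given for phase 0 is translated per phase by the shift of
    the intensity-weighted centroid of the top-40% voxels.  Any phase
    failure rejects the whole series with a message naming the phases.
    """
    vol0 = series.phases[0][0]
    region0 = _as_region(search_region, vol0)

    def _hot_centroid(vol: ImageVolume) -> np.ndarray:
        v = np.asarray(vol.values, float)
        hot = region0 & (v >= 0.4 * v[region0].max())
        w = v[hot]
        return (np.argwhere(hot) * w[:, None]).sum(axis=0) / w.sum()

    c0 = _hot_centroid(vol0)
    results: list[CoaResult] = []
    failures: list[str] = []
    out_phases = []
    for k, (vol, _) in enumerate(series.phases):
        shift = np.rint(_hot_centroid(vol) - c0).astype(int)
        region = region0
        if np.any(shift != 0):
            region = np.roll(region0, tuple(shift), axis=(0, 1, 2))
        try:
            res = coa_segment(vol, region, cfg)
        except SegmentationError as exc:
            failures.append(f"phase {k}: {exc}")
            continue
        results.append(res)
        out_phases.append((vol, res.mask))
    if failures:
        raise SegmentationError(
            "COA failed on phases: " + "; ".join(failures)
        )
    return PhaseSeries(tuple(out_phases)), results
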