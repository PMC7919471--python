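"""Radiomic feature bank over a (volume, mask) pair.

Three preprocessing variants are supported:

* raw        — SUV values; texture on fixed-bin-width discretization (W = 0.01)
* ``WF-``    — wavelet band-pass filtered values (2:1 sub-band weighting),
               then fixed-bin discretized; co-occurrence variance and
               run-length features
* ``Q-``     — equal-probability quantized gray levels; run-length,
               size-zone and neighborhood gray-tone features

Texture matrices are merged over the 13 unique 3D directions at Chebyshev
distance 1 (single matrix, not per-direction averaging).  Features that
are undefined on a given input (e.g. neighborhood statistics on a
one-voxel mask) are reported as NaN and listed in
``FeatureVector.undefined``; downstream stages exclude them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from gdr.phantom_io import ImageVolume, RoiMask
from gdr.wavelet import wavelet_bandpass_volume

__all__ = [
    "DIRECTIONS_13",
    "DiscretizationConfig",
    "FeatureSet",
    "FeatureVector",
    "DEFAULT_FEATURE_SET",
    "ELIGIBLE_17",
    "discretize_fixed_bin",
    "equalize_quantize",
    "wavelet_bandpass",
    "auc_csh",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "extract_features",
]

# The 13 unique displacement vectors of the 26-neighborhood (one per
# +/- pair), Chebyshev distance 1.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

COARSENESS_CAP = 1e6  # reported when the neighborhood sum vanishes


@dataclass(frozen=True)
class DiscretizationConfig:
    """Gray-level discretization used for texture matrices."""

    bin_width: float = 0.01  # SUV per level, fixed-bin mode
    n_levels: int = 64  # equal-probability mode
    anchor: str = "min"  # "min" (level 1 at mask minimum) or "zero"

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.anchor not in ("min", "zero"):
            raise ValueError("anchor must be 'min' or 'zero'")


@dataclass(frozen=True)
class FeatureSet:
    """Declared feature names per preprocessing variant."""

    first_order: tuple[str, ...] = (
        "SUVmax",
        "SUVmean",
        "variance",
        "skewness",
        "kurtosis",
        "CoV",
        "volume_ml",
        "AUC_CSH",
    )
    glcm: tuple[str, ...] = (
        "Variance_CM",
        "energy",
        "entropy",
        "contrast",
        "homogeneity",
        "correlation",
    )
    glrlm: tuple[str, ...] = ("SRE", "LRE", "RLN", "RP", "GLN")
    glszm: tuple[str, ...] = ("SZE", "LZE", "ZSN", "ZP")
    ngtdm: tuple[str, ...] = ("Coarseness", "Contrast_NG", "Busyness")
    wf: tuple[str, ...] = ("Variance_CM", "SRE", "LRE", "RLN", "RP", "GLN")
    q: tuple[str, ...] = (
        "SZE",
        "LZE",
        "ZSN",
        "ZP",
        "SRE",
        "LRE",
        "RLN",
        "RP",
        "GLN",
        "Contrast_NG",
        "Busyness",
        "Coarseness",
    )

    def declared_names(self) -> tuple[str, ...]:
        names = list(self.first_order)
        names += list(self.glcm) + list(self.glrlm)
        names += list(self.glszm) + list(self.ngtdm)
        names += [f"WF-{n}" for n in self.wf]
        names += [f"Q-{n}" for n in self.q]
        return tuple(names)


DEFAULT_FEATURE_SET = FeatureSet()

#: Feature names that pass both eligibility screens in the reference study.
ELIGIBLE_17: tuple[str, ...] = (
    "AUC_CSH",
    "Variance_CM",
    "WF-Variance_CM",
    "WF-SRE",
    "WF-LRE",
    "WF-RLN",
    "WF-RP",
    "Q-SZE",
    "Q-LZE",
    "Q-ZSN",
    "Q-ZP",
    "Q-SRE",
    "Q-LRE",
    "Q-RLN",
    "Q-RP",
    "Q-Contrast_NG",
    "Q-Busyness",
)


@dataclass
class FeatureVector:
    values: dict[str, float]
    undefined: set[str] = field(default_factory=set)
    metadata: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# Discretization
# --------------------------------------------------------------------------


def discretize_fixed_bin(
    values: np.ndarray, bin_width: float, anchor: str = "min"
) -> np.ndarray:
    """Integer gray levels ``floor((v - ref) / W) + 1``; ref = min or 0."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    v = np.asarray(values, dtype=float)
    if v.size == 0 or not np.all(np.isfinite(v)):
        raise ValueError("values must be non-empty and finite")
    ref = v.min() if anchor == "min" else 0.0
    return np.floor((v - ref) / bin_width).astype(np.int64) + 1


def equalize_quantize(values: np.ndarray, n_levels: int = 64) -> np.ndarray:
    """Equal-probability (histogram-equalizing) gray levels in [1, n_levels].

    Level of v is ``ceil(n_levels * F(v))`` with F the empirical CDF; ties
    share a level and the mapping is monotone in v.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values must be non-empty")
    order = np.argsort(v, kind="stable")
    ranks = np.empty(v.size, dtype=np.int64)
    # rank of v = number of samples <= v (ties get the max rank of the group)
    sv = v[order]
    ranks_sorted = np.arange(1, v.size + 1)
    for end in range(v.size - 2, -1, -1):
        if sv[end] == sv[end + 1]:
            ranks_sorted[end] = ranks_sorted[end + 1]
    ranks[order] = ranks_sorted
    levels = np.ceil(n_levels * ranks / v.size).astype(np.int64)
    return np.clip(levels, 1, n_levels)


def wavelet_bandpass(
    volume: ImageVolume, mask: RoiMask, bandpass_weight: float = 2.0
) -> np.ndarray:
    """Band-pass-filtered voxel values inside the mask (C order of indices).

    The single-level 3D transform runs on the mask bounding box of the
    volume; mixed sub-bands get ``bandpass_weight``, pure low/high bands
    weight 1.
    """
    mask.check_aligned(volume)
    idx = np.argwhere(mask.values)
    if idx.size == 0:
        raise ValueError("mask is empty")
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    if np.any(hi - lo < 2):
        raise ValueError("mask bounding box must span >= 2 voxels per axis")
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    box = np.asarray(volume.values, dtype=float)[sl]
    filtered = wavelet_bandpass_volume(box, bandpass_weight=bandpass_weight)
    return filtered[mask.values[sl]]


# --------------------------------------------------------------------------
# First order
# --------------------------------------------------------------------------


def auc_csh(values: np.ndarray) -> float:
    """Area under the cumulative SUV-volume histogram.

    With f(t) = fraction of voxels at or above t * max (t in [0, 1]),
    the exact area is mean(values) / max(values) — the sorted-values
    closed form of the piecewise-constant integral.  Higher = more
    homogeneous uptake.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values must be non-empty")
    m = v.max()
    if m <= 0:
        raise ValueError("AUC_CSH undefined for all-zero input")
    if np.ptp(v) == 0.0:
        return 1.0  # constant lesion, exactly
    return float(v.mean() / m)


def _first_order(values: np.ndarray, voxel_volume_mm3: float) -> dict[str, float]:
    v = np.asarray(values, dtype=float)
    mean = float(v.mean())
    var = float(v.var())
    sd = math.sqrt(var)
    if sd > 0:
        z = (v - mean) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))
    else:
        skew, kurt = 0.0, 0.0
    return {
        "SUVmax": float(v.max()),
        "SUVmean": mean,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "CoV": sd / mean if mean > 0 else float("nan"),
        "volume_ml": v.size * voxel_volume_mm3 / 1000.0,
        "AUC_CSH": auc_csh(v),
    }


# --------------------------------------------------------------------------
# Texture matrices (levels: 3D int array, 0 = outside mask)
# --------------------------------------------------------------------------


def _glcm_matrix(
    levels: np.ndarray, directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13
) -> np.ndarray:
    """Merged symmetric co-occurrence matrix, normalized to sum 1."""
    lv = np.asarray(levels, dtype=np.int64)
    L = int(lv.max())
    if L < 1:
        raise ValueError("no in-mask voxels")
    P = np.zeros((L, L))
    for d in directions:
        a = lv
        b = lv
        for axis, step in enumerate(d):
            a = _shift_crop(a, axis, step, head=True)
            b = _shift_crop(b, axis, step, head=False)
        valid = (a > 0) & (b > 0)
        np.add.at(P, (a[valid] - 1, b[valid] - 1), 1.0)
    P = P + P.T
    total = P.sum()
    if total == 0:
        raise ValueError("no co-occurring voxel pairs in the mask")
    return P / total


def _shift_crop(x: np.ndarray, axis: int, step: int, head: bool) -> np.ndarray:
    """Crop so that x[head] aligns with x[tail] displaced by `step` on `axis`."""
    if step == 0:
        return x
    n = x.shape[axis]
    if head:
        sl = slice(0, n - abs(step)) if step > 0 else slice(abs(step), n)
    else:
        sl = slice(abs(step), n) if step > 0 else slice(0, n - abs(step))
    index = [slice(None)] * x.ndim
    index[axis] = sl
    return x[tuple(index)]


def glcm_features(
    levels: np.ndarray, directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13
) -> dict[str, float]:
    P = _glcm_matrix(levels, directions)
    L = P.shape[0]
    i = np.arange(1, L + 1, dtype=float)
    I, J = np.meshgrid(i, i, indexing="ij")
    mu = float((I * P).sum())
    var = float(((I - mu) ** 2 * P).sum())
    nz = P[P > 0]
    sd = math.sqrt(var)
    if sd > 0:
        corr = float(((I - mu) * (J - mu) * P).sum() / (sd * sd))
    else:
        corr = 1.0  # degenerate single-level matrix
    return {
        "Variance_CM": var,
        "energy": float((P**2).sum()),
        "entropy": float(-(nz * np.log2(nz)).sum()),
        "contrast": float(((I - J) ** 2 * P).sum()),
        "homogeneity": float((P / (1.0 + np.abs(I - J))).sum()),
        "correlation": corr,
    }


def _run_lengths(
    levels: np.ndarray, directions: tuple[tuple[int, int, int], ...]
) -> dict[tuple[int, int], int]:
    """Counts of maximal equal-level runs: (level, length) -> count."""
    lv = np.asarray(levels, dtype=np.int64)
    shape = lv.shape
    counts: dict[tuple[int, int], int] = {}
    for d in directions:
        d = np.asarray(d)
        # run starts: in-mask voxels whose predecessor along d differs
        starts = np.argwhere(lv > 0)
        prev = starts - d
        ok = np.all((prev >= 0) & (prev < shape), axis=1)
        same_prev = np.zeros(len(starts), dtype=bool)
        if ok.any():
            p = prev[ok]
            same_prev[ok] = lv[tuple(p.T)] == lv[tuple(starts[ok].T)]
        starts = starts[~same_prev]
        # walk forward from each start
        pos = starts.copy()
        level_of = lv[tuple(starts.T)]
        length = np.ones(len(starts), dtype=np.int64)
        alive = np.arange(len(starts))
        while len(alive):
            nxt = pos[alive] + d
            inb = np.all((nxt >= 0) & (nxt < shape), axis=1)
            cont = np.zeros(len(alive), dtype=bool)
            if inb.any():
                cont[inb] = lv[tuple(nxt[inb].T)] == level_of[alive[inb]]
            grown = alive[cont]
            length[grown] += 1
            pos[grown] += d
            alive = grown
        for g, l in zip(level_of, length):
            counts[(int(g), int(l))] = counts.get((int(g), int(l)), 0) + 1
    return counts


def glrlm_features(
    levels: np.ndarray, directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13
) -> dict[str, float]:
    lv = np.asarray(levels, dtype=np.int64)
    n_vox = int((lv > 0).sum())
    if n_vox < 1:
        raise ValueError("no in-mask voxels")
    counts = _run_lengths(lv, directions)
    r = np.array(list(counts.values()), dtype=float)
    gl = np.array([k[0] for k in counts], dtype=float)
    ln = np.array([k[1] for k in counts], dtype=float)
    nr = r.sum()
    sre = float((r / ln**2).sum() / nr)
    lre = float((r * ln**2).sum() / nr)
    rln_sum = 0.0
    for j in np.unique(ln):
        rln_sum += r[ln == j].sum() ** 2
    gln_sum = 0.0
    for i_ in np.unique(gl):
        gln_sum += r[gl == i_].sum() ** 2
    return {
        "SRE": sre,
        "LRE": lre,
        "RLN": float(rln_sum / nr),
        "GLN": float(gln_sum / nr),
        "RP": float(nr / (len(directions) * n_vox)),
    }


def glszm_features(levels: np.ndarray) -> dict[str, float]:
    lv = np.asarray(levels, dtype=np.int64)
    n_vox = int((lv > 0).sum())
    if n_vox < 1:
        raise ValueError("no in-mask voxels")
    sizes: list[float] = []
    for g in np.unique(lv[lv > 0]):
        lab, n = ndimage.label(lv == g, structure=_STRUCT_26)
        if n:
            zs = ndimage.sum_labels(np.ones(lv.shape), lab, range(1, n + 1))
            sizes.extend(zs.tolist())
    z = np.asarray(sizes, dtype=float)
    nz = float(len(z))
    # zone-size non-uniformity groups zones by size (run-length RLN analogue)
    zsn_sum = sum(float((z == s_).sum()) ** 2 for s_ in np.unique(z))
    return {
        "SZE": float((1.0 / z**2).sum() / nz),
        "LZE": float((z**2).sum() / nz),
        "ZSN": float(zsn_sum / nz),
        "ZP": float(nz / n_vox),
    }


def ngtdm_features(levels: np.ndarray) -> dict[str, float]:
    """Neighborhood gray-tone difference features (Amadasun–King).

    Returns NaN for all three features when no voxel has an in-mask
    26-neighbor.
    """
    lv = np.asarray(levels, dtype=np.int64)
    inmask = lv > 0
    if int(inmask.sum()) < 2:
        return {k: float("nan") for k in ("Coarseness", "Contrast_NG", "Busyness")}
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nb_sum = ndimage.convolve(
        (lv * inmask).astype(float), kernel, mode="constant", cval=0.0
    )
    nb_cnt = ndimage.convolve(inmask.astype(float), kernel, mode="constant", cval=0.0)
    valid = inmask & (nb_cnt > 0)
    if not valid.any():
        return {k: float("nan") for k in ("Coarseness", "Contrast_NG", "Busyness")}

    A = nb_sum[valid] / nb_cnt[valid]
    g = lv[valid].astype(float)
    N = g.size
    levels_present = np.unique(lv[valid])
    s = np.array([np.abs(g[lv[valid] == k] - A[lv[valid] == k]).sum()
                  for k in levels_present])
    p = np.array([(lv[valid] == k).sum() for k in levels_present], dtype=float) / N
    kv = levels_present.astype(float)

    ps = float((p * s).sum())
    coarseness = min(1.0 / ps, COARSENESS_CAP) if ps > 0 else COARSENESS_CAP

    ngv = len(levels_present)
    if ngv > 1:
        KK, LL = np.meshgrid(kv, kv, indexing="ij")
        PP = np.outer(p, p)
        contrast = float(
            (PP * (KK - LL) ** 2).sum() / (ngv * (ngv - 1)) * (s.sum() / N)
        )
        busy_den = float(np.abs(np.subtract.outer(kv * p, kv * p)).sum())
        busyness = ps / busy_den if busy_den > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
    return {"Coarseness": coarseness, "Contrast_NG": contrast, "Busyness": busyness}


# --------------------------------------------------------------------------
# Extraction driver
# --------------------------------------------------------------------------


def _levels_to_grid(mask_values: np.ndarray, levels_flat: np.ndarray,
                    bbox: tuple[slice, ...]) -> np.ndarray:
    grid = np.zeros_like(mask_values[bbox], dtype=np.int64)
    grid[mask_values[bbox]] = levels_flat
    return grid


def extract_features(
    volume: ImageVolume,
    mask: RoiMask,
    cfg: DiscretizationConfig = DiscretizationConfig(),
    feature_set: FeatureSet = DEFAULT_FEATURE_SET,
    names: tuple[str, ...] | None = None,
) -> FeatureVector:
    """Compute the declared feature bank on one (volume, mask) pair.

    ``names`` optionally restricts computation to a subset of declared
    feature names (matching prefixes decide which variants run).
    First-order features always come from raw SUV.
    """
    mask.check_aligned(volume)
    if mask.voxel_count == 0:
        raise ValueError("mask is empty")
    wanted = set(names if names is not None else feature_set.declared_names())

    idx = np.argwhere(mask.values)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    bbox = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    mbox = mask.values[bbox]
    raw = np.asarray(volume.values, dtype=float)[bbox][mbox]

    out: dict[str, float] = {}
    undefined: set[str] = set()

    def _take(prefix: str, family: dict[str, float], declared) -> None:
        for name in declared:
            full = prefix + name
            if full not in wanted:
                continue
            val = family.get(name, float("nan"))
            out[full] = val
            if not np.isfinite(val):
                undefined.add(full)

    voxel_vol = float(np.prod(volume.spacing))
    if wanted & set(feature_set.first_order):
        _take("", _first_order(raw, voxel_vol), feature_set.first_order)

    def _family_grids(values_flat: np.ndarray) -> np.ndarray:
        lv = discretize_fixed_bin(values_flat, cfg.bin_width, cfg.anchor)
        return _levels_to_grid(mask.values, lv, bbox)

    # raw texture
    raw_texture_names = (
        set(feature_set.glcm)
        | set(feature_set.glrlm)
        | set(feature_set.glszm)
        | set(feature_set.ngtdm)
    )
    if wanted & raw_texture_names:
        grid = _family_grids(raw)
        if wanted & set(feature_set.glcm):
            _take("", _safe(glcm_features, grid), feature_set.glcm)
        if wanted & set(feature_set.glrlm):
            _take("", _safe(glrlm_features, grid), feature_set.glrlm)
        if wanted & set(feature_set.glszm):
            _take("", _safe(glszm_features, grid), feature_set.glszm)
        if wanted & set(feature_set.ngtdm):
            _take("", _safe(ngtdm_features, grid), feature_set.ngtdm)

    # WF- variant
    wf_names = {f"WF-{n}" for n in feature_set.wf}
    if wanted & wf_names:
        try:
            filtered = wavelet_bandpass(volume, mask)
            grid = _family_grids(filtered)
            fam: dict[str, float] = {}
            if set(feature_set.wf) & set(feature_set.glcm):
                fam.update(_safe(glcm_features, grid))
            if set(feature_set.wf) & set(feature_set.glrlm):
                fam.update(_safe(glrlm_features, grid))
            _take("WF-", fam, feature_set.wf)
        except ValueError:
            _take("WF-", {}, feature_set.wf)

    # Q- variant
    q_names = {f"Q-{n}" for n in feature_set.q}
    if wanted & q_names:
        lv = equalize_quantize(raw, cfg.n_levels)
        grid = _levels_to_grid(mask.values, lv, bbox)
        fam = {}
        if set(feature_set.q) & set(feature_set.glrlm):
            fam.update(_safe(glrlm_features, grid))
        if set(feature_set.q) & set(feature_set.glszm):
            fam.update(_safe(glszm_features, grid))
        if set(feature_set.q) & set(feature_set.ngtdm):
            fam.update(_safe(ngtdm_features, grid))
        _take("Q-", fam, feature_set.q)

    return FeatureVector(
        values=out,
        undefined=undefined,
        metadata={
            "bin_width": cfg.bin_width,
            "n_levels": cfg.n_levels,
            "voxel_count": mask.voxel_count,
        },
    )


def _safe(fn, grid) -> dict[str, float]:
    try:
        return fn(grid)
    except ValueError:
        return {}
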