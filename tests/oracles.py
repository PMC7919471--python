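"""Independent brute-force oracles for the texture features.

Everything here is deliberately written with plain Python loops and
dictionaries — no shared code with the package implementations — so a
match is evidence, not tautology.
"""

from __future__ import annotations

import math

import numpy as np

DIRS_13 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]
DIRS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _voxels(levels):
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if levels[x, y, z] > 0:
                    yield x, y, z


def _inside(levels, v):
    x, y, z = v
    nx, ny, nz = levels.shape
    return 0 <= x < nx and 0 <= y < ny and 0 <= z < nz and levels[x, y, z] > 0


def oracle_glcm(levels, directions=DIRS_13):
    """Exhaustive pair listing -> merged symmetric normalized matrix + features."""
    levels = np.asarray(levels)
    pairs: dict[tuple[int, int], int] = {}
    for v in _voxels(levels):
        for d in directions:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if _inside(levels, w):
                i, j = int(levels[v]), int(levels[w])
                pairs[(i, j)] = pairs.get((i, j), 0) + 1
                pairs[(j, i)] = pairs.get((j, i), 0) + 1
    total = sum(pairs.values())
    p = {k: c / total for k, c in pairs.items()}
    mu = sum(i * q for (i, _), q in p.items())
    var = sum((i - mu) ** 2 * q for (i, _), q in p.items())
    sd2 = sum((i - mu) * (j - mu) * q for (i, j), q in p.items())
    return {
        "Variance_CM": var,
        "energy": sum(q * q for q in p.values()),
        "entropy": -sum(q * math.log2(q) for q in p.values() if q > 0),
        "contrast": sum((i - j) ** 2 * q for (i, j), q in p.items()),
        "homogeneity": sum(q / (1 + abs(i - j)) for (i, j), q in p.items()),
        "correlation": (sd2 / var) if var > 0 else 1.0,
    }


def oracle_glrlm(levels, directions=DIRS_13):
    """Run enumeration by walking every line start."""
    levels = np.asarray(levels)
    runs: dict[tuple[int, int], int] = {}
    for d in directions:
        for v in _voxels(levels):
            prev = (v[0] - d[0], v[1] - d[1], v[2] - d[2])
            if _inside(levels, prev) and levels[prev] == levels[v]:
                continue  # not a run start
            g = int(levels[v])
            length = 1
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            while _inside(levels, w) and int(levels[w]) == g:
                length += 1
                w = (w[0] + d[0], w[1] + d[1], w[2] + d[2])
            runs[(g, length)] = runs.get((g, length), 0) + 1
    nr = sum(runs.values())
    nvox = sum(1 for _ in _voxels(levels))
    sre = sum(c / j**2 for (_, j), c in runs.items()) / nr
    lre = sum(c * j**2 for (_, j), c in runs.items()) / nr
    by_len: dict[int, int] = {}
    by_gl: dict[int, int] = {}
    for (g, j), c in runs.items():
        by_len[j] = by_len.get(j, 0) + c
        by_gl[g] = by_gl.get(g, 0) + c
    return {
        "SRE": sre,
        "LRE": lre,
        "RLN": sum(c**2 for c in by_len.values()) / nr,
        "GLN": sum(c**2 for c in by_gl.values()) / nr,
        "RP": nr / (len(directions) * nvox),
    }


def oracle_glszm(levels):
    """Flood-fill (explicit stack, 26-connectivity) zone enumeration."""
    levels = np.asarray(levels)
    seen = set()
    sizes = []
    for v in _voxels(levels):
        if v in seen:
            continue
        g = int(levels[v])
        stack = [v]
        seen.add(v)
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for d in DIRS_26:
                w = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                if w not in seen and _inside(levels, w) and int(levels[w]) == g:
                    seen.add(w)
                    stack.append(w)
        sizes.append(size)
    nz = len(sizes)
    nvox = sum(sizes)
    by_size: dict[int, int] = {}
    for s in sizes:
        by_size[s] = by_size.get(s, 0) + 1
    return {
        "SZE": sum(1 / s**2 for s in sizes) / nz,
        "LZE": sum(s**2 for s in sizes) / nz,
        "ZSN": sum(c**2 for c in by_size.values()) / nz,
        "ZP": nz / nvox,
    }


def oracle_ngtdm(levels, coarseness_cap=1e6):
    """Per-voxel 26-neighborhood loops, Amadasun–King formulas."""
    levels = np.asarray(levels)
    s: dict[int, float] = {}
    n: dict[int, int] = {}
    total = 0
    for v in _voxels(levels):
        nb = []
        for d in DIRS_26:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if _inside(levels, w):
                nb.append(int(levels[w]))
        if not nb:
            continue
        g = int(levels[v])
        a = sum(nb) / len(nb)
        s[g] = s.get(g, 0.0) + abs(g - a)
        n[g] = n.get(g, 0) + 1
        total += 1
    if total == 0:
        return {k: float("nan") for k in ("Coarseness", "Contrast_NG", "Busyness")}
    p = {g: n[g] / total for g in n}
    ps = sum(p[g] * s[g] for g in p)
    coarseness = min(1.0 / ps, coarseness_cap) if ps > 0 else coarseness_cap
    gs = sorted(p)
    if len(gs) > 1:
        c1 = sum(
            p[i] * p[j] * (i - j) ** 2 for i in gs for j in gs
        ) / (len(gs) * (len(gs) - 1))
        contrast = c1 * sum(s.values()) / total
        den = sum(abs(i * p[i] - j * p[j]) for i in gs for j in gs)
        busyness = ps / den if den > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
    return {"Coarseness": coarseness, "Contrast_NG": contrast, "Busyness": busyness}


def gaussian_blur_oracle(vol, sigma_vox, truncate=6.0):
    """Direct dense Gaussian convolution (separable, explicit loops over taps)."""
    out = np.asarray(vol, dtype=float).copy()
    for axis, s in enumerate(sigma_vox):
        if s == 0:
            continue
        r = int(truncate * s + 0.5)
        t = np.arange(-r, r + 1, dtype=float)
        k = np.exp(-0.5 * (t / s) ** 2)
        k /= k.sum()
        acc = np.zeros_like(out)
        for off, w in zip(range(-r, r + 1), k):
            shifted = np.roll(out, off, axis=axis)
            # nearest-edge padding semantics
            sl = [slice(None)] * 3
            if off > 0:
                sl[axis] = slice(0, off)
                idx = [slice(None)] * 3
                idx[axis] = slice(off, off + 1)
                shifted[tuple(sl)] = out[tuple([slice(0, 1) if a == axis else slice(None) for a in range(3)])]
            elif off < 0:
                sl[axis] = slice(out.shape[axis] + off, None)
                shifted[tuple(sl)] = out[tuple([slice(-1, None) if a == axis else slice(None) for a in range(3)])]
            acc += w * shifted
        out = acc
    return out
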