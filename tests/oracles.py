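"""Independent brute-force oracles used by the test suite.

Everything here is written against the plain mathematical definitions
(explicit loops, dense convolution, full enumeration) and deliberately
avoids the code paths it is used to check.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------- imaging
def brute_block_mean_inplane(arr: np.ndarray, factor: int) -> np.ndarray:
    """Explicit in-plane block mean with edge padding, via python loops."""
    pad0 = (-arr.shape[0]) % factor
    pad1 = (-arr.shape[1]) % factor
    arr = np.pad(arr.astype(float), ((0, pad0), (0, pad1), (0, 0)), mode="edge")
    nx, ny, nz = arr.shape
    out = np.zeros((nx // factor, ny // factor, nz))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            block = arr[i * factor : (i + 1) * factor, j * factor : (j + 1) * factor, :]
            out[i, j, :] = block.mean(axis=(0, 1))
    return out


def brute_bbox(mask: np.ndarray):
    """Bounding box by exhaustive index scan."""
    lo = [int(1e9)] * 3
    hi = [-1] * 3
    for idx in np.argwhere(mask):
        for a in range(3):
            lo[a] = min(lo[a], idx[a])
            hi[a] = max(hi[a], idx[a])
    return tuple(lo), tuple(h + 1 for h in hi)


def gaussian_kernel_1d(sigma: float, truncate: float = 6.0) -> np.ndarray:
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def dense_gaussian_smooth(arr: np.ndarray, sigmas, truncate: float = 6.0) -> np.ndarray:
    """Separable convolution with an explicitly truncated kernel, zero-padded."""
    def conv_same(v, k):
        # centred window of the full convolution: zero-padded 'same' that
        # also works when the kernel is longer than the signal
        full = np.convolve(v, k, mode="full")
        start = (len(k) - 1) // 2
        return full[start : start + len(v)]

    out = arr.astype(float)
    for axis, sigma in enumerate(sigmas):
        if sigma == 0:
            continue
        k = gaussian_kernel_1d(sigma, truncate)
        out = np.apply_along_axis(lambda v: conv_same(v, k), axis, out)
    return out


def oracle_segment_flv(ct1_arr, liver, fov, spacing, threshold=800.0, factor=2, sigma=4.0):
    """Dense reimplementation of the full segmentation chain.

    Explicit block mean, >=0.5 mask vote, exhaustive bounding box, strict
    threshold, dense truncated-kernel convolution of mask and scope,
    ratio, explicit median over strictly positive values within the scope,
    >= threshold.  Returns the mask on the downsampled (working) grid.
    """
    ds_ct1 = brute_block_mean_inplane(ct1_arr, factor)
    ds_liver = brute_block_mean_inplane(liver.astype(float), factor) >= 0.5
    ds_fov = brute_block_mean_inplane(fov.astype(float), factor) >= 0.5
    roi = ds_liver & ds_fov
    lo, hi = brute_bbox(roi)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    ct1_c = ds_ct1[sl]
    roi_c = roi[sl]
    raw = (ct1_c < threshold) & roi_c
    if sigma > 0 and raw.any():
        sm_mask = dense_gaussian_smooth(raw.astype(float), (sigma, sigma, 0.0))
        sm_scope = dense_gaussian_smooth(roi_c.astype(float), (sigma, sigma, 0.0))
        field = np.zeros(raw.shape)
        ok = roi_c & (sm_scope > 1e-12)
        field[ok] = sm_mask[ok] / sm_scope[ok]
    else:
        field = raw.astype(float)
    positive = field[roi_c & (field > 0)]
    if positive.size == 0:
        flv_c = np.zeros_like(raw)
    else:
        med = np.median(positive)
        flv_c = (field >= med) & roi_c
    out = np.zeros(ds_ct1.shape, dtype=bool)
    out[sl] = flv_c
    return out


# ------------------------------------------------------------------- dose
def slow_ray_integral(red, spacing, origin, start, end) -> float:
    """Single-ray plane-crossing line integral, scalar python implementation."""
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    delta = end - start
    length = float(np.linalg.norm(delta))
    ts = {0.0, 1.0}
    for a in range(3):
        if abs(delta[a]) < 1e-12:
            continue
        for m in range(red.shape[a] + 1):
            plane = origin[a] + m * spacing[a]
            t = (plane - start[a]) / delta[a]
            if 0.0 < t < 1.0:
                ts.add(float(t))
    ts = sorted(ts)
    total = 0.0
    for t0, t1 in zip(ts, ts[1:]):
        mid = start + 0.5 * (t0 + t1) * delta
        idx = []
        inside = True
        for a in range(3):
            i = int(np.floor((mid[a] - origin[a]) / spacing[a]))
            if not (0 <= i < red.shape[a]):
                inside = False
                break
            idx.append(i)
        if inside:
            total += red[tuple(idx)] * (t1 - t0) * length
    return total


# ------------------------------------------------------------------ stats
def brute_wilcoxon(diffs) -> tuple[float, float]:
    """Exact signed-rank test by full enumeration with itertools.

    Returns (W+, two-sided p). Midranks for ties, zeros dropped,
    p = min(1, 2 min(P(W<=w), P(W>=w))).
    """
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    abs_d = np.abs(d)
    order = np.argsort(abs_d, kind="stable")
    ranks = np.empty(n)
    sv = abs_d[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    w = float(ranks[d > 0].sum())
    all_w = []
    for signs in itertools.product([0, 1], repeat=n):
        all_w.append(sum(r for s, r in zip(signs, ranks) if s))
    all_w = np.asarray(all_w)
    eps = 1e-9
    p_le = np.mean(all_w <= w + eps)
    p_ge = np.mean(all_w >= w - eps)
    return w, min(1.0, 2.0 * min(p_le, p_ge))
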