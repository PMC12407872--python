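"""Brute-force reference implementations used to validate the package.

Everything here is written with explicit per-pixel loops and elementary
arithmetic, independent of the vectorised code paths in ``axsite`` (the one
shared definition is the iterative-intermeans update rule, which IS the
threshold's specification).
"""

from __future__ import annotations

import math

import numpy as np

SQ2 = math.sqrt(2.0)
# weighted border-pixel categories of the contour-based perimeter estimator:
# v = 1 + 2*(# 4-connected border neighbours) + 10*(# diagonal border neighbours)
_PERIM_WEIGHTS = {
    5: 1.0,
    7: 1.0,
    15: 1.0,
    17: 1.0,
    25: 1.0,
    27: 1.0,
    21: SQ2,
    33: SQ2,
    13: (1.0 + SQ2) / 2.0,
    23: (1.0 + SQ2) / 2.0,
}


def sliding_percentile(x: np.ndarray, rate_hz: float, window_s: float, q: float) -> np.ndarray:
    """Per-window sort-and-interpolate percentile with edge truncation."""
    n = len(x)
    half = int(round(window_s * rate_hz / 2.0))
    out = np.empty(n)
    for t in range(n):
        w = x[max(0, t - half) : min(n, t + half + 1)]
        out[t] = np.percentile(w, q)
    return out


def rolling_ball_background(img: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale opening with a non-flat ball kernel, computed pixel by pixel.

    For each pixel the window of the padded (edge-clamped) image is taken and
    the min/max over the ball support evaluated directly.
    """
    h, w = img.shape
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    d2 = yy * yy + xx * xx
    support = d2 <= radius * radius
    heights = np.sqrt(np.maximum(radius * radius - d2, 0.0))[support]

    def _scan(a: np.ndarray, sign: float) -> np.ndarray:
        pad = np.pad(a, radius, mode="edge")
        out = np.empty_like(a, dtype=float)
        for y in range(h):
            for x in range(w):
                win = pad[y : y + 2 * radius + 1, x : x + 2 * radius + 1][support]
                if sign < 0:
                    out[y, x] = float(np.min(win - heights))
                else:
                    out[y, x] = float(np.max(win + heights))
        return out

    return _scan(_scan(np.asarray(img, dtype=float), -1.0), +1.0)


def intermeans_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Iterative intermeans on a 256-bin histogram, plain loops."""
    v = [float(u) for u in np.asarray(values).ravel() if math.isfinite(u)]
    lo, hi = min(v), max(v)
    if hi == lo:
        return hi
    hist = [0] * nbins
    for u in v:
        b = int((u - lo) / (hi - lo) * nbins)
        if b >= nbins:
            b = nbins - 1
        hist[b] = hist[b] + 1
    width = (hi - lo) / nbins
    centers = [lo + (i + 0.5) * width for i in range(nbins)]
    t = nbins // 2
    for _ in range(10_000):
        wb = sum(hist[: t + 1])
        wa = sum(hist[t + 1 :])
        if wb == 0:
            t += 1
            continue
        if wa == 0:
            t -= 1
            continue
        mb = sum(h * c for h, c in zip(hist[: t + 1], centers[: t + 1])) / wb
        ma = sum(h * c for h, c in zip(hist[t + 1 :], centers[t + 1 :])) / wa
        t_new = int(round(((mb + ma) / 2.0 - lo) / (hi - lo) * nbins - 0.5))
        t_new = min(max(t_new, 0), nbins - 2)
        if t_new == t:
            break
        t = t_new
    return lo + (t + 1) * width


def label_components(mask: np.ndarray) -> list[list[tuple[int, int]]]:
    """8-connected components by flood fill, in raster order of first pixel."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for y in range(h):
        for x in range(w):
            if mask[y, x] and not seen[y, x]:
                stack = [(y, x)]
                seen[y, x] = True
                comp = []
                while stack:
                    cy, cx = stack.pop()
                    comp.append((cy, cx))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = cy + dy, cx + dx
                            if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                comps.append(comp)
    return comps


def perimeter(pixels: set[tuple[int, int]]) -> float:
    """Weighted-contour perimeter of one component, explicit loops."""
    border = set()
    for (y, x) in pixels:
        n4 = [(y - 1, x), (y + 1, x), (y, x - 1), (y, x + 1)]
        if any(p not in pixels for p in n4):
            border.add((y, x))
    total = 0.0
    for (y, x) in border:
        a = sum(1 for p in [(y - 1, x), (y + 1, x), (y, x - 1), (y, x + 1)] if p in border)
        b = sum(
            1
            for p in [(y - 1, x - 1), (y - 1, x + 1), (y + 1, x - 1), (y + 1, x + 1)]
            if p in border
        )
        total += _PERIM_WEIGHTS.get(1 + 2 * a + 10 * b, 0.0)
    return total


def segment_particles(
    channel: np.ndarray,
    pixel_size_um: float,
    radius_px: int,
    size_range_um2: tuple[float, float],
    circ_range: tuple[float, float],
) -> list[dict]:
    """Full particle segmentation chain, brute force."""
    img = np.asarray(channel, dtype=float)
    if img.std() == 0:
        return []
    sub = img - rolling_ball_background(img, radius_px)
    thr = intermeans_threshold(sub)
    mask = sub > thr
    out = []
    for comp in label_components(mask):
        pixels = set(comp)
        area_px = len(pixels)
        area_um2 = area_px * pixel_size_um**2
        p = perimeter(pixels)
        circ = 1.0 if p == 0 else min(4.0 * math.pi * area_px / p**2, 1.0)
        if size_range_um2[0] <= area_um2 <= size_range_um2[1] and circ_range[0] <= circ <= circ_range[1]:
            out.append({"pixels": pixels, "area_um2": area_um2, "circularity": circ})
    return out


def roi_positive(pixels: set[tuple[int, int]], channel: np.ndarray) -> bool:
    """Strict 2x-mean rule with explicit sums."""
    total = 0.0
    for (y, x) in pixels:
        total += float(channel[y, x])
    roi_mean = total / len(pixels)
    img_mean = float(sum(float(v) for v in np.asarray(channel).ravel())) / channel.size
    return roi_mean > 2.0 * img_mean


def colocalization_chain(channels: dict, pixel_size_um: float, radius_px: int,
                         size_range: tuple, circ_range: tuple) -> dict:
    rois = segment_particles(channels["VAMP2"], pixel_size_um, radius_px, size_range, circ_range)
    n_vpos = n_th = n_triple = 0
    flags = []
    for roi in rois:
        vpos = roi_positive(roi["pixels"], channels["VAMP2"])
        tpos = bpos = False
        if vpos:
            n_vpos += 1
            tpos = roi_positive(roi["pixels"], channels["TH"])
            if tpos:
                n_th += 1
                bpos = roi_positive(roi["pixels"], channels["bassoon"])
                if bpos:
                    n_triple += 1
        flags.append((frozenset(roi["pixels"]), vpos, tpos, bpos))
    return {
        "n_rois": len(rois),
        "n_vamp2_pos": n_vpos,
        "n_th_pos": n_th,
        "n_triple": n_triple,
        "pct_th": 100.0 * n_th / n_vpos if n_vpos else None,
        "pct_bsn": 100.0 * n_triple / n_th if n_th else None,
        "flags": set(flags),
    }


def intersect_and_measure(channels: dict, pixel_size_um: float, radius_px: int,
                          bassoon_size: tuple, th_size: tuple, circ_range: tuple) -> dict:
    bsn = segment_particles(channels["bassoon"], pixel_size_um, radius_px, bassoon_size, circ_range)
    th = segment_particles(channels["TH"], pixel_size_um, radius_px, th_size, circ_range)
    kept = []
    all_overlaps = []
    for b in bsn:
        for t in th:
            inter = b["pixels"] & t["pixels"]
            if inter:
                area = len(inter) * pixel_size_um**2
                vpos = roi_positive(inter, channels["VAMP2"])
                all_overlaps.append((area, vpos))
                if vpos:
                    kept.append(area)
    return {
        "n_overlaps": len(all_overlaps),
        "n_kept": len(kept),
        "mean_area": (sum(kept) / len(kept)) if kept else None,
        "overlaps": sorted(all_overlaps),
    }
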