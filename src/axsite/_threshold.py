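"""Histogram thresholding shared by the 2D and 3D segmentation stages."""

from __future__ import annotations

import numpy as np


def intermeans_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Iterative intermeans ("IsoData"-variant) threshold on an intensity array.

    The image histogram is binned into ``nbins`` equal-width bins between the
    data minimum and maximum.  Starting from the middle bin, the cut is moved
    to the rounded midpoint of the mean intensity below and the mean intensity
    above the cut until it stabilises — the classic iterative intermeans rule
    that common particle-analysis tools ship as their default threshold.

    Returns the threshold as an intensity value (upper edge of the cut bin);
    foreground is ``values > threshold``.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("cannot threshold an empty array")
    lo = float(v.min())
    hi = float(v.max())
    if hi == lo:
        # Zero-variance input: nothing can be foreground.
        return hi
    hist, edges = np.histogram(v, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])

    t = nbins // 2
    for _ in range(10_000):
        below = hist[: t + 1]
        above = hist[t + 1 :]
        wb = below.sum()
        wa = above.sum()
        if wb == 0:
            t += 1
            continue
        if wa == 0:
            t -= 1
            continue
        mb = float(np.dot(below, centers[: t + 1]) / wb)
        ma = float(np.dot(above, centers[t + 1 :]) / wa)
        t_new = int(round(((mb + ma) / 2.0 - lo) / (hi - lo) * nbins - 0.5))
        t_new = min(max(t_new, 0), nbins - 2)
        if t_new == t:
            break
        t = t_new
    return float(edges[t + 1])
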