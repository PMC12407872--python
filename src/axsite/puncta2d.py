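"""Particle segmentation and marker colocalization in 2D synaptosome fields.

The chain mirrors a standard FIJI particle-analysis workflow: rolling-ball
background subtraction (morphological opening with a non-flat ball kernel,
default radius 33 px), binarization at the iterative-intermeans ("default")
threshold, 8-connected component labeling, and size/circularity filters.
Marker positivity uses the strict 2x-mean rule: an ROI is positive for a
channel iff its mean intensity is MORE than twice the mean over all pixels
of that channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import label as sk_label
from skimage.measure import perimeter as sk_perimeter

from axsite._threshold import intermeans_threshold
from axsite.synthetic_data import LabeledField2D

__all__ = [
    "Roi",
    "ColocalizationSummary",
    "AreaSummary",
    "rolling_ball_background",
    "segment_particles",
    "classify_roi_positive",
    "colocalization_chain",
    "intersect_and_measure_area",
]

ROLLING_BALL_RADIUS_PX = 33
SIZE_RANGE_DEFAULT = (0.04, 0.40)  # um^2, bassoon/VAMP2 channels
SIZE_RANGE_TH = (0.06, 0.60)  # um^2
CIRC_RANGE_DEFAULT = (0.30, 1.00)
POSITIVITY_FACTOR = 2.0


@dataclass
class Roi:
    """A segmented particle: pixel set plus calibrated shape descriptors."""

    pixels: tuple[np.ndarray, np.ndarray]  # (rows, cols)
    area_px: int
    area_um2: float
    perimeter_um: float
    circularity: float

    def mean_intensity(self, channel: np.ndarray) -> float:
        return float(channel[self.pixels].mean())


@dataclass
class ColocalizationSummary:
    n_vamp2_rois: int
    n_vamp2_pos: int
    n_th_pos: int
    n_triple_pos: int
    pct_th_of_vamp2: float | None
    pct_bassoon_of_double: float | None
    table: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)


@dataclass
class AreaSummary:
    n_overlaps: int
    n_vamp2_pos_overlaps: int
    mean_overlap_area_um2: float | None
    table: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)


def _ball_kernel(radius: int) -> np.ndarray:
    """Non-flat ball structuring element: heights sqrt(r^2 - d^2) on a disk."""
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    d2 = x**2 + y**2
    k = np.full(d2.shape, -np.inf)
    inside = d2 <= radius**2
    k[inside] = np.sqrt(radius**2 - d2[inside].astype(float))
    return k


def rolling_ball_background(image: np.ndarray, radius_px: int = ROLLING_BALL_RADIUS_PX) -> np.ndarray:
    """Rolling-ball background: grayscale opening with the ball kernel.

    Edge handling clamps to the nearest pixel; the opening is pointwise <= the
    image, so the subtracted result is nonnegative.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be > 0")
    k = _ball_kernel(radius_px)
    fp = np.isfinite(k)
    heights = np.where(fp, k, 0.0)
    ero = ndi.grey_erosion(image.astype(float), footprint=fp, structure=heights, mode="nearest")
    return ndi.grey_dilation(ero, footprint=fp, structure=heights, mode="nearest")


def segment_particles(
    channel: np.ndarray,
    pixel_size_um: float,
    radius_px: int = ROLLING_BALL_RADIUS_PX,
    size_range_um2: tuple[float, float] = SIZE_RANGE_DEFAULT,
    circ_range: tuple[float, float] = CIRC_RANGE_DEFAULT,
) -> list[Roi]:
    """Segment particles in one channel.

    Rolling-ball subtraction, intermeans threshold, 8-connected labeling,
    then area (calibrated um^2) and circularity (4*pi*A/P^2, clipped at 1.0)
    filters.  A zero-variance channel yields an empty list.
    """
    img = np.asarray(channel, dtype=float)
    if size_range_um2[0] > size_range_um2[1] or circ_range[0] > circ_range[1]:
        raise ValueError("filter ranges must be ordered")
    if img.std() == 0:
        return []
    sub = img - rolling_ball_background(img, radius_px)
    thr = intermeans_threshold(sub)
    mask = sub > thr
    lab = sk_label(mask, connectivity=2)
    rois: list[Roi] = []
    px_area = pixel_size_um**2
    for lbl in range(1, lab.max() + 1):
        region = lab == lbl
        pix = np.nonzero(region)
        area_px = int(region.sum())
        area_um2 = area_px * px_area
        p_px = float(sk_perimeter(region, neighborhood=4))
        circ = 1.0 if p_px == 0 else min(4.0 * np.pi * area_px / p_px**2, 1.0)
        if size_range_um2[0] <= area_um2 <= size_range_um2[1] and circ_range[0] <= circ <= circ_range[1]:
            rois.append(
                Roi(
                    pixels=pix,
                    area_px=area_px,
                    area_um2=area_um2,
                    perimeter_um=p_px * pixel_size_um,
                    circularity=circ,
                )
            )
    return rois


def classify_roi_positive(
    roi: Roi, channel: np.ndarray, factor: float = POSITIVITY_FACTOR
) -> bool:
    """Strict 2x-mean rule: mean(channel over ROI) > factor * mean(channel)."""
    if roi.pixels[0].size == 0:
        raise ValueError("empty ROI")
    return roi.mean_intensity(channel) > factor * float(np.asarray(channel, float).mean())


def colocalization_chain(
    field: LabeledField2D,
    radius_px: int = ROLLING_BALL_RADIUS_PX,
    size_range_um2: tuple[float, float] = SIZE_RANGE_DEFAULT,
    circ_range: tuple[float, float] = CIRC_RANGE_DEFAULT,
) -> ColocalizationSummary:
    """VAMP2-seeded marker chain.

    ROIs are segmented from the VAMP2 channel and filtered to VAMP2+ by the
    2x-mean rule; TH positivity is classified within those, and bassoon
    positivity within the TH+/VAMP2+ set.  Percentages are reported as
    missing (None) when their denominator is zero.
    """
    vamp2 = field.channels["VAMP2"]
    th = field.channels["TH"]
    bsn = field.channels["bassoon"]
    rois = segment_particles(vamp2, field.pixel_size_um, radius_px, size_range_um2, circ_range)

    rows = []
    n_vpos = n_th = n_triple = 0
    for i, roi in enumerate(rois):
        vpos = classify_roi_positive(roi, vamp2)
        tpos = bpos = False
        if vpos:
            n_vpos += 1
            tpos = classify_roi_positive(roi, th)
            if tpos:
                n_th += 1
                bpos = classify_roi_positive(roi, bsn)
                if bpos:
                    n_triple += 1
        rows.append(
            {
                "roi": i,
                "area_um2": roi.area_um2,
                "circularity": roi.circularity,
                "vamp2_pos": vpos,
                "th_pos": tpos,
                "bassoon_pos": bpos,
            }
        )
    pct_th = 100.0 * n_th / n_vpos if n_vpos else None
    pct_bsn = 100.0 * n_triple / n_th if n_th else None
    return ColocalizationSummary(
        n_vamp2_rois=len(rois),
        n_vamp2_pos=n_vpos,
        n_th_pos=n_th,
        n_triple_pos=n_triple,
        pct_th_of_vamp2=pct_th,
        pct_bassoon_of_double=pct_bsn,
        table=pd.DataFrame(rows),
    )


def intersect_and_measure_area(
    field: LabeledField2D,
    radius_px: int = ROLLING_BALL_RADIUS_PX,
    bassoon_size_um2: tuple[float, float] = SIZE_RANGE_DEFAULT,
    th_size_um2: tuple[float, float] = SIZE_RANGE_TH,
    circ_range: tuple[float, float] = CIRC_RANGE_DEFAULT,
) -> AreaSummary:
    """Bassoon-within-TH overlap areas on VAMP2+ synaptosomes.

    Bassoon and TH are segmented independently (with their own size bands);
    each nonempty pairwise pixel intersection forms an overlap ROI ("AND"
    combination).  Overlaps whose VAMP2 intensity passes the 2x-mean rule are
    kept and their mean area reported; no overlaps means a missing value,
    never zero.
    """
    bsn = field.channels["bassoon"]
    th = field.channels["TH"]
    vamp2 = field.channels["VAMP2"]
    px = field.pixel_size_um

    bsn_rois = segment_particles(bsn, px, radius_px, bassoon_size_um2, circ_range)
    th_rois = segment_particles(th, px, radius_px, th_size_um2, circ_range)

    th_label = np.zeros(th.shape, dtype=int)
    for j, roi in enumerate(th_rois, start=1):
        th_label[roi.pixels] = j

    vamp2_mean = float(np.asarray(vamp2, float).mean())
    rows = []
    kept_areas = []
    for i, broi in enumerate(bsn_rois):
        under = th_label[broi.pixels]
        for j in np.unique(under[under > 0]):
            sel = under == j
            pix = (broi.pixels[0][sel], broi.pixels[1][sel])
            area = pix[0].size * px**2
            vpos = float(vamp2[pix].mean()) > POSITIVITY_FACTOR * vamp2_mean
            rows.append(
                {
                    "bassoon_roi": i,
                    "th_roi": int(j) - 1,
                    "overlap_area_um2": area,
                    "vamp2_pos": vpos,
                }
            )
            if vpos:
                kept_areas.append(area)
    mean_area = float(np.mean(kept_areas)) if kept_areas else None
    return AreaSummary(
        n_overlaps=len(rows),
        n_vamp2_pos_overlaps=len(kept_areas),
        mean_overlap_area_um2=mean_area,
        table=pd.DataFrame(rows),
    )
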