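"""Xenograft slide quantification of GFP-positive cell clusters.

Tumor cryosections are imaged in two channels: Hoechst (nuclei) and
GFP (labeled knockout cells).  The pipeline demarcates the tumor by
dilating and fusing the nuclear signal into a mask, measures the GFP
background (mean and SD) within that mask, thresholds GFP pixels at
``k`` standard deviations above the background mean for k = 4, 5 and 6,
counts the connected GFP-positive clusters within a size window
(excluding large noncellular stains), and sums counts and areas over
all analyzed slides.  Repeating the analysis at the three thresholds
checks that conclusions do not hinge on the cutoff choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from skimage import measure, morphology
from skimage.filters import threshold_otsu

__all__ = [
    "Slide",
    "SlideQuant",
    "TumorSummary",
    "DEFAULT_K_LEVELS",
    "tumor_mask",
    "gfp_background",
    "gfp_threshold",
    "count_clusters",
    "quantify_slide",
    "summarize_tumor",
    "group_ordering_concordance",
]

DEFAULT_K_LEVELS = (4, 5, 6)


@dataclass
class Slide:
    """One tumor section: nuclear and GFP channel images."""

    nuclear: np.ndarray
    gfp: np.ndarray
    pixel_size: float = 1.0  # um per pixel
    slide_index: int = 0

    def __post_init__(self) -> None:
        self.nuclear = np.asarray(self.nuclear, dtype=float)
        self.gfp = np.asarray(self.gfp, dtype=float)
        if self.nuclear.shape != self.gfp.shape:
            raise ValueError("nuclear and GFP channels must share a shape")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be > 0")


class ClusterStats(NamedTuple):
    count: int
    ensemble_area: int  # pixels


@dataclass
class SlideQuant:
    """Per-slide quantification at each thresholding level k."""

    slide_index: int
    tumor_area_px: int
    tumor_area_mm2: float
    background_mean: float
    background_sd: float
    per_k: dict[int, ClusterStats]

    def __post_init__(self) -> None:
        if self.tumor_area_px < 0:
            raise ValueError("tumor area must be >= 0")
        for k, s in self.per_k.items():
            if s.count < 0 or s.ensemble_area < 0:
                raise ValueError("counts and areas must be >= 0")
            if s.ensemble_area > self.tumor_area_px:
                raise ValueError(f"k={k}: ensemble cluster area exceeds tumor area")


def tumor_mask(
    nuclear: np.ndarray,
    *,
    dilation_radius_px: int = 50,
    min_region_px: int = 1000,
    threshold: float | None = None,
) -> tuple[np.ndarray, int]:
    """Tumor mask from the nuclear channel.

    The nuclear foreground (Otsu threshold unless one is supplied) is
    dilated with a disk of ``dilation_radius_px`` so neighboring nuclei
    fuse into one region; regions smaller than ``min_region_px`` are
    discarded as debris and the remainder is the tumor mask.

    Returns (mask, area_px).
    """
    nuclear = np.asarray(nuclear, dtype=float)
    if nuclear.size == 0:
        raise ValueError("empty nuclear image")
    thr = threshold_otsu(nuclear) if threshold is None else threshold
    fg = nuclear > thr
    if not fg.any():
        raise ValueError("empty nuclear foreground; no tumor signal")
    if dilation_radius_px > 0:
        fg = morphology.isotropic_dilation(fg, radius=dilation_radius_px)
    if min_region_px > 0:
        # drop components strictly smaller than min_region_px
        fg = morphology.remove_small_objects(fg, max_size=min_region_px - 1)
    if not fg.any():
        raise ValueError("no region survived the minimum-size filter")
    return fg, int(fg.sum())


def gfp_background(gfp: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    """Mean and SD of GFP intensity over the tumor-mask pixels."""
    gfp = np.asarray(gfp, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if gfp.shape != mask.shape:
        raise ValueError("gfp and mask must share a shape")
    vals = gfp[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    return float(vals.mean()), float(vals.std())


def gfp_threshold(
    gfp: np.ndarray, mask: np.ndarray, mean: float, sd: float, k: float
) -> np.ndarray:
    """Keep GFP-positive pixels; zero everything else.

    A pixel is GFP-positive when it lies inside the tumor mask and its
    intensity strictly exceeds ``mean + k * sd``.
    """
    if not (k > 0):
        raise ValueError("k must be > 0")
    if not (sd > 0):
        raise ValueError("sd must be > 0 (constant background has no threshold scale)")
    gfp = np.asarray(gfp, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    keep = mask & (gfp > mean + k * sd)
    return np.where(keep, gfp, 0.0)


def count_clusters(
    thresholded: np.ndarray,
    *,
    min_cluster_px: int = 10,
    max_cluster_px: int | None = None,
) -> ClusterStats:
    """Count GFP-positive clusters and their ensemble area.

    Connected components (8-connectivity) of the nonzero pixels with
    area in [min_cluster_px, max_cluster_px] are counted; larger
    particles are treated as noncellular stains and excluded from both
    count and area.  An empty image yields (0, 0).
    """
    labels = measure.label(np.asarray(thresholded) > 0, connectivity=2)
    if labels.max() == 0:
        return ClusterStats(0, 0)
    areas = np.bincount(labels.ravel())[1:]
    keep = areas >= min_cluster_px
    if max_cluster_px is not None:
        keep &= areas <= max_cluster_px
    return ClusterStats(int(keep.sum()), int(areas[keep].sum()))


def quantify_slide(
    slide: Slide,
    *,
    k_levels: Sequence[int] = DEFAULT_K_LEVELS,
    dilation_radius_px: int = 50,
    min_region_px: int = 1000,
    min_cluster_px: int = 10,
    max_cluster_frac: float = 0.05,
    nuclear_threshold: float | None = None,
) -> SlideQuant:
    """Full per-slide pipeline: mask, background, threshold, clusters.

    ``max_cluster_frac`` sets the large-particle cutoff as a fraction of
    the tumor area (default 5%).
    """
    mask, area_px = tumor_mask(
        slide.nuclear,
        dilation_radius_px=dilation_radius_px,
        min_region_px=min_region_px,
        threshold=nuclear_threshold,
    )
    mean, sd = gfp_background(slide.gfp, mask)
    max_px = int(max_cluster_frac * area_px) if max_cluster_frac else None
    per_k: dict[int, ClusterStats] = {}
    for k in k_levels:
        thr_img = gfp_threshold(slide.gfp, mask, mean, sd, k)
        per_k[k] = count_clusters(
            thr_img, min_cluster_px=min_cluster_px, max_cluster_px=max_px
        )
    area_mm2 = area_px * (slide.pixel_size / 1000.0) ** 2
    return SlideQuant(
        slide_index=slide.slide_index,
        tumor_area_px=area_px,
        tumor_area_mm2=area_mm2,
        background_mean=mean,
        background_sd=sd,
        per_k=per_k,
    )


@dataclass
class TumorSummary:
    """Whole-tumor totals: per-k cluster count/area and tumor area."""

    n_slides: int
    tumor_area_px: int
    tumor_area_mm2: float
    per_k: dict[int, ClusterStats]


def summarize_tumor(slides: Sequence[SlideQuant]) -> TumorSummary:
    """Sum cluster counts, cluster areas and tumor area over slides."""
    if not slides:
        raise ValueError("no slides to summarize")
    k_sets = {tuple(sorted(s.per_k)) for s in slides}
    if len(k_sets) != 1:
        raise ValueError("slides were quantified at differing k levels")
    ks = k_sets.pop()
    per_k = {
        k: ClusterStats(
            count=sum(s.per_k[k].count for s in slides),
            ensemble_area=sum(s.per_k[k].ensemble_area for s in slides),
        )
        for k in ks
    }
    return TumorSummary(
        n_slides=len(slides),
        tumor_area_px=sum(s.tumor_area_px for s in slides),
        tumor_area_mm2=sum(s.tumor_area_mm2 for s in slides),
        per_k=per_k,
    )


def group_ordering_concordance(
    groups: Mapping[str, TumorSummary], *, metric: str = "ensemble_area"
) -> dict:
    """Check that group orderings agree across thresholding levels.

    For each k the groups (e.g. left vs right flank tumors) are ranked
    by total cluster count or ensemble area; the report says whether the
    ordering is the same at every k — the robustness check that the
    biological inference does not depend on the threshold choice.
    """
    if not groups:
        raise ValueError("no groups")
    ks = sorted(next(iter(groups.values())).per_k)
    orderings = {}
    for k in ks:
        if metric == "ensemble_area":
            key = lambda name: groups[name].per_k[k].ensemble_area
        elif metric == "count":
            key = lambda name: groups[name].per_k[k].count
        else:
            raise ValueError(f"unknown metric {metric!r}")
        orderings[k] = tuple(sorted(groups, key=key, reverse=True))
    concordant = len(set(orderings.values())) == 1
    return {"metric": metric, "orderings": orderings, "concordant": concordant}
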