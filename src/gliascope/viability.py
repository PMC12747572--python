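"""Live/dead viability from three-channel (nuclei / live / dead) fields.

Total cells are counted from the nucleus channel (Hoechst-type stain):
Gaussian blur, Otsu threshold, size-filtered connected components, and a
distance-transform watershed to split touching pairs. Dead cells are nuclei
whose surrounding disk in the dead channel (EthD-1-type stain) exceeds an
Otsu-derived cutoff; dead signal with no matching nucleus is ignored. Live
cells are the difference, and viability (%) = 100 · live / total. The
calcein (live) channel is not needed for the counts and is kept only for
inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import watershed

from .errors import DegenerateInputError, SpecError
from .images import MultichannelImage

logger = logging.getLogger(__name__)

__all__ = [
    "ViabilityConfig",
    "ViabilityCounts",
    "count_nuclei",
    "count_dead",
    "compute_viability",
    "analyze_field",
]


@dataclass
class ViabilityConfig:
    blur_sigma_px: float = 2.0
    min_nucleus_area_px: int = 20
    split_min_distance_px: int = 5
    dead_disk_radius_px: float = 4.0
    # genuine stain must sit this many background-sd above the background mean,
    # otherwise Otsu is just splitting noise and the field counts as empty
    min_contrast_snr: float = 3.0

    def __post_init__(self) -> None:
        if self.min_nucleus_area_px <= 0 or self.split_min_distance_px <= 0:
            raise SpecError("area and distance parameters must be positive")


@dataclass
class ViabilityCounts:
    total: int
    dead: int

    def __post_init__(self) -> None:
        if self.total < 0 or self.dead < 0 or self.dead > self.total:
            raise SpecError("need 0 <= dead <= total")

    @property
    def live(self) -> int:
        return self.total - self.dead

    @property
    def viability_pct(self) -> float:
        return compute_viability(self.total, self.dead)


def count_nuclei(
    nucleus_channel: np.ndarray, cfg: ViabilityConfig | None = None
) -> tuple[int, np.ndarray]:
    """Count nuclei and return their centroids as an (N, 2) array of (y, x).

    Blur → Otsu → size filter → distance-transform peak splitting (watershed)
    for touching pairs. An image that thresholds to empty returns 0.
    """
    cfg = cfg or ViabilityConfig()
    img = np.asarray(nucleus_channel, dtype=float)
    if img.max() == img.min():
        raise DegenerateInputError("nucleus channel is single-valued")
    smoothed = ndi.gaussian_filter(img, cfg.blur_sigma_px)
    binary = smoothed > threshold_otsu(smoothed)
    if binary.any() and not binary.all():
        contrast = smoothed[binary].mean() - smoothed[~binary].mean()
        bg_sd = max(float(img[~binary].std()), 1e-12)
        if contrast < cfg.min_contrast_snr * bg_sd:
            logger.info("count_nuclei: foreground contrast below noise floor; 0 nuclei")
            return 0, np.empty((0, 2))
    labels = cc_label(binary)
    for region in regionprops(labels):
        if region.area < cfg.min_nucleus_area_px:
            binary[labels == region.label] = False
    if not binary.any():
        return 0, np.empty((0, 2))
    dist = ndi.distance_transform_edt(binary)
    peaks = peak_local_max(
        dist, min_distance=cfg.split_min_distance_px, labels=cc_label(binary),
        exclude_border=False,
    )
    if peaks.shape[0] == 0:
        segmented = cc_label(binary)
    else:
        markers = np.zeros_like(dist, dtype=int)
        markers[tuple(peaks.T)] = np.arange(1, peaks.shape[0] + 1)
        segmented = watershed(-dist, markers, mask=binary)
    centroids = np.array([r.centroid for r in regionprops(segmented)])
    return int(segmented.max()), centroids


def count_dead(
    dead_channel: np.ndarray,
    nuclei_centroids: np.ndarray,
    cfg: ViabilityConfig | None = None,
) -> int:
    """Number of nuclei whose dead-channel disk mean exceeds the Otsu cutoff.

    A single-valued (blank) dead channel yields 0. Dead signal that is not
    colocalised with any nucleus is not counted (logged only).
    """
    cfg = cfg or ViabilityConfig()
    img = np.asarray(dead_channel, dtype=float)
    if nuclei_centroids.shape[0] == 0:
        return 0
    if img.max() == img.min():
        return 0
    cutoff = threshold_otsu(ndi.gaussian_filter(img, cfg.blur_sigma_px))
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    dead = 0
    claimed = np.zeros_like(img, dtype=bool)
    for cy, cx in nuclei_centroids:
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= cfg.dead_disk_radius_px**2
        if img[disk].mean() > cutoff:
            dead += 1
        claimed |= disk
    orphan = (img > cutoff) & ~claimed
    n_orphan = int(cc_label(orphan).max())
    if n_orphan:
        logger.info("count_dead: %d dead-signal blobs without a nucleus ignored", n_orphan)
    return dead


def compute_viability(total: int, dead: int) -> float:
    """Viability (%) = 100 · (total − dead) / total."""
    if total < 1:
        raise SpecError("total must be >= 1")
    if dead > total or dead < 0:
        raise SpecError("need 0 <= dead <= total")
    return 100.0 * (total - dead) / total


def analyze_field(
    image: MultichannelImage, cfg: ViabilityConfig | None = None
) -> ViabilityCounts:
    """Counts for one field; channels ordered (nuclei, live, dead)."""
    cfg = cfg or ViabilityConfig()
    total, centroids = count_nuclei(image.channel(0), cfg)
    if total == 0:
        raise DegenerateInputError("no nuclei found in field")
    dead = count_dead(image.channel(2), centroids, cfg)
    return ViabilityCounts(total=total, dead=dead)
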