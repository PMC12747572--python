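"""3-D astrocyte morphometry: segmentation and five shape descriptors.

The chain mirrors a confocal morphometry workflow for membrane/nucleus-stained
cultures: per-channel contrast normalisation, Gaussian blur and thresholding;
block down-sampling to a coarse "unit" grid; density-based clustering (DBSCAN)
of the foreground voxels into cells and nuclei; volumetric filtering of
fragments; nucleus-to-cell matching; then five per-cell descriptors —

* **aspect ratio** — max Y range / max X range of the cell's voxels;
* **circularity** — ``C = 4πA/P²`` of an ellipse fitted from the X/Y ranges,
  which reduces to ``2XY/(X²+Y²)`` (an optional mode uses the true projected
  area with the ellipse perimeter);
* **centroid distance** — Euclidean distance between body and nucleus
  centroids;
* **solidity** — convex-hull volume over body volume (≥ 1, hull-over-body
  orientation), hulls taken over voxel-cube corner points;
* **ramification** — ``(P/A)/(2√(π/A))`` of the maximum-area axis projection,
  with the perimeter from that projection's 2-D convex hull (1 for a disk).

QC excludes cells without a nucleus, with body–nucleus centroid distances
beyond a cutoff, with degenerate geometry, and per-metric iterative Grubbs
outliers. All lengths are in "units" (down-sampled voxel edges); the default
conversion is 0.62 μm per unit.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull, QhullError
from skimage.filters import threshold_otsu
from sklearn.cluster import DBSCAN

from .errors import ConfigError, DegenerateInputError
from .images import VolumetricImage
from .stats import grubbs

logger = logging.getLogger(__name__)

__all__ = [
    "MorphConfig",
    "VoxelCloud",
    "SegmentedCell",
    "MorphologyRecord",
    "preprocess_stack",
    "segment_cells",
    "filter_components",
    "match_nuclei",
    "aspect_ratio",
    "circularity",
    "centroid_distance",
    "solidity",
    "ramification",
    "build_records",
    "apply_qc",
    "analyze_stack",
    "records_to_dataframe",
]

METRIC_NAMES = ("aspect_ratio", "circularity", "centroid_distance_units", "solidity", "ramification")


@dataclass
class MorphConfig:
    """Tunable parameters of the morphometry chain (lengths in the noted units)."""

    blur_sigma_px: float = 2.0
    threshold_method: str = "otsu"  # or "fixed"
    fixed_threshold: float | None = None  # on the [0, 1] normalised scale
    downsample_factor: int = 4
    dbscan_eps: float = 2.0  # units
    dbscan_min_samples: int = 10
    min_cell_volume_units: float = 50.0
    min_nucleus_volume_units: float = 5.0
    max_centroid_distance_units: float = 100.0
    unit_to_um: float = 0.62
    grubbs_alpha: float = 0.05
    circularity_mode: str = "ellipse"  # or "projected_area"

    def __post_init__(self) -> None:
        if self.downsample_factor < 1:
            raise ConfigError("downsample_factor must be >= 1")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ConfigError(f"unknown threshold_method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ConfigError("fixed_threshold required with threshold_method='fixed'")
        if min(self.min_cell_volume_units, self.min_nucleus_volume_units) <= 0:
            raise ConfigError("volume filters must be positive")
        if self.max_centroid_distance_units <= 0:
            raise ConfigError("max_centroid_distance_units must be positive")
        if not 0 < self.grubbs_alpha < 1:
            raise ConfigError("grubbs_alpha must be in (0, 1)")
        if self.circularity_mode not in ("ellipse", "projected_area"):
            raise ConfigError(f"unknown circularity_mode {self.circularity_mode!r}")


@dataclass
class VoxelCloud:
    """Binary voxel coordinates on the down-sampled "unit" grid, (Z, Y, X)."""

    coordinates: np.ndarray  # (N, 3) int
    channel: str = "cell"

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.int64).reshape(-1, 3)

    @property
    def is_empty(self) -> bool:
        return self.coordinates.shape[0] == 0


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _binarize_channel(img: np.ndarray, cfg: MorphConfig, name: str) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    lo, hi = img.min(), img.max()
    if hi == lo:
        raise DegenerateInputError(f"channel {name!r} is single-valued; cannot threshold")
    img = (img - lo) / (hi - lo)
    if cfg.blur_sigma_px > 0:
        img = gaussian_filter(img, cfg.blur_sigma_px)
    if cfg.threshold_method == "otsu":
        thr = threshold_otsu(img)
    else:
        thr = float(cfg.fixed_threshold)
    return img > thr


def _downsample_majority(binary: np.ndarray, factor: int) -> np.ndarray:
    """Block-pool a binary volume: a block becomes foreground by strict majority."""
    if factor == 1:
        return binary
    pad = [(0, (-s) % factor) for s in binary.shape]
    padded = np.pad(binary, pad, mode="constant", constant_values=False)
    z, y, x = (s // factor for s in padded.shape)
    blocks = padded.reshape(z, factor, y, factor, x, factor)
    frac = blocks.mean(axis=(1, 3, 5))
    return frac > 0.5


def preprocess_stack(
    stack: VolumetricImage, cfg: MorphConfig
) -> tuple[VoxelCloud, VoxelCloud]:
    """Normalise, blur, threshold and down-sample both channels to voxel clouds.

    Channel 0 is the membrane/cell stain, channel 1 the nucleus stain. Each
    channel is min-max normalised to [0, 1], blurred, thresholded (Otsu by
    default) and block-pooled by majority vote into the unit grid.
    """
    if stack.n_channels < 2:
        raise DegenerateInputError("stack must carry membrane and nucleus channels")
    clouds = []
    for idx, name in ((0, "cell"), (1, "nucleus")):
        binary = _binarize_channel(stack.channel(idx), cfg, name)
        units = _downsample_majority(binary, cfg.downsample_factor)
        clouds.append(VoxelCloud(coordinates=np.argwhere(units), channel=name))
    return clouds[0], clouds[1]


# ---------------------------------------------------------------------------
# Segmentation and geometry
# ---------------------------------------------------------------------------

_CUBE_CORNERS = np.array(
    [[dz, dy, dx] for dz in (0, 1) for dy in (0, 1) for dx in (0, 1)], dtype=np.int64
)
_SQUARE_CORNERS = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int64)


@dataclass
class Projection:
    """One axis-aligned 2-D binary projection of a voxel set."""

    axis: int  # dropped axis (0=Z, 1=Y, 2=X)
    pixels: np.ndarray  # (M, 2) unique pixel coordinates
    area: float  # pixel count (unit squares)
    hull_perimeter: float  # perimeter of the 2-D hull over pixel corners


@dataclass
class SegmentedCell:
    """A segmented voxel cluster with all derived geometry populated."""

    voxels: VoxelCloud
    volume_units: int = 0
    range_z: int = 0
    range_y: int = 0
    range_x: int = 0
    centroid: np.ndarray = field(default_factory=lambda: np.zeros(3))
    hull_volume_units: float = 0.0
    projections: dict[int, Projection] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)


def _build_projection(coords: np.ndarray, axis: int) -> Projection:
    keep = [d for d in range(3) if d != axis]
    pixels = np.unique(coords[:, keep], axis=0)
    corners = (pixels[:, None, :] + _SQUARE_CORNERS[None, :, :]).reshape(-1, 2)
    corners = np.unique(corners, axis=0)
    # scipy 2-D hulls report perimeter as .area
    perimeter = float(ConvexHull(corners.astype(float)).area)
    return Projection(axis=axis, pixels=pixels, area=float(len(pixels)), hull_perimeter=perimeter)


def make_cell(coords: np.ndarray, channel: str = "cell") -> SegmentedCell:
    """Materialise a voxel cluster: volume, ranges, centroid, hull, projections.

    The convex hull is taken over the 8 corner points of every voxel cube, so
    even flat or single-voxel bodies have a full-dimensional hull and solidity
    stays finite.
    """
    coords = np.asarray(coords, dtype=np.int64).reshape(-1, 3)
    cell = SegmentedCell(voxels=VoxelCloud(coords, channel=channel))
    cell.volume_units = coords.shape[0]
    mins, maxs = coords.min(axis=0), coords.max(axis=0)
    cell.range_z, cell.range_y, cell.range_x = (maxs - mins + 1).tolist()
    cell.centroid = coords.mean(axis=0) + 0.5  # centre of mass of voxel cubes
    corner_pts = (coords[:, None, :] + _CUBE_CORNERS[None, :, :]).reshape(-1, 3)
    corner_pts = np.unique(corner_pts, axis=0).astype(float)
    try:
        cell.hull_volume_units = float(ConvexHull(corner_pts).volume)
    except QhullError:  # pragma: no cover - corner points span 3-D by construction
        cell.hull_volume_units = float(cell.volume_units)
        cell.flags.add("boundary_abnormal")
    for axis in range(3):
        cell.projections[axis] = _build_projection(coords, axis)
    return cell


def segment_cells(cloud: VoxelCloud, cfg: MorphConfig) -> list[SegmentedCell]:
    """Cluster a voxel cloud into cells with DBSCAN; noise voxels are dropped.

    Output is sorted by centroid (lexicographic Z, Y, X) so clustering order
    never affects downstream records.
    """
    if cloud.is_empty:
        warnings.warn(f"empty {cloud.channel} cloud: nothing to segment", stacklevel=2)
        return []
    labels = DBSCAN(eps=cfg.dbscan_eps, min_samples=cfg.dbscan_min_samples).fit_predict(
        cloud.coordinates
    )
    cells = [
        make_cell(cloud.coordinates[labels == lab], channel=cloud.channel)
        for lab in sorted(set(labels) - {-1})
    ]
    n_noise = int(np.sum(labels == -1))
    if n_noise:
        logger.info("segment_cells(%s): %d noise voxels dropped", cloud.channel, n_noise)
    cells.sort(key=lambda c: tuple(c.centroid))
    return cells


def filter_components(
    cells: list[SegmentedCell],
    nuclei: list[SegmentedCell],
    cfg: MorphConfig,
) -> tuple[list[SegmentedCell], list[SegmentedCell]]:
    """Drop fragments: cells below the cell-volume cutoff, nuclei below theirs.

    The rule is strict "below": a body exactly at the cutoff is retained.
    """
    kept_cells = [c for c in cells if c.volume_units >= cfg.min_cell_volume_units]
    kept_nuclei = [n for n in nuclei if n.volume_units >= cfg.min_nucleus_volume_units]
    logger.info(
        "filter_components: dropped %d cells, %d nuclei",
        len(cells) - len(kept_cells),
        len(nuclei) - len(kept_nuclei),
    )
    return kept_cells, kept_nuclei


def match_nuclei(
    cells: list[SegmentedCell],
    nuclei: list[SegmentedCell],
    cfg: MorphConfig | None = None,
) -> list[tuple[int, int | None]]:
    """Assign nuclei to cells; returns ``(cell_index, nucleus_index or None)``.

    A nucleus belongs to the cell whose voxel set contains its centroid;
    failing containment, to the nearest cell centroid within the configured
    radius. Each cell keeps at most one nucleus (nearest wins; ties break
    toward the lower cell index, and the decision is logged).
    """
    max_radius = (cfg or MorphConfig()).max_centroid_distance_units
    voxel_sets = [set(map(tuple, c.voxels.coordinates)) for c in cells]
    # candidate assignment per nucleus: (cell_idx, distance)
    proposals: list[tuple[int, int, float]] = []  # (nucleus_idx, cell_idx, dist)
    for ni, nuc in enumerate(nuclei):
        host = None
        vox = tuple(np.floor(nuc.centroid).astype(int))
        containing = [ci for ci, vs in enumerate(voxel_sets) if vox in vs]
        if containing:
            host = min(containing)
        if host is None:
            dists = [float(np.linalg.norm(c.centroid - nuc.centroid)) for c in cells]
            in_range = [(d, ci) for ci, d in enumerate(dists) if d <= max_radius]
            if in_range:
                d_min = min(in_range)[0]
                tied = sorted(ci for d, ci in in_range if d == d_min)
                host = tied[0]
                if len(tied) > 1:
                    logger.info(
                        "nucleus %d equidistant from cells %s; assigned to %d",
                        ni, tied, host,
                    )
        if host is not None:
            proposals.append((ni, host, float(np.linalg.norm(cells[host].centroid - nuc.centroid))))
    best: dict[int, tuple[float, int]] = {}
    for ni, ci, d in proposals:
        if ci not in best or (d, ni) < best[ci]:
            best[ci] = (d, ni)
    return [(ci, best[ci][1] if ci in best else None) for ci in range(len(cells))]


# ---------------------------------------------------------------------------
# Shape descriptors
# ---------------------------------------------------------------------------

def aspect_ratio(cell: SegmentedCell) -> float:
    """Maximum Y extent over maximum X extent (both ≥ 1 voxel)."""
    return cell.range_y / cell.range_x


def circularity(cell: SegmentedCell, cfg: MorphConfig | None = None) -> float:
    """``4πA/P²`` with the ellipse fitted from the X/Y ranges.

    In the default ``ellipse`` mode both A and P come from the fitted ellipse
    (semi-axes X = range_x/2, Y = range_y/2; perimeter by the
    ``2π√((X²+Y²)/2)`` approximation), which simplifies to ``2XY/(X²+Y²)`` —
    1 for X = Y, → 0 with elongation. ``projected_area`` mode keeps the
    ellipse perimeter but uses the true XY-projected area.
    """
    cfg = cfg or MorphConfig()
    x, y = cell.range_x / 2.0, cell.range_y / 2.0
    if cfg.circularity_mode == "ellipse":
        return 2.0 * x * y / (x * x + y * y)
    p_ellipse = 2.0 * math.pi * math.sqrt((x * x + y * y) / 2.0)
    a_actual = cell.projections[0].area  # projection along Z = XY plane
    return 4.0 * math.pi * a_actual / (p_ellipse**2)


def centroid_distance(cell: SegmentedCell, nucleus: SegmentedCell,
                      cfg: MorphConfig | None = None) -> tuple[float, float]:
    """Euclidean body–nucleus centroid distance; returns ``(units, μm)``."""
    cfg = cfg or MorphConfig()
    d = float(np.linalg.norm(np.asarray(cell.centroid) - np.asarray(nucleus.centroid)))
    return d, d * cfg.unit_to_um


def solidity(cell: SegmentedCell) -> float:
    """Convex-hull volume over body volume (≥ 1; 1 iff the body is convex).

    Note the hull-over-body orientation: larger values mean less convex
    (more ramified) bodies, the reverse of the common area-fraction solidity.
    """
    return cell.hull_volume_units / cell.volume_units


def ramification(cell: SegmentedCell) -> float:
    """Contour complexity of the maximum-area axis projection.

    ``R = (P/A) / (2√(π/A))`` with A the projected area and P the perimeter
    of that projection's convex hull; R = 1 for a disk, 2/√π for a square.
    """
    proj = max(cell.projections.values(), key=lambda p: (p.area, -p.axis))
    a, p = proj.area, proj.hull_perimeter
    return (p / a) / (2.0 * math.sqrt(math.pi / a))


# ---------------------------------------------------------------------------
# Records and QC
# ---------------------------------------------------------------------------

@dataclass
class MorphologyRecord:
    """Per-cell descriptor row plus QC flags; excluded from summaries iff flagged."""

    cell_id: int
    aspect_ratio: float
    circularity: float
    centroid_distance_units: float
    centroid_distance_um: float
    solidity: float
    ramification: float
    volume_units: int
    nucleus_id: int | None
    qc_flags: set[str] = field(default_factory=set)


def build_records(
    cells: list[SegmentedCell],
    nuclei: list[SegmentedCell],
    matches: list[tuple[int, int | None]],
    cfg: MorphConfig,
) -> list[MorphologyRecord]:
    """Score every cell; flags (not silent drops) mark QC failures."""
    records = []
    for ci, ni in matches:
        cell = cells[ci]
        flags = set(cell.flags)
        if ni is None:
            flags.add("no_nucleus")
            d_units = d_um = float("nan")
        else:
            d_units, d_um = centroid_distance(cell, nuclei[ni], cfg)
            if d_units > cfg.max_centroid_distance_units:
                flags.add("centroid_out_of_range")
        rec = MorphologyRecord(
            cell_id=ci,
            aspect_ratio=aspect_ratio(cell),
            circularity=circularity(cell, cfg),
            centroid_distance_units=d_units,
            centroid_distance_um=d_um,
            solidity=solidity(cell),
            ramification=ramification(cell),
            volume_units=cell.volume_units,
            nucleus_id=ni,
            qc_flags=flags,
        )
        for name in ("aspect_ratio", "circularity", "solidity", "ramification"):
            v = getattr(rec, name)
            if not np.isfinite(v) or v <= 0:
                rec.qc_flags.add("boundary_abnormal")
        records.append(rec)
    return records


def apply_qc(
    records: list[MorphologyRecord], cfg: MorphConfig
) -> tuple[list[MorphologyRecord], list[MorphologyRecord]]:
    """Split records into kept and excluded.

    Flag-based exclusions (missing nucleus, out-of-range centroid distance,
    degenerate geometry) happen first; the survivors are then screened per
    metric with the iterative two-sided Grubbs test, flagging one record per
    iteration until none is significant. Grubbs needs ≥ 3 records, otherwise
    it is skipped with a warning.
    """
    kept = [r for r in records if not r.qc_flags]
    excluded = [r for r in records if r.qc_flags]
    if len(kept) < 3:
        if kept:
            warnings.warn("fewer than 3 records: Grubbs outlier screen skipped", stacklevel=2)
        return kept, excluded
    for metric in METRIC_NAMES:
        values = [getattr(r, metric) for r in kept]
        if any(not np.isfinite(v) for v in values):
            continue
        for idx in grubbs(values, alpha=cfg.grubbs_alpha):
            kept[idx].qc_flags.add("grubbs_outlier")
        flagged = [r for r in kept if r.qc_flags]
        if flagged:
            excluded.extend(flagged)
            kept = [r for r in kept if not r.qc_flags]
        if len(kept) < 3:
            break
    return kept, excluded


def records_to_dataframe(records: list[MorphologyRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {k: v for k, v in vars(r).items() if k != "qc_flags"}
        row["qc_flags"] = ";".join(sorted(r.qc_flags))
        rows.append(row)
    columns = [
        "cell_id", "aspect_ratio", "circularity", "centroid_distance_units",
        "centroid_distance_um", "solidity", "ramification", "volume_units",
        "nucleus_id", "qc_flags",
    ]
    return pd.DataFrame(rows, columns=columns)


def analyze_stack(
    stack: VolumetricImage, cfg: MorphConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full chain: preprocess → segment → filter → match → score → QC.

    Returns ``(kept, excluded)`` data frames of per-cell records.
    """
    cfg = cfg or MorphConfig()
    cell_cloud, nucleus_cloud = preprocess_stack(stack, cfg)
    cells = segment_cells(cell_cloud, cfg)
    nuclei = segment_cells(nucleus_cloud, cfg)
    cells, nuclei = filter_components(cells, nuclei, cfg)
    matches = match_nuclei(cells, nuclei, cfg)
    records = build_records(cells, nuclei, matches, cfg)
    kept, excluded = apply_qc(records, cfg)
    return records_to_dataframe(kept), records_to_dataframe(excluded)
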