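"""Seeded synthetic microscopy inputs with exact ground truth.

Three generators emulate the three kinds of data the pipeline consumes:

* **morphology stacks** — two-channel 3-D volumes (membrane, nucleus) holding
  blob-like cells (ellipsoids by default, optionally stellate bodies with
  radiating arms) with offset nuclear spheres, Gaussian blur and read noise;
* **calcium movies / traces** — ΔF/F transients with the rise-then-decay
  waveform ``A·(1 − e^{−Δ/τ_r})·e^{−Δ/τ_d}`` riding on a baseline with
  optional exponential bleach and Gaussian noise (10 Hz, 5 min by default,
  matching the acquisition the analysis chain targets);
* **viability fields** — three-channel (nuclei / live / dead) spot images
  with known total and dead counts.

Every generator is bit-reproducible for a fixed spec + seed, and returns the
analytic ground truth the recovery tests score against. Placement is
reject-and-retry, bounded, so truth objects never overlap and segmentation
ground truth is unambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import PlacementError, SpecError
from .images import CalciumMovie, MultichannelImage, VolumetricImage

__all__ = [
    "CellTruth",
    "MorphStackSpec",
    "EventTruth",
    "CalciumMovieSpec",
    "CalciumCellSpec",
    "ViabilityFieldSpec",
    "generate_morphology_stack",
    "generate_calcium_movie",
    "generate_trace",
    "generate_viability_field",
    "random_cell_truths",
    "random_events",
    "transient_waveform",
    "waveform_peak",
]


# ---------------------------------------------------------------------------
# Morphology stacks
# ---------------------------------------------------------------------------

@dataclass
class CellTruth:
    """Analytic description of one synthetic cell body plus nucleus.

    Coordinates are physical μm in (Z, Y, X) order. The body is an
    axis-aligned ellipsoid with ``semi_axes_um``; when ``n_arms > 0`` a
    stellate body is rendered instead: the same core with ``n_arms``
    cylindrical arms radiating in the XY plane (analytic volume is then not
    tracked and :attr:`volume_um3` is ``None``).
    """

    center_um: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float]
    nucleus_offset_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    nucleus_radius_um: float = 2.0
    intensity: float = 200.0
    n_arms: int = 0
    arm_length_um: float = 0.0
    arm_width_um: float = 0.0

    def __post_init__(self) -> None:
        a = np.asarray(self.semi_axes_um, dtype=float)
        if np.any(a <= 0):
            raise SpecError("semi axes must be positive")
        if self.nucleus_radius_um <= 0:
            raise SpecError("nucleus radius must be positive")
        # conservative containment: nucleus sphere inside the ellipsoid body
        o = np.abs(np.asarray(self.nucleus_offset_um, dtype=float))
        if np.sum(((o + self.nucleus_radius_um) / a) ** 2) > 1.0 + 1e-9:
            raise SpecError("nucleus not fully inside cell body")
        if self.intensity <= 0:
            raise SpecError("intensity must be positive")

    # -- analytic truth ----------------------------------------------------
    @property
    def volume_um3(self) -> float | None:
        if self.n_arms:
            return None
        a, b, c = self.semi_axes_um
        return 4.0 / 3.0 * math.pi * a * b * c

    @property
    def ranges_um(self) -> tuple[float, float, float]:
        """Axis-aligned extent (Z, Y, X): 2× the semi-axes for an ellipsoid."""
        z, y, x = (2 * s for s in self.semi_axes_um)
        if self.n_arms:
            span = 2 * max(self.arm_length_um, max(self.semi_axes_um[1:]))
            y, x = span, span
        return (z, y, x)

    @property
    def aspect_ratio(self) -> float:
        _, ry, rx = self.ranges_um
        return ry / rx

    @property
    def nucleus_center_um(self) -> tuple[float, float, float]:
        return tuple(c + o for c, o in zip(self.center_um, self.nucleus_offset_um))

    @property
    def centroid_distance_um(self) -> float:
        return float(np.linalg.norm(self.nucleus_offset_um))


@dataclass
class MorphStackSpec:
    """Recipe for one two-channel (membrane, nucleus) volumetric stack."""

    grid_shape: tuple[int, int, int]  # (Z, Y, X) voxels
    voxel_pitch_um: float
    cells: Sequence[CellTruth]
    background_level: float = 10.0
    noise_sd: float = 2.0
    blur_sigma_um: float = 0.5
    shell_thickness_um: float | None = None  # None => filled bodies
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape):
            raise SpecError("grid_shape must be positive")
        if self.voxel_pitch_um <= 0:
            raise SpecError("voxel pitch must be positive")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        for c in self.cells:
            if c.intensity <= self.background_level:
                raise SpecError("cell intensity must exceed background")
        _check_disjoint(self.cells)


def _bbox(cell: CellTruth) -> tuple[np.ndarray, np.ndarray]:
    c = np.asarray(cell.center_um)
    half = np.asarray(cell.ranges_um) / 2.0
    return c - half, c + half


def _check_disjoint(cells: Sequence[CellTruth]) -> None:
    for i in range(len(cells)):
        lo_i, hi_i = _bbox(cells[i])
        for j in range(i + 1, len(cells)):
            lo_j, hi_j = _bbox(cells[j])
            if np.all(hi_i > lo_j) and np.all(hi_j > lo_i):
                raise PlacementError(f"cells {i} and {j} overlap (bounding boxes)")


def random_cell_truths(
    n_cells: int,
    grid_shape: tuple[int, int, int],
    voxel_pitch_um: float,
    rng: np.random.Generator,
    semi_axes_range_um: tuple[float, float] = (6.0, 12.0),
    nucleus_radius_um: float = 2.5,
    intensity: float = 200.0,
    clearance_um: float = 5.0,
    max_tries: int = 1000,
) -> list[CellTruth]:
    """Draw ``n_cells`` non-overlapping ellipsoid cells by reject-and-retry.

    Candidate bodies keep ``clearance_um`` of empty space between bounding
    boxes so blur halos never bridge neighbours. Raises
    :class:`PlacementError` after ``max_tries`` failed placements, so
    infeasible densities fail loudly instead of looping forever.
    """
    extent = np.asarray(grid_shape) * voxel_pitch_um
    placed: list[CellTruth] = []
    tries = 0
    while len(placed) < n_cells:
        if tries >= max_tries:
            raise PlacementError(
                f"placed {len(placed)}/{n_cells} cells after {max_tries} tries"
            )
        tries += 1
        semi = rng.uniform(*semi_axes_range_um, size=3)
        margin = semi + 2.0  # keep blur halo inside the grid
        if np.any(extent <= 2 * margin):
            raise PlacementError("grid too small for requested cell size")
        center = rng.uniform(margin, extent - margin)
        # nucleus offset inside the body with room for its radius
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        frac = rng.uniform(0.0, 0.4)
        offset = direction * frac * (semi.min() - nucleus_radius_um)
        cand = CellTruth(
            center_um=tuple(center),
            semi_axes_um=tuple(semi),
            nucleus_offset_um=tuple(offset),
            nucleus_radius_um=nucleus_radius_um,
            intensity=intensity,
        )
        inflated = replace(cand, semi_axes_um=tuple(s + clearance_um / 2 for s in semi))
        try:
            _check_disjoint(placed + [inflated])
        except PlacementError:
            continue
        placed.append(cand)
    return placed


def _render_body(
    membrane: np.ndarray,
    nucleus: np.ndarray,
    cell: CellTruth,
    pitch: float,
    shell_thickness_um: float | None,
) -> None:
    grid_shape = membrane.shape
    lo, hi = _bbox(cell)
    lo_idx = np.maximum(np.floor(lo / pitch).astype(int) - 1, 0)
    hi_idx = np.minimum(np.ceil(hi / pitch).astype(int) + 2, grid_shape)
    axes = [
        (np.arange(lo_idx[d], hi_idx[d]) + 0.5) * pitch - cell.center_um[d]
        for d in range(3)
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    a, b, c = cell.semi_axes_um
    inside = (zz / a) ** 2 + (yy / b) ** 2 + (xx / c) ** 2 <= 1.0
    if shell_thickness_um is not None:
        ai, bi, ci = (max(s - shell_thickness_um, 1e-6) for s in (a, b, c))
        core = (zz / ai) ** 2 + (yy / bi) ** 2 + (xx / ci) ** 2 <= 1.0
        inside &= ~core
    if cell.n_arms:
        # arms radiate in the XY plane from the body centre
        for k in range(cell.n_arms):
            theta = 2 * math.pi * k / cell.n_arms
            uy, ux = math.sin(theta), math.cos(theta)
            along = yy * uy + xx * ux
            perp2 = (yy * ux - xx * uy) ** 2 + zz**2
            arm = (
                (along >= 0)
                & (along <= cell.arm_length_um)
                & (perp2 <= (cell.arm_width_um / 2) ** 2)
            )
            inside |= arm
    sl = tuple(slice(lo_idx[d], hi_idx[d]) for d in range(3))
    membrane[sl][inside] = np.maximum(membrane[sl][inside], cell.intensity)

    nc = cell.nucleus_center_um
    nuc_axes = [
        (np.arange(lo_idx[d], hi_idx[d]) + 0.5) * pitch - nc[d] for d in range(3)
    ]
    zz, yy, xx = np.meshgrid(*nuc_axes, indexing="ij")
    in_nuc = zz**2 + yy**2 + xx**2 <= cell.nucleus_radius_um**2
    nucleus[sl][in_nuc] = np.maximum(nucleus[sl][in_nuc], cell.intensity)


def generate_morphology_stack(
    spec: MorphStackSpec,
) -> tuple[VolumetricImage, list[CellTruth]]:
    """Render a two-channel (membrane, nucleus) stack plus its ground truth.

    Each truth entry carries the exact analytic volume, axis ranges and
    centroid of its body in μm; the returned image has the spec's blur and
    additive Gaussian noise applied. Identical spec + seed yields
    bit-identical arrays.
    """
    rng = np.random.default_rng(spec.seed)
    membrane = np.zeros(spec.grid_shape, dtype=np.float64)
    nucleus = np.zeros(spec.grid_shape, dtype=np.float64)
    for cell in spec.cells:
        _render_body(membrane, nucleus, cell, spec.voxel_pitch_um, spec.shell_thickness_um)
    data = np.stack([membrane, nucleus]) + spec.background_level
    if spec.blur_sigma_um > 0:
        sigma_vox = spec.blur_sigma_um / spec.voxel_pitch_um
        for ch in range(2):
            data[ch] = ndi.gaussian_filter(data[ch], sigma_vox)
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)
    img = VolumetricImage(
        data=data,
        voxel_pitch_um=(spec.voxel_pitch_um,) * 3,
        channel_names=("membrane", "nucleus"),
    )
    return img, list(spec.cells)


# ---------------------------------------------------------------------------
# Calcium transients
# ---------------------------------------------------------------------------

def transient_waveform(
    t_s: np.ndarray,
    onset_s: float,
    amplitude_dff: float,
    rise_tau_s: float,
    decay_tau_s: float,
) -> np.ndarray:
    """ΔF/F transient: 0 before onset, ``A(1−e^{−Δ/τ_r})e^{−Δ/τ_d}`` after."""
    dt = np.asarray(t_s, dtype=float) - onset_s
    out = np.zeros_like(dt)
    pos = dt >= 0
    out[pos] = (
        amplitude_dff
        * (1.0 - np.exp(-dt[pos] / rise_tau_s))
        * np.exp(-dt[pos] / decay_tau_s)
    )
    return out


def waveform_peak(amplitude_dff: float, rise_tau_s: float, decay_tau_s: float) -> float:
    """Closed-form peak of the transient waveform.

    The maximum of ``(1−e^{−Δ/τ_r})e^{−Δ/τ_d}`` sits at
    ``Δ* = τ_r·ln(1 + τ_d/τ_r)``.
    """
    dt_star = rise_tau_s * math.log(1.0 + decay_tau_s / rise_tau_s)
    return float(
        amplitude_dff
        * (1.0 - math.exp(-dt_star / rise_tau_s))
        * math.exp(-dt_star / decay_tau_s)
    )


@dataclass
class EventTruth:
    """One ground-truth calcium transient assigned to a cell."""

    cell_index: int
    onset_s: float
    amplitude_dff: float
    rise_tau_s: float
    decay_tau_s: float

    def __post_init__(self) -> None:
        if self.amplitude_dff <= 0:
            raise SpecError("amplitude_dff must be positive")
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0:
            raise SpecError("time constants must be positive")

    @property
    def peak_dff(self) -> float:
        return waveform_peak(self.amplitude_dff, self.rise_tau_s, self.decay_tau_s)


@dataclass
class CalciumCellSpec:
    """One cell footprint in a synthetic movie: disk at ``center_px`` (x, y)."""

    center_px: tuple[float, float]
    radius_px: float = 6.0
    baseline_F: float = 100.0


@dataclass
class CalciumMovieSpec:
    """Recipe for a synthetic calcium time lapse.

    Defaults mirror the target acquisition (10 Hz over 5 min); the frame is a
    spatially reduced field (256 px at 5.2 μm/px spans the same ≈1.33 mm as
    the native 2048 px at 0.65 μm/px) since trace analysis is insensitive to
    the pixel grid once ROIs are placed.
    """

    frame_rate_hz: float = 10.0
    duration_s: float = 300.0
    frame_shape: tuple[int, int] = (256, 256)
    pixel_pitch_um: float = 5.2
    cells: Sequence[CalciumCellSpec] = field(default_factory=list)
    events: Sequence[EventTruth] = field(default_factory=list)
    bleach_tau_s: float | None = None
    noise_sd: float = 1.0
    background_F: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise SpecError("frame_rate_hz must be positive")
        if self.duration_s <= 0:
            raise SpecError("duration_s must be positive")
        if self.background_F <= 0:
            raise SpecError("background_F must be positive")
        for c in self.cells:
            if c.baseline_F <= self.background_F:
                raise SpecError("baseline_F must exceed background_F")
        for e in self.events:
            if not 0 <= e.cell_index < len(self.cells):
                raise SpecError(f"event references absent cell {e.cell_index}")
            if e.onset_s >= self.duration_s:
                raise SpecError("event onset beyond recording duration")


def generate_trace(
    events: Sequence[EventTruth],
    frame_rate_hz: float = 10.0,
    duration_s: float = 300.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, list[EventTruth]]:
    """Pure ΔF/F series from the transient waveform plus Gaussian noise.

    Fast unit-test path that bypasses imagery: the returned series is exactly
    the sum of the events' waveforms sampled at ``frame_rate_hz``.
    """
    for e in events:
        if e.onset_s >= duration_s:
            raise SpecError("event onset beyond duration")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = round(frame_rate_hz * duration_s)
    t = np.arange(n) / frame_rate_hz
    dff = np.zeros(n)
    for e in events:
        dff += transient_waveform(t, e.onset_s, e.amplitude_dff, e.rise_tau_s, e.decay_tau_s)
    if noise_sd > 0:
        dff = dff + rng.normal(0.0, noise_sd, size=n)
    return dff, list(events)


def random_events(
    n_cells: int,
    rng: np.random.Generator,
    events_per_cell: tuple[int, int] = (1, 2),
    amplitude_choices: Sequence[float] = (0.3, 0.5, 1.0),
    rise_tau_range_s: tuple[float, float] = (1.0, 1.3),
    decay_tau_range_s: tuple[float, float] = (3.0, 4.5),
    duration_s: float = 300.0,
    min_separation_s: float = 150.0,
    active_fraction: float = 1.0,
) -> list[EventTruth]:
    """Draw well-separated ground-truth events for ``n_cells`` cells.

    Defaults model rare spontaneous large-scale transients: one or two per
    cell per 5-min recording, ≥ 150 s apart, with a fast rise (τ_r ≈ 1 s) and
    a slower exponential decay (τ_d ≈ 3–4.5 s, i.e. boundary-to-boundary
    event durations of tens of seconds). In this regime the transient's
    spectrum sits inside the 0.01–1 Hz analysis band: a high-pass at f_c
    removes roughly 2·f_c·(event mass) from under the peak, so short decays
    and wide separations keep the filtering amplitude loss within the 20%
    budget the generators guarantee, and even the smallest default amplitude
    (0.3) clears the 0.1 detection threshold. Onsets also keep ~40 s clear of
    the recording end so no transient is truncated by the filter window edge.
    """
    events: list[EventTruth] = []
    lo, hi = events_per_cell
    for c in range(n_cells):
        if rng.uniform() > active_fraction:
            continue
        k = int(rng.integers(lo, hi + 1))
        max_onset = duration_s - 9 * decay_tau_range_s[1]
        onsets: list[float] = []
        tries = 0
        while len(onsets) < k and tries < 200:
            tries += 1
            cand = float(rng.uniform(5.0, max_onset))
            if all(abs(cand - o) >= min_separation_s for o in onsets):
                onsets.append(cand)
        for onset in sorted(onsets):
            events.append(
                EventTruth(
                    cell_index=c,
                    onset_s=onset,
                    amplitude_dff=float(rng.choice(amplitude_choices)),
                    rise_tau_s=float(rng.uniform(*rise_tau_range_s)),
                    decay_tau_s=float(rng.uniform(*decay_tau_range_s)),
                )
            )
    return events


def generate_calcium_movie(
    spec: CalciumMovieSpec,
) -> tuple[CalciumMovie, list[EventTruth], pd.DataFrame]:
    """Render a synthetic calcium movie, its event truth and ROI-centre table.

    Pixels inside cell *c*:  ``baseline_F_c · (1 + Σ events of c) · bleach(t)``;
    background pixels: ``background_F · bleach(t)``; Gaussian noise on top.
    The centres table has columns ``roi_id, x_px, y_px`` as consumed by the
    trace-extraction stage.
    """
    rng = np.random.default_rng(spec.seed)
    n = round(spec.frame_rate_hz * spec.duration_s)
    t = np.arange(n) / spec.frame_rate_hz
    bleach = (
        np.exp(-t / spec.bleach_tau_s) if spec.bleach_tau_s else np.ones_like(t)
    )
    h, w = spec.frame_shape
    frames = np.empty((n, h, w), dtype=np.float64)
    frames[:] = (spec.background_F * bleach)[:, None, None]

    yy, xx = np.mgrid[0:h, 0:w]
    for ci, cell in enumerate(spec.cells):
        cx, cy = cell.center_px
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= cell.radius_px**2
        signal = np.zeros(n)
        for e in spec.events:
            if e.cell_index == ci:
                signal += transient_waveform(
                    t, e.onset_s, e.amplitude_dff, e.rise_tau_s, e.decay_tau_s
                )
        cell_ts = cell.baseline_F * (1.0 + signal) * bleach
        frames[:, disk] = cell_ts[:, None]
    if spec.noise_sd > 0:
        frames += rng.normal(0.0, spec.noise_sd, size=frames.shape)

    centers = pd.DataFrame(
        {
            "roi_id": np.arange(len(spec.cells)),
            "x_px": [c.center_px[0] for c in spec.cells],
            "y_px": [c.center_px[1] for c in spec.cells],
        }
    )
    movie = CalciumMovie(
        frames=frames,
        frame_rate_hz=spec.frame_rate_hz,
        pixel_pitch_um=spec.pixel_pitch_um,
    )
    return movie, list(spec.events), centers


# ---------------------------------------------------------------------------
# Live/dead viability fields
# ---------------------------------------------------------------------------

@dataclass
class ViabilityFieldSpec:
    """Recipe for a three-channel (nuclei / live / dead) field."""

    n_total: int
    n_dead: int
    frame_shape: tuple[int, int] = (512, 512)
    spot_radius_px: float = 6.0
    min_separation_px: float = 30.0
    spot_intensity: float = 200.0
    noise_sd: float = 0.0
    blur_sigma_px: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_total < 0 or self.n_dead < 0:
            raise SpecError("counts must be non-negative")
        if self.n_dead > self.n_total:
            raise SpecError("n_dead cannot exceed n_total")


def generate_viability_field(
    spec: ViabilityFieldSpec,
) -> tuple[MultichannelImage, dict]:
    """Render nuclei / live / dead channels with known counts.

    All ``n_total`` nuclei appear in the nucleus channel; a random subset of
    ``n_dead`` of them is marked in the dead channel, the rest get a wider
    cytoplasmic disk in the live channel. Returns the image and a truth dict
    with ``total``, ``dead``, ``live`` and the spot centres.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.frame_shape
    margin = spec.spot_radius_px * 3 + 2
    centers: list[tuple[float, float]] = []
    tries = 0
    max_tries = max(1000, 1000 * spec.n_total)
    while len(centers) < spec.n_total:
        if tries >= max_tries:
            raise PlacementError(
                f"placed {len(centers)}/{spec.n_total} spots after {max_tries} tries"
            )
        tries += 1
        cand = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        if all(
            (cand[0] - c[0]) ** 2 + (cand[1] - c[1]) ** 2 >= spec.min_separation_px**2
            for c in centers
        ):
            centers.append(cand)

    dead_idx = set(
        rng.choice(spec.n_total, size=spec.n_dead, replace=False).tolist()
        if spec.n_dead
        else []
    )
    nuclei = np.zeros((h, w))
    live = np.zeros((h, w))
    dead = np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    for i, (cy, cx) in enumerate(centers):
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        nuclei[r2 <= spec.spot_radius_px**2] = spec.spot_intensity
        if i in dead_idx:
            dead[r2 <= spec.spot_radius_px**2] = spec.spot_intensity
        else:
            live[r2 <= (2 * spec.spot_radius_px) ** 2] = spec.spot_intensity
    data = np.stack([nuclei, live, dead])
    if spec.blur_sigma_px > 0:
        for ch in range(3):
            data[ch] = ndi.gaussian_filter(data[ch], spec.blur_sigma_px)
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)
    img = MultichannelImage(data=data, channel_names=("nuclei", "live", "dead"))
    truth = {
        "total": spec.n_total,
        "dead": spec.n_dead,
        "live": spec.n_total - spec.n_dead,
        "centers_px": centers,
        "dead_indices": sorted(dead_idx),
    }
    return img, truth
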