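"""Calcium time-lapse processing: masks, traces, ΔF/F₀, filtering, events.

The chain follows a somatic calcium-imaging workflow on cultured astrocytes:

1. a binary cell mask from the movie's maximum-intensity projection via Otsu
   thresholding, refined by binary dilation, hole filling and small-component
   removal;
2. per-ROI fluorescence from a 5-pixel-radius disk around each annotated cell
   centre, with background from pixels outside the mask;
3. ΔF/F₀ = (F_t − F₀)/F₀ with F₀ the mean background at each time point
   (a cell-over-background contrast; a conventional per-ROI baseline mode is
   available but off by default);
4. a 6th-order Butterworth low-pass (1 Hz) followed by a 2nd-order high-pass
   (0.01 Hz), zero-phase by default;
5. event detection on the filtered trace: threshold crossings at 0.1 ΔF/F,
   extended to the flanking zero crossings and refined to local minima;
6. kinetics (amplitude, AUC, duration, rise, decay) and per-condition
   activity summaries.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import signal
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk

from .errors import (
    ConfigError,
    DegenerateEventError,
    DegenerateInputError,
    InvalidBackgroundError,
    NoBackgroundError,
)
from .images import CalciumMovie

logger = logging.getLogger(__name__)

__all__ = [
    "CalciumConfig",
    "CellMask",
    "RoiTrace",
    "CalciumEvent",
    "ActivitySummary",
    "build_mask",
    "extract_trace",
    "compute_dff",
    "filter_trace",
    "filter_frequency_response",
    "detect_events",
    "compute_kinetics",
    "summarize_activity",
    "downsample_movie",
    "analyze_movie",
    "events_to_dataframe",
]


@dataclass
class CalciumConfig:
    roi_radius_px: float = 5.0
    lp_order: int = 6
    lp_cutoff_hz: float = 1.0
    hp_order: int = 2
    hp_cutoff_hz: float = 0.01
    event_threshold_dff: float = 0.1
    min_component_px: int = 50
    dilation_radius_px: int = 2
    downsample_factor: int = 1  # spatial; centres are rescaled to match
    zero_phase: bool = True
    baseline_mode: str = "background"  # or "roi" (per-ROI F0 = mean of own F)

    def __post_init__(self) -> None:
        if self.event_threshold_dff <= 0:
            raise ConfigError("event_threshold_dff must be positive")
        if self.lp_cutoff_hz <= 0 or self.hp_cutoff_hz <= 0:
            raise ConfigError("cutoffs must be positive")
        if self.baseline_mode not in ("background", "roi"):
            raise ConfigError(f"unknown baseline_mode {self.baseline_mode!r}")


@dataclass
class CellMask:
    mask: np.ndarray  # bool (H, W)
    labels: np.ndarray  # int (H, W), 0 = background
    areas: dict[int, int]

    @property
    def n_components(self) -> int:
        return len(self.areas)


@dataclass
class RoiTrace:
    """Per-ROI series: raw F, background B, ΔF/F₀ and its filtered version."""

    roi_id: int
    center_px: tuple[float, float]  # (x, y)
    radius_px: float
    F: np.ndarray
    B: np.ndarray
    dff: np.ndarray | None = None
    filtered: np.ndarray | None = None


@dataclass
class CalciumEvent:
    roi_id: int
    onset_idx: int
    peak_idx: int
    offset_idx: int
    amplitude: float = float("nan")
    auc: float = float("nan")
    duration_s: float = float("nan")
    rise_s: float = float("nan")
    decay_s: float = float("nan")


@dataclass
class ActivitySummary:
    n_rois: int
    n_active: int
    proportion_active: float
    events_per_active_cell: dict[int, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Mask and traces
# ---------------------------------------------------------------------------

def build_mask(movie: CalciumMovie, cfg: CalciumConfig | None = None) -> CellMask:
    """Binary cell mask from the maximum-intensity projection.

    Otsu threshold on the projection, then disk dilation, hole filling and
    removal of components smaller than ``min_component_px``.
    """
    cfg = cfg or CalciumConfig()
    proj = movie.frames.max(axis=0)
    if proj.max() == proj.min():
        raise DegenerateInputError("maximum projection is single-valued")
    binary = proj > threshold_otsu(proj)
    if cfg.dilation_radius_px > 0:
        binary = ndi.binary_dilation(binary, structure=disk(cfg.dilation_radius_px))
    binary = ndi.binary_fill_holes(binary)
    labels = cc_label(binary)
    areas = {}
    for lab in range(1, labels.max() + 1):
        area = int(np.sum(labels == lab))
        if area < cfg.min_component_px:
            binary[labels == lab] = False
        else:
            areas[lab] = area
    labels = cc_label(binary)
    areas = {lab: int(np.sum(labels == lab)) for lab in range(1, labels.max() + 1)}
    return CellMask(mask=binary, labels=labels, areas=areas)


def roi_disk_offsets(radius_px: float) -> np.ndarray:
    """Integer (dy, dx) lattice offsets with dy² + dx² ≤ radius²."""
    r = int(np.floor(radius_px))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy**2 + dx**2 <= radius_px**2
    return np.stack([dy[keep], dx[keep]], axis=1)


def extract_trace(
    movie: CalciumMovie,
    center_px: tuple[float, float],
    mask: CellMask,
    cfg: CalciumConfig | None = None,
    roi_id: int = 0,
) -> RoiTrace:
    """Mean fluorescence in a circular ROI plus mean background per frame.

    ``center_px`` is (x, y). The ROI is the set of lattice pixels within
    ``roi_radius_px`` of the centre (81 pixels at the default radius 5);
    disks partially outside the frame are clipped with a warning. Background
    is the mean over pixels outside the mask.
    """
    cfg = cfg or CalciumConfig()
    h, w = movie.frames.shape[1:]
    cx, cy = center_px
    if not (0 <= cx < w and 0 <= cy < h):
        raise ConfigError(f"ROI centre {center_px} outside frame {(w, h)}")
    offsets = roi_disk_offsets(cfg.roi_radius_px)
    ys = np.rint(cy).astype(int) + offsets[:, 0]
    xs = np.rint(cx).astype(int) + offsets[:, 1]
    inside = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
    if not inside.all():
        warnings.warn(
            f"ROI {roi_id} at {center_px} clipped to {int(inside.sum())} in-frame pixels",
            stacklevel=2,
        )
        ys, xs = ys[inside], xs[inside]
    F = movie.frames[:, ys, xs].mean(axis=1)
    outside = ~mask.mask
    if not outside.any():
        raise NoBackgroundError("mask covers the entire frame")
    B = movie.frames[:, outside].mean(axis=1)
    return RoiTrace(roi_id=roi_id, center_px=(float(cx), float(cy)),
                    radius_px=cfg.roi_radius_px, F=F, B=B)


def compute_dff(trace: RoiTrace, cfg: CalciumConfig | None = None) -> np.ndarray:
    """ΔF/F₀ per frame.

    Default ``background`` mode: (F_t − B_t)/B_t with the time-varying mean
    background as F₀. ``roi`` mode uses the ROI's own temporal mean instead.
    """
    cfg = cfg or CalciumConfig()
    if cfg.baseline_mode == "background":
        f0 = trace.B
        if np.any(f0 <= 0):
            raise InvalidBackgroundError("background fluorescence must be positive")
    else:
        f0 = np.full_like(trace.F, trace.F.mean())
        if np.any(f0 <= 0):
            raise InvalidBackgroundError("ROI baseline must be positive")
    trace.dff = (trace.F - f0) / f0
    return trace.dff


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _design_sos(cfg: CalciumConfig, frame_rate_hz: float):
    nyq = frame_rate_hz / 2.0
    if cfg.lp_cutoff_hz >= nyq or cfg.hp_cutoff_hz >= nyq:
        raise ConfigError("filter cutoff at or above Nyquist frequency")
    lp = signal.butter(cfg.lp_order, cfg.lp_cutoff_hz, "lowpass", fs=frame_rate_hz, output="sos")
    hp = signal.butter(cfg.hp_order, cfg.hp_cutoff_hz, "highpass", fs=frame_rate_hz, output="sos")
    return lp, hp


def filter_trace(
    dff: np.ndarray, frame_rate_hz: float, cfg: CalciumConfig | None = None
) -> np.ndarray:
    """Band-filter a ΔF/F trace: Butterworth low-pass then high-pass.

    Zero-phase (forward–backward) application by default so event kinetics
    are not phase-shifted; set ``zero_phase=False`` for single-pass causal
    filtering.
    """
    cfg = cfg or CalciumConfig()
    lp, hp = _design_sos(cfg, frame_rate_hz)
    x = np.asarray(dff, dtype=float)
    if cfg.zero_phase:
        y = signal.sosfiltfilt(lp, x)
        y = signal.sosfiltfilt(hp, y)
    else:
        y = signal.sosfilt(lp, x)
        y = signal.sosfilt(hp, y)
    return y


def filter_frequency_response(
    cfg: CalciumConfig, frame_rate_hz: float, freqs_hz: Sequence[float]
) -> dict[str, np.ndarray]:
    """Single-pass magnitude response of each designed stage at ``freqs_hz``."""
    lp, hp = _design_sos(cfg, frame_rate_hz)
    w = np.asarray(freqs_hz, dtype=float)
    _, h_lp = signal.sosfreqz(lp, worN=2 * np.pi * w / frame_rate_hz)
    _, h_hp = signal.sosfreqz(hp, worN=2 * np.pi * w / frame_rate_hz)
    return {"lowpass": np.abs(h_lp), "highpass": np.abs(h_hp)}


# ---------------------------------------------------------------------------
# Event detection and kinetics
# ---------------------------------------------------------------------------

def _runs_above(x: np.ndarray, thr: float) -> list[tuple[int, int]]:
    above = x > thr
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]]
    return list(zip(starts.tolist(), ends.tolist()))


def detect_events(
    filtered: np.ndarray,
    cfg: CalciumConfig | None = None,
    roi_id: int = 0,
) -> list[CalciumEvent]:
    """Detect transients on a filtered ΔF/F trace.

    Candidates are maximal runs above ``event_threshold_dff``. Each run is
    extended outward to the nearest zero crossings, then each boundary is
    refined inward to the local minimum of that flank (the argmin of the
    zero-crossing-to-threshold span; ties break toward the earlier frame).
    Overlapping candidates are merged; events come back in temporal order,
    disjoint, with onset ≤ peak ≤ offset.
    """
    cfg = cfg or CalciumConfig()
    x = np.asarray(filtered, dtype=float)
    n = x.size
    spans: list[tuple[int, int]] = []
    for s, e in _runs_above(x, cfg.event_threshold_dff):
        i = s
        while i > 0 and x[i - 1] > 0:
            i -= 1
        j = e
        while j < n - 1 and x[j + 1] > 0:
            j += 1
        onset = i + int(np.argmin(x[i : s + 1]))
        offset = e + int(np.argmin(x[e : j + 1]))
        spans.append((onset, offset))
    merged: list[list[int]] = []
    for onset, offset in sorted(spans):
        if merged and onset <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], offset)
        else:
            merged.append([onset, offset])
    events = []
    for onset, offset in merged:
        peak = onset + int(np.argmax(x[onset : offset + 1]))
        events.append(
            CalciumEvent(
                roi_id=roi_id,
                onset_idx=int(onset),
                peak_idx=int(peak),
                offset_idx=int(offset),
                amplitude=float(x[peak]),
            )
        )
    return events


def compute_kinetics(
    event: CalciumEvent,
    filtered: np.ndarray,
    frame_rate_hz: float,
) -> CalciumEvent:
    """Fill amplitude, AUC, duration, rise and decay for one event.

    Amplitude is the maximum filtered value over [onset, offset]; AUC is the
    trapezoidal integral of the filtered trace over the same span in
    ΔF/F·s; rise = onset→peak, decay = peak→offset, duration = onset→offset
    (so duration = rise + decay by construction under these definitions).
    """
    if event.onset_idx == event.offset_idx:
        raise DegenerateEventError("event with onset == offset has no kinetics")
    x = np.asarray(filtered, dtype=float)
    seg = x[event.onset_idx : event.offset_idx + 1]
    dt = 1.0 / frame_rate_hz
    return replace(
        event,
        amplitude=float(seg.max()),
        auc=float(np.trapezoid(seg, dx=dt)),
        duration_s=(event.offset_idx - event.onset_idx) * dt,
        rise_s=(event.peak_idx - event.onset_idx) * dt,
        decay_s=(event.offset_idx - event.peak_idx) * dt,
    )


def summarize_activity(
    events_by_roi: dict[int, Sequence[CalciumEvent]], n_rois: int
) -> ActivitySummary:
    """Proportion of active ROIs (≥ 1 event) and the per-active-cell count distribution."""
    if n_rois < 1:
        raise ConfigError("n_rois must be >= 1")
    counts = [len(evts) for evts in events_by_roi.values() if len(evts) > 0]
    dist = dict(sorted(Counter(counts).items()))
    return ActivitySummary(
        n_rois=n_rois,
        n_active=len(counts),
        proportion_active=len(counts) / n_rois,
        events_per_active_cell=dist,
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def downsample_movie(movie: CalciumMovie, factor: int) -> CalciumMovie:
    """Spatial block-mean downsampling (time is untouched)."""
    if factor == 1:
        return movie
    t, h, w = movie.frames.shape
    h2, w2 = h // factor, w // factor
    cropped = movie.frames[:, : h2 * factor, : w2 * factor]
    frames = cropped.reshape(t, h2, factor, w2, factor).mean(axis=(2, 4))
    return CalciumMovie(
        frames=frames,
        frame_rate_hz=movie.frame_rate_hz,
        pixel_pitch_um=movie.pixel_pitch_um * factor,
    )


def analyze_movie(
    movie: CalciumMovie,
    centers: pd.DataFrame,
    cfg: CalciumConfig | None = None,
) -> tuple[list[RoiTrace], list[CalciumEvent], ActivitySummary]:
    """Full chain from movie + annotated centres to events and activity summary.

    ``centers`` needs columns ``roi_id, x_px, y_px`` (original-resolution
    pixels; they are rescaled if the movie is spatially downsampled here).
    """
    cfg = cfg or CalciumConfig()
    if cfg.downsample_factor > 1:
        movie = downsample_movie(movie, cfg.downsample_factor)
    mask = build_mask(movie, cfg)
    traces: list[RoiTrace] = []
    all_events: list[CalciumEvent] = []
    events_by_roi: dict[int, list[CalciumEvent]] = {}
    for row in centers.itertuples(index=False):
        roi_id = int(row.roi_id)
        cx = float(row.x_px) / cfg.downsample_factor
        cy = float(row.y_px) / cfg.downsample_factor
        trace = extract_trace(movie, (cx, cy), mask, cfg, roi_id=roi_id)
        compute_dff(trace, cfg)
        trace.filtered = filter_trace(trace.dff, movie.frame_rate_hz, cfg)
        events = [
            compute_kinetics(e, trace.filtered, movie.frame_rate_hz)
            for e in detect_events(trace.filtered, cfg, roi_id=roi_id)
        ]
        traces.append(trace)
        events_by_roi[roi_id] = events
        all_events.extend(events)
    summary = summarize_activity(events_by_roi, n_rois=len(traces))
    return traces, all_events, summary


def events_to_dataframe(events: Sequence[CalciumEvent]) -> pd.DataFrame:
    columns = ["roi_id", "onset_idx", "peak_idx", "offset_idx",
               "amplitude", "auc", "duration_s", "rise_s", "decay_s"]
    return pd.DataFrame([vars(e) for e in events], columns=columns)
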