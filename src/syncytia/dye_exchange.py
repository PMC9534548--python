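"""Steady-state dye mixing: coupling coefficients and cytometry gating.

Two cell populations are loaded with distinct cytoplasm-retained
CellTracker dyes and co-cultured.  Because the dyes cannot recross an
intact plasma membrane, any cell carrying both dyes must have received
one of them through gap junctions.  Mixing is quantified two ways:

* imaging — per-pixel coupling coefficient ``CC = 2 * min(F_O, F_V) /
  (F_O + F_V)`` on channel signals normalized to paired mono-culture
  controls; CC is 0 for a pure single-dye pixel and 1 for a perfectly
  mixed one;
* flow cytometry — events above the off-channel thresholds defined by a
  high percentile (default 95th) of the mono-culture populations are
  counted as dual-positive, giving an exchanged fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "DualChannelImage",
    "CouplingMap",
    "EventTable",
    "normalize_channels",
    "coupling_coefficient",
    "coupling_map",
    "coupling_distribution",
    "gate_thresholds",
    "exchanged_fraction",
]

EVENT_SOURCES = ("mono_A", "mono_B", "co_culture", "acute_mix")


@dataclass
class DualChannelImage:
    """Registered two-dye image pair with mono-culture normalization means.

    ``channel_O`` / ``channel_V`` are the Orange- and Violet-dye
    intensity arrays; ``mono_control_means`` are the mean signals of the
    paired single-dye control images used for normalization.
    """

    channel_O: np.ndarray
    channel_V: np.ndarray
    pixel_size: float = 1.0
    mono_control_means: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.channel_O = np.asarray(self.channel_O, dtype=float)
        self.channel_V = np.asarray(self.channel_V, dtype=float)
        if self.channel_O.shape != self.channel_V.shape:
            raise ValueError("channels must share a shape")
        if np.any(self.channel_O < 0) or np.any(self.channel_V < 0):
            raise ValueError("intensities must be >= 0")
        if not all(m > 0 for m in self.mono_control_means):
            raise ValueError("mono control means must be > 0")


@dataclass
class CouplingMap:
    """Per-pixel coupling coefficients; excluded pixels are NaN."""

    cc: np.ndarray

    def __post_init__(self) -> None:
        vals = self.present()
        if vals.size and (vals.min() < 0 or vals.max() > 1 + 1e-12):
            raise ValueError("coupling coefficients must lie in [0, 1]")

    def present(self) -> np.ndarray:
        return self.cc[np.isfinite(self.cc)]


@dataclass
class EventTable:
    """Flow-cytometry events: one row per cell, two detection channels."""

    events: pd.DataFrame
    source: str = "co_culture"

    def __post_init__(self) -> None:
        if self.source not in EVENT_SOURCES:
            raise ValueError(f"source must be one of {EVENT_SOURCES}")
        missing = {"channel_A", "channel_B"} - set(self.events.columns)
        if missing:
            raise ValueError(f"event table missing columns {sorted(missing)}")
        if len(self.events) and (
            (self.events["channel_A"] <= 0).any() or (self.events["channel_B"] <= 0).any()
        ):
            raise ValueError("intensities must be > 0 (log-displayable)")

    def __len__(self) -> int:
        return len(self.events)


def normalize_channels(img: DualChannelImage) -> tuple[np.ndarray, np.ndarray]:
    """Divide each channel by the mean of its paired mono-culture control."""
    m_o, m_v = img.mono_control_means
    if m_o <= 0 or m_v <= 0:
        raise ValueError("control means must be > 0")
    return img.channel_O / m_o, img.channel_V / m_v


def coupling_coefficient(f_o, f_v):
    """CC = 2 * min(F_O/(F_O+F_V), F_V/(F_O+F_V)), elementwise.

    Symmetric in its arguments, 0 when one channel is dark, 1 when the
    normalized channels are equal.  Pixels with zero total signal yield
    NaN; callers should exclude them via a background rule (see
    :func:`coupling_map`).
    """
    f_o = np.asarray(f_o, dtype=float)
    f_v = np.asarray(f_v, dtype=float)
    total = f_o + f_v
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = 2.0 * np.minimum(f_o, f_v) / total
    return cc if cc.ndim else float(cc)


def coupling_map(
    img: DualChannelImage,
    *,
    background_sd: float | None = None,
    background_factor: float = 3.0,
) -> CouplingMap:
    """Normalized per-pixel CC with background exclusion.

    A pixel enters the map only when its summed normalized signal
    exceeds ``background_factor`` times the background SD (estimated
    from the darkest image corner when not supplied).  Excluded pixels
    are NaN, never zero-filled — a dark pixel carries no mixing
    information.
    """
    f_o, f_v = normalize_channels(img)
    total = f_o + f_v
    if background_sd is None:
        background_sd = _corner_background_sd(total)
    cc = coupling_coefficient(f_o, f_v)
    cc = np.where(total > background_factor * background_sd, cc, np.nan)
    cc = np.where(np.isfinite(cc), np.clip(cc, 0.0, 1.0), np.nan)
    return CouplingMap(cc=cc)


def _corner_background_sd(total: np.ndarray, frac: float = 0.05) -> float:
    """SD of the darkest corner patch (background estimate)."""
    h, w = total.shape[-2], total.shape[-1]
    k = max(4, int(frac * min(h, w)))
    corners = [
        total[:k, :k],
        total[:k, -k:],
        total[-k:, :k],
        total[-k:, -k:],
    ]
    darkest = min(corners, key=lambda c: float(np.mean(c)))
    sd = float(np.std(darkest))
    return sd if sd > 0 else 1e-12


class CouplingDistribution(NamedTuple):
    bin_edges: np.ndarray
    counts: np.ndarray
    fraction_above: float
    threshold: float
    unit: str  # "pixel" or "cell"
    values: np.ndarray


def coupling_distribution(
    cmap: CouplingMap,
    *,
    labels: np.ndarray | None = None,
    n_bins: int = 20,
    threshold: float = 0.5,
) -> CouplingDistribution:
    """Frequency distribution of CC and the fraction above a threshold.

    With a label image (cell segmentation), the unit is the cell and its
    CC is the median over that cell's included pixels; otherwise the
    unit is the pixel.
    """
    if labels is not None:
        labels = np.asarray(labels)
        vals = []
        for lab in np.unique(labels):
            if lab == 0:
                continue
            v = cmap.cc[labels == lab]
            v = v[np.isfinite(v)]
            if v.size:
                vals.append(float(np.median(v)))
        values = np.array(vals)
        unit = "cell"
    else:
        values = cmap.present()
        unit = "pixel"
    if values.size == 0:
        raise ValueError("empty coupling map (no included units)")
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    frac = float(np.mean(values > threshold))
    return CouplingDistribution(edges, counts, frac, threshold, unit, values)


class GateThresholds(NamedTuple):
    """Off-channel gating levels from single-dye mono-cultures."""

    threshold_A: float  # on channel_A, from mono_B events
    threshold_B: float  # on channel_B, from mono_A events
    percentile: float


def gate_thresholds(
    mono_A: EventTable, mono_B: EventTable, percentile: float = 95.0
) -> GateThresholds:
    """Per-channel dual-positive thresholds from mono-culture controls.

    The threshold on channel B is the given percentile of the channel-B
    signal of the A-only population (its off-channel background), and
    vice versa: a level that single-positive cells rarely exceed.
    """
    if not (50 < percentile <= 100):
        raise ValueError("percentile must lie in (50, 100]")
    if len(mono_A) == 0 or len(mono_B) == 0:
        raise ValueError("mono-culture tables must be nonempty")
    thr_b = float(np.percentile(mono_A.events["channel_B"], percentile))
    thr_a = float(np.percentile(mono_B.events["channel_A"], percentile))
    return GateThresholds(threshold_A=thr_a, threshold_B=thr_b, percentile=percentile)


def exchanged_fraction(
    co: EventTable,
    thresholds: GateThresholds,
    *,
    fp_correction: bool = True,
) -> float:
    """Fraction of events that exchanged dye (dual-positive gating).

    An event is dual-positive when it exceeds both off-channel
    thresholds.  By construction of percentile gating, a fraction
    ``alpha = 1 - percentile/100`` of genuinely single-positive events
    still falls above their off-channel threshold; with
    ``fp_correction`` (default) this known rate is inverted,

        f = (p_dual - alpha) / (1 - alpha),  clipped to [0, 1],

    so the estimator is unbiased for the true exchanged fraction while
    an acute-mix null still reads (approximately) zero.  Set
    ``fp_correction=False`` for the raw dual-positive fraction.
    """
    if len(co) == 0:
        raise ValueError("empty event table")
    dual = (co.events["channel_A"] > thresholds.threshold_A) & (
        co.events["channel_B"] > thresholds.threshold_B
    )
    p_dual = float(dual.mean())
    if not fp_correction:
        return p_dual
    alpha = 1.0 - thresholds.percentile / 100.0
    if alpha >= 1.0:
        return p_dual
    return float(np.clip((p_dual - alpha) / (1.0 - alpha), 0.0, 1.0))
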