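"""Feature extraction from bioelectrochemical measurements.

Covers the quantities typically reported from a mediated-electron-transfer
bioreactor experiment:

* chronoamperometry — windowed steady-state current densities and the
  percent/fold changes across media-swap events;
* differential pulse voltammetry (DPV) — peak potential, baseline-
  subtracted height and width at half height (W_1/2), plus the apparent
  electron count from the small-amplitude Nernstian width criterion
  W_1/2 = 3.526·RT/nF (≈ 90.6/n mV at 25 °C);
* cyclic voltammetry (CV) — catalytic-wave onset (3σ threshold crossing
  on the positive-going sweep) and the midpoint potential of a reversible
  couple (mean of anodic and cathodic peak potentials).

Currents are carried as densities (µA cm⁻²), normalized by geometric
electrode area at ingestion.  Potentials are V vs Ag/AgCl.

The Nernstian-width electron count is an interpretive layer: the width
criterion assumes a reversible couple probed with small pulse amplitude
at uniform temperature (configurable, default 298.15 K).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "NoPeakError",
    "AmperometryTrace",
    "Voltammogram",
    "PeakFeature",
    "SteadyState",
    "RelativeChange",
    "ElectronCount",
    "CVFeatures",
    "steady_state_current",
    "relative_change",
    "dpv_peak_features",
    "apparent_electron_count",
    "cv_features",
    "NERNSTIAN_WIDTH_COEFF",
]

GAS_CONSTANT = 8.31446261815324  # J mol⁻¹ K⁻¹
FARADAY = 96485.33212  # C mol⁻¹
#: Small-amplitude Nernstian DPV width is COEFF × RT/F ÷ n.
NERNSTIAN_WIDTH_COEFF = 3.526

POTENTIAL_WINDOW = (-0.8, 0.6)  # V vs Ag/AgCl instrument window


class NoPeakError(ValueError):
    """No qualifying peak found in a voltammogram."""


@dataclass
class AmperometryTrace:
    """Chronoamperometry trace: current density vs time, with events.

    time : s, strictly increasing
    current_density : µA cm⁻² (already normalized by geometric area)
    events : (label, time) markers, e.g. media swaps or shuttle additions
    """

    time: np.ndarray
    current_density: np.ndarray
    events: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current_density = np.asarray(self.current_density, dtype=float)
        if self.time.shape != self.current_density.shape:
            raise ValueError("time and current arrays differ in length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.current_density)):
            raise ValueError("current values must be finite")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time_col: str = "time_s",
        current_col: str = "current_uA_cm2",
        events: list[tuple[str, float]] | None = None,
    ) -> "AmperometryTrace":
        return cls(
            time=df[time_col].to_numpy(dtype=float),
            current_density=df[current_col].to_numpy(dtype=float),
            events=events or [],
        )


@dataclass
class Voltammogram:
    """Potential-sweep measurement (CV or DPV) with scan metadata."""

    potential: np.ndarray  # V vs Ag/AgCl
    current: np.ndarray  # µA (or µA cm⁻² if normalized)
    mode: str  # "cv" | "dpv"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.potential = np.asarray(self.potential, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.potential.shape != self.current.shape:
            raise ValueError("potential and current arrays differ in length")
        if self.mode not in ("cv", "dpv"):
            raise ValueError(f"mode must be 'cv' or 'dpv', got {self.mode!r}")
        lo, hi = POTENTIAL_WINDOW
        if self.potential.min() < lo - 1e-9 or self.potential.max() > hi + 1e-9:
            raise ValueError(
                f"potentials outside the instrument window {POTENTIAL_WINDOW} V"
            )


@dataclass(frozen=True)
class PeakFeature:
    """A voltammetric peak: apex potential, height and W_1/2."""

    peak_potential: float  # V
    peak_height: float  # baseline-subtracted, current units
    w_half_mV: float

    def __post_init__(self) -> None:
        if self.w_half_mV <= 0:
            raise ValueError("W_1/2 must be > 0")
        if self.peak_height <= 0:
            raise ValueError("peak height must be > 0")


@dataclass(frozen=True)
class SteadyState:
    """Windowed steady-state current with a linear-drift diagnostic."""

    mean: float  # µA cm⁻²
    drift_slope: float  # µA cm⁻² per s over the window
    window: tuple[float, float]
    n_samples: int


def steady_state_current(
    trace: AmperometryTrace, window: tuple[float, float]
) -> SteadyState:
    """Mean current density over a time window, with drift slope.

    The window must lie inside the trace and contain at least 10 samples;
    the drift slope (least-squares linear trend) flags windows that have
    not actually reached steady state.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError(f"empty window {window}")
    if t0 < trace.time[0] or t1 > trace.time[-1]:
        raise ValueError(
            f"window {window} outside trace span "
            f"({trace.time[0]}, {trace.time[-1]})"
        )
    mask = (trace.time >= t0) & (trace.time <= t1)
    if mask.sum() < 10:
        raise ValueError(f"window contains {mask.sum()} samples; need >= 10")
    t, i = trace.time[mask], trace.current_density[mask]
    slope = float(np.polyfit(t, i, 1)[0]) if np.ptp(t) > 0 else 0.0
    return SteadyState(
        mean=float(i.mean()),
        drift_slope=slope,
        window=(t0, t1),
        n_samples=int(mask.sum()),
    )


@dataclass(frozen=True)
class RelativeChange:
    percent_change: float  # (after-before)/before × 100
    fold_change: float  # after/before


def relative_change(before: float, after: float) -> RelativeChange:
    """Percent and fold change between two (steady-state) currents."""
    if not (np.isfinite(before) and np.isfinite(after)):
        raise ValueError("inputs must be finite")
    if before == 0:
        raise ZeroDivisionError("fold change undefined for a zero baseline")
    return RelativeChange(
        percent_change=(after - before) / before * 100.0,
        fold_change=after / before,
    )


def _dpv_baseline(
    potential: np.ndarray, current: np.ndarray, flank_fraction: float = 0.2
) -> tuple[np.ndarray, float]:
    """Linear baseline from the outer flanks of a DPV scan.

    Fits a straight line to the outer ``flank_fraction`` of points on each
    side (the peak is assumed to sit in the interior) and returns the
    baseline evaluated everywhere plus the residual SD over the flanks as
    the noise estimate.
    """
    n = len(potential)
    k = max(int(round(n * flank_fraction)), 2)
    idx = np.r_[0:k, n - k : n]
    coef = np.polyfit(potential[idx], current[idx], 1)
    baseline = np.polyval(coef, potential)
    noise = float(np.std(current[idx] - baseline[idx]))
    return baseline, noise


def dpv_peak_features(v: Voltammogram) -> PeakFeature:
    """Peak potential, height and W_1/2 of a DPV peak.

    Baseline: linear fit over the outer 20% of the scan on each side.
    The apex must exceed the baseline by more than 3× the flank noise;
    otherwise :class:`NoPeakError` is raised.  Half-height crossings are
    located by linear interpolation on each side of the apex.
    """
    if v.mode != "dpv":
        raise ValueError(f"expected a DPV scan, got mode {v.mode!r}")
    order = np.argsort(v.potential)
    e, i_raw = v.potential[order], v.current[order]
    # apex and crossings are located on a lightly smoothed signal, but the
    # noise estimate comes from the raw flank residuals — a smoothed noise
    # maximum must clear the raw 3σ bar, so pure noise never qualifies
    i = savgol_filter(i_raw, 11, 2) if len(i_raw) >= 11 else i_raw
    _, noise = _dpv_baseline(e, i_raw)
    baseline, _ = _dpv_baseline(e, i)
    y = i - baseline
    apex = int(np.argmax(y))
    height = float(y[apex])
    if height <= 0 or height <= 3.0 * noise:
        raise NoPeakError(
            f"no peak above baseline + 3×noise (height {height:.3g}, "
            f"noise {noise:.3g})"
        )
    half = height / 2.0

    def crossing(sl: slice, step: int) -> float:
        # walk away from the apex until y drops through half height
        idxs = range(apex, sl.stop, step) if step > 0 else range(apex, sl.stop, step)
        prev = apex
        for j in idxs:
            if y[j] < half:
                # interpolate between prev (>= half) and j (< half)
                e0, e1 = e[prev], e[j]
                y0, y1 = y[prev], y[j]
                return float(e0 + (half - y0) * (e1 - e0) / (y1 - y0))
            prev = j
        raise NoPeakError("half-height crossing not found within the scan")

    e_right = crossing(slice(apex, len(y)), +1)
    e_left = crossing(slice(apex, -1), -1)
    w_half = (e_right - e_left) * 1000.0  # V → mV
    return PeakFeature(
        peak_potential=float(e[apex]), peak_height=height, w_half_mV=w_half
    )


@dataclass(frozen=True)
class ElectronCount:
    """Apparent electron number from the Nernstian DPV width criterion."""

    n_apparent: float
    multielectron: bool  # n_apparent > 1


def apparent_electron_count(
    w_half_mV: float, temperature: float = 298.15
) -> ElectronCount:
    """Electron count implied by a DPV peak width.

    In the small-pulse Nernstian limit W_1/2 = 3.526·RT/nF, so
    n = (3.526·RT/F in mV) / W_1/2 ≈ 90.6 / W_1/2 at 298.15 K.  A width
    narrower than the one-electron limit (n_apparent > 1) indicates a
    multi-electron transfer.
    """
    if w_half_mV <= 0:
        raise ValueError(f"W_1/2 must be > 0, got {w_half_mV}")
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    w_one = NERNSTIAN_WIDTH_COEFF * GAS_CONSTANT * temperature / FARADAY * 1000.0
    n = w_one / w_half_mV
    return ElectronCount(n_apparent=n, multielectron=n > 1.0)


@dataclass(frozen=True)
class CVFeatures:
    """Catalytic-wave onset and (if present) reversible-couple midpoint."""

    onset_potential: float | None  # V; None when no wave above threshold
    midpoint_potential: float | None  # V; None unless both peaks found
    anodic_peak: float | None = None
    cathodic_peak: float | None = None

    @property
    def has_wave(self) -> bool:
        return self.onset_potential is not None


def _split_sweeps(e: np.ndarray, i: np.ndarray):
    """Split a CV into positive-going and negative-going sweeps."""
    de = np.diff(e)
    pos = de > 0
    if pos.all() or not pos.any():
        # single-direction scan
        return (e, i) if pos.all() else (None, None), (e, i) if not pos.any() else (None, None)
    turn = int(np.argmin(pos)) if pos[0] else int(np.argmax(pos))
    first = (e[: turn + 1], i[: turn + 1])
    second = (e[turn:], i[turn:])
    if pos[0]:
        return first, second
    return second, first


def _peak_index(
    y: np.ndarray, baseline: np.ndarray, kind: str, min_prominence: float = 0.1
) -> int | None:
    """Index of a genuine voltammetric peak, or None.

    The global max (min) must be interior, and the signal must fall back
    toward the baseline past the apex by at least ``min_prominence`` of
    the peak excursion — a monotone wave (e.g. steady-state catalysis)
    has no peak.
    """
    excursion = y - baseline
    if kind == "min":
        excursion = -excursion
    idx = int(np.argmax(excursion))
    if idx == 0 or idx == len(y) - 1:
        return None
    height = excursion[idx]
    if height <= 0:
        return None
    drop_after = height - np.min(excursion[idx:])
    drop_before = height - np.min(excursion[: idx + 1])
    if min(drop_after, drop_before) < min_prominence * height:
        return None
    return idx


def cv_features(
    v: Voltammogram,
    noise_window: tuple[float, float],
    smooth_window: int = 11,
    smooth_order: int = 2,
    threshold_sigmas: float = 3.0,
) -> CVFeatures:
    """Onset and midpoint potentials from a cyclic voltammogram.

    * Onset: on the positive-going sweep, the current is smoothed
      (Savitzky–Golay, window 11 points, order 2) and a linear baseline is
      fitted over ``noise_window`` (a potential range known to precede the
      wave).  The onset is the first potential at which the smoothed
      current exceeds baseline + ``threshold_sigmas`` × baseline noise and
      stays above it; a trace that never crosses gives a no-wave result
      (``onset_potential=None``), not an exception.
    * Midpoint: mean of the anodic (forward-sweep maximum) and cathodic
      (reverse-sweep minimum) peak potentials, reported only when both
      are interior local extrema (a detectable reversible couple).
    """
    if v.mode != "cv":
        raise ValueError(f"expected a CV scan, got mode {v.mode!r}")
    (fe, fi), (re_, ri) = _split_sweeps(v.potential, v.current)

    onset = None
    anodic = cathodic = None
    if fe is not None and len(fe) >= smooth_window:
        order = np.argsort(fe)
        e_f, i_f = fe[order], fi[order]
        sm = savgol_filter(i_f, smooth_window, smooth_order)
        lo, hi = noise_window
        base_mask = (e_f >= lo) & (e_f <= hi)
        if base_mask.sum() < 3:
            raise ValueError(
                f"noise window {noise_window} covers {base_mask.sum()} "
                "forward-sweep samples; need >= 3"
            )
        coef = np.polyfit(e_f[base_mask], i_f[base_mask], 1)
        baseline = np.polyval(coef, e_f)
        sd = float(np.std(i_f[base_mask] - baseline[base_mask]))
        floor = max(sd, 1e-12 * max(1.0, float(np.max(np.abs(i_f)))))
        above = sm > baseline + threshold_sigmas * floor
        # only look past the end of the baseline window
        start = int(np.searchsorted(e_f, hi))
        for j in range(start, len(e_f)):
            if above[j]:
                onset = float(e_f[j])
                break
        a_idx = _peak_index(sm, baseline, "max")
        if a_idx is not None and sm[a_idx] > baseline[a_idx] + threshold_sigmas * floor:
            anodic = float(e_f[a_idx])
    if re_ is not None and len(re_) >= smooth_window:
        order = np.argsort(re_)
        e_r, i_r = re_[order], ri[order]
        sm_r = savgol_filter(i_r, smooth_window, smooth_order)
        lo, hi = noise_window
        base_mask_r = (e_r >= lo) & (e_r <= hi)
        if base_mask_r.sum() >= 3:
            coef_r = np.polyfit(e_r[base_mask_r], i_r[base_mask_r], 1)
            baseline_r = np.polyval(coef_r, e_r)
        else:
            baseline_r = np.zeros_like(e_r)
        c_idx = _peak_index(sm_r, baseline_r, "min")
        if c_idx is not None:
            cathodic = float(e_r[c_idx])

    midpoint = None
    if anodic is not None and cathodic is not None:
        midpoint = (anodic + cathodic) / 2.0
    return CVFeatures(
        onset_potential=onset,
        midpoint_potential=midpoint,
        anodic_peak=anodic,
        cathodic_peak=cathodic,
    )
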