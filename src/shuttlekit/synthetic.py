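"""Seeded synthetic-data generators for every analysis stage.

Each generator draws from its own ``numpy.random.default_rng(seed)``
stream (never shared across calls), takes the true parameters explicitly,
and returns the consuming module's data container together with a
``truth`` dict recording exactly what was generated — so every estimator
in the package can be round-tripped against known truth with no external
data.

Defaults emulate the bench conditions of a mediated electron-transfer
study: a 4PL dose–response with EC₅₀ 25 nM read in triplicate at 8 doses
with Gaussian noise at 2% of the dynamic range; DPV scans with 1 mV
resolution over the −0.8…+0.6 V instrument window; reversible CV couples
centred at −0.32 V; chronoamperometry plateaus near 22 µA cm⁻² with
media-swap events; and six-point linear calibration curves.

Noise is Gaussian throughout.  The DPV peak uses the small-amplitude
analytic Nernstian form (sech² of the normalized overpotential) — the
regime the W_1/2 electron-count criterion assumes — rather than a full
pulse-train simulation.  The reversible CV couple is produced by an
explicit finite-difference simulation of semi-infinite diffusion with a
Nernstian surface condition, so its peak separation is an emergent
check (≈ 57–59/n mV at 25 °C), not painted on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .doseresponse import DoseResponseData, dose_resp
from .electrochem import (
    FARADAY,
    GAS_CONSTANT,
    NERNSTIAN_WIDTH_COEFF,
    POTENTIAL_WINDOW,
    AmperometryTrace,
    Voltammogram,
)
from .quantify import CalibrationPoint

__all__ = [
    "AmperometrySegment",
    "gen_dose_response",
    "gen_dpv",
    "gen_cv",
    "gen_amperometry",
    "gen_calibration",
    "generate",
    "nernstian_w_half_mV",
]

_DEFAULT_DOSES_NM = tuple(float(x) for x in np.logspace(0, 4, 8).round(3))


def nernstian_w_half_mV(n_electrons: float, temperature: float = 298.15) -> float:
    """Theoretical small-amplitude DPV width 3.526·RT/nF in mV."""
    return (
        NERNSTIAN_WIDTH_COEFF * GAS_CONSTANT * temperature / (n_electrons * FARADAY)
    ) * 1000.0


def gen_dose_response(
    seed: int,
    ec50: float = 25.0,
    a1: float = 0.0,
    a2: float = 1.0,
    hill: float = 1.0,
    doses: Sequence[float] = _DEFAULT_DOSES_NM,
    replicates: int = 3,
    noise_sd: float | None = None,
) -> tuple[DoseResponseData, dict]:
    """4PL dose–response data with Gaussian noise.

    ``noise_sd`` defaults to 2% of the dynamic range |A2 − A1|.
    Replicates are independent draws at each dose.
    """
    doses = np.asarray(doses, dtype=float)
    if len(np.unique(doses[doses > 0])) < 4:
        raise ValueError("need >= 4 distinct positive doses")
    if ec50 <= 0:
        raise ValueError(f"ec50 must be > 0, got {ec50}")
    if noise_sd is None:
        noise_sd = 0.02 * abs(a2 - a1)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    conc = np.repeat(doses, replicates)
    clean = dose_resp(conc, a1, a2, np.log10(ec50), hill)
    resp = clean + rng.normal(0.0, noise_sd, size=conc.shape)
    reps = np.tile(np.arange(replicates), len(doses))
    truth = {
        "kind": "dose_response",
        "a1": a1,
        "a2": a2,
        "ec50_nM": ec50,
        "hill": hill,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return DoseResponseData(conc, resp, replicates=reps), truth


def gen_dpv(
    seed: int,
    e0: float = -0.32,
    n_electrons: float = 1.0,
    peak_height: float = 1.0,
    window: tuple[float, float] = POTENTIAL_WINDOW,
    step_mV: float = 1.0,
    noise_sd: float = 0.0,
    baseline_slope: float = 0.0,
    baseline_intercept: float = 0.0,
    temperature: float = 298.15,
) -> tuple[Voltammogram, dict]:
    """Small-amplitude Nernstian DPV peak plus linear baseline and noise.

    The differential current of a reversible n-electron couple probed
    with a small pulse is proportional to sech²(nF(E−E₀)/2RT), whose full
    width at half maximum is 3.526·RT/nF — the shape the W_1/2 criterion
    assumes.
    """
    lo, hi = window
    if not lo < e0 < hi:
        raise ValueError(f"e0 {e0} outside the scan window {window}")
    rng = np.random.default_rng(seed)
    e = np.arange(lo, hi + 1e-12, step_mV / 1000.0)
    u = n_electrons * FARADAY * (e - e0) / (2.0 * GAS_CONSTANT * temperature)
    i = peak_height / np.cosh(u) ** 2
    i += baseline_intercept + baseline_slope * e
    i += rng.normal(0.0, noise_sd, size=e.shape)
    truth = {
        "kind": "dpv",
        "e0_V": e0,
        "n_electrons": n_electrons,
        "peak_height": peak_height,
        "w_half_mV": nernstian_w_half_mV(n_electrons, temperature),
        "noise_sd": noise_sd,
        "seed": seed,
    }
    meta = {
        "pulse_height_mV": 50.0,
        "pulse_width_ms": 500.0,
        "step_height_mV": step_mV,
        "step_time_ms": 1000.0,
        "temperature_K": temperature,
    }
    return Voltammogram(e, i, mode="dpv", metadata=meta), truth


def _simulate_reversible_couple(
    e: np.ndarray,
    e0: float,
    n_electrons: float,
    temperature: float,
    substeps: int = 24,
) -> np.ndarray:
    """Dimensionless current of a reversible couple along a potential program.

    Explicit finite-difference simulation of semi-infinite diffusion with
    equal diffusivities and a Nernstian surface condition (only the
    reduced species present initially, so the forward positive-going
    sweep is anodic).  The potential program is refined by ``substeps``
    internal time steps per sample for accuracy; returns the surface flux
    at each requested potential.
    """
    f = n_electrons * FARADAY / (GAS_CONSTANT * temperature)
    e_fine = np.interp(
        np.arange(len(e) * substeps) / substeps, np.arange(len(e)), e
    )
    n_t = len(e_fine)
    d_m = 0.45  # model diffusion number, < 0.5 for stability
    n_x = int(6.0 * np.sqrt(d_m * n_t)) + 2
    c_r = np.ones(n_x)
    c_o = np.zeros(n_x)
    flux = np.empty(n_t)
    for k in range(n_t):
        c_r[1:-1] += d_m * (c_r[2:] - 2 * c_r[1:-1] + c_r[:-2])
        c_o[1:-1] += d_m * (c_o[2:] - 2 * c_o[1:-1] + c_o[:-2])
        c_r[-1], c_o[-1] = 1.0, 0.0
        theta = np.exp(np.clip(f * (e_fine[k] - e0), -300, 300))
        total = c_r[1] + c_o[1]
        c_r[0] = total / (1.0 + theta)
        c_o[0] = total - c_r[0]
        flux[k] = c_r[1] - c_r[0]
    return flux[::substeps]


def gen_cv(
    seed: int,
    e0: float = -0.32,
    n_electrons: float = 1.0,
    peak_current: float = 1.0,
    window: tuple[float, float] = (-0.8, 0.2),
    step_mV: float = 1.0,
    noise_sd: float = 0.0,
    catalytic: dict | None = None,
    temperature: float = 298.15,
) -> tuple[Voltammogram, dict]:
    """Cyclic voltammogram: reversible couple and/or catalytic wave.

    * Reversible couple (``peak_current > 0``): finite-difference
      simulation (see :func:`_simulate_reversible_couple`) scaled so the
      anodic peak equals ``peak_current``.
    * Catalytic wave (``catalytic={"foot_V": ..., "amplitude": ...,
      "rise_V": ...}``): zero below the foot potential, rising as
      ``amplitude·(1 − exp(−(E−foot)/rise))`` above it, identical on both
      sweeps (steady-state catalysis).  Set ``peak_current=0`` for a pure
      catalytic wave.

    The scan runs ``window[0] → window[1] → window[0]`` at ``step_mV``
    resolution.
    """
    lo, hi = window
    if peak_current > 0 and not lo < e0 < hi:
        raise ValueError(f"e0 {e0} outside the scan window {window}")
    rng = np.random.default_rng(seed)
    step = step_mV / 1000.0
    fwd = np.arange(lo, hi + 1e-12, step)
    rev = fwd[-2::-1]
    e = np.concatenate([fwd, rev])
    i = np.zeros_like(e)
    if peak_current > 0:
        flux = _simulate_reversible_couple(e, e0, n_electrons, temperature)
        scale = peak_current / flux.max()
        i += scale * flux
    if catalytic is not None:
        foot = catalytic["foot_V"]
        amp = catalytic["amplitude"]
        rise = catalytic.get("rise_V", 0.02)
        over = np.clip(e - foot, 0.0, None)
        i += amp * (1.0 - np.exp(-over / rise)) * (e > foot)
    i += rng.normal(0.0, noise_sd, size=e.shape)
    truth = {
        "kind": "cv",
        "e0_V": e0 if peak_current > 0 else None,
        "n_electrons": n_electrons,
        "peak_current": peak_current,
        "catalytic": catalytic,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    meta = {"scan_rate_mV_s": 10.0, "temperature_K": temperature}
    return Voltammogram(e, i, mode="cv", metadata=meta), truth


@dataclass(frozen=True)
class AmperometrySegment:
    """One chronoamperometry segment: from ``t_start`` the current relaxes
    exponentially toward ``plateau`` with time constant ``tau``."""

    t_start: float  # s
    plateau: float  # µA cm⁻²
    tau: float  # s
    label: str = ""

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


def gen_amperometry(
    seed: int,
    segments: Sequence[AmperometrySegment],
    t_end: float,
    dt: float = 60.0,
    initial_current: float = 0.0,
    noise_sd: float = 0.0,
) -> tuple[AmperometryTrace, dict]:
    """Piecewise-exponential chronoamperometry with event markers.

    Each segment starts from the current value reached at its boundary
    (continuity) and relaxes toward its plateau; segment boundaries are
    recorded as labelled events (media swaps, shuttle additions).
    Segments must be strictly ordered and non-overlapping.
    """
    if not segments:
        raise ValueError("need at least one segment")
    starts = [s.t_start for s in segments]
    if any(b <= a for a, b in zip(starts, starts[1:])):
        raise ValueError("segments overlap or are out of order")
    if starts[0] < 0 or starts[-1] >= t_end:
        raise ValueError("segment starts must lie in [0, t_end)")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_end + 1e-9, dt)
    i = np.full_like(t, initial_current)
    level = initial_current
    bounds = starts + [t_end + dt]
    for k, seg in enumerate(segments):
        mask = (t >= seg.t_start) & (t < bounds[k + 1])
        i[mask] = seg.plateau + (level - seg.plateau) * np.exp(
            -(t[mask] - seg.t_start) / seg.tau
        )
        level = seg.plateau + (level - seg.plateau) * np.exp(
            -(bounds[k + 1] - seg.t_start) / seg.tau
        )
    i += rng.normal(0.0, noise_sd, size=t.shape)
    events = [(s.label, s.t_start) for s in segments if s.label]
    truth = {
        "kind": "amperometry",
        "segments": [
            {"t_start": s.t_start, "plateau": s.plateau, "tau": s.tau, "label": s.label}
            for s in segments
        ],
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return AmperometryTrace(t, i, events=events), truth


def gen_calibration(
    seed: int,
    concentrations: Sequence[float] = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0),
    slope: float = 100.0,
    intercept: float = 0.0,
    noise_sd: float = 0.0,
) -> tuple[list[CalibrationPoint], dict]:
    """Linear calibration points: area = slope·conc + intercept + noise."""
    conc = np.asarray(concentrations, dtype=float)
    if len(np.unique(conc)) < 2:
        raise ValueError("need >= 2 distinct concentrations")
    if slope <= 0:
        raise ValueError(f"slope must be > 0, got {slope}")
    rng = np.random.default_rng(seed)
    areas = slope * conc + intercept + rng.normal(0.0, noise_sd, size=conc.shape)
    pts = [CalibrationPoint(float(c), float(a)) for c, a in zip(conc, areas)]
    truth = {
        "kind": "calibration",
        "slope": slope,
        "intercept": intercept,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return pts, truth


_GENERATORS = {
    "dose_response": gen_dose_response,
    "dpv": gen_dpv,
    "cv": gen_cv,
    "amperometry": gen_amperometry,
    "calibration": gen_calibration,
}


def generate(kind: str, seed: int, **params):
    """Dispatch to a generator by kind (see ``_GENERATORS`` keys)."""
    if kind not in _GENERATORS:
        raise ValueError(f"unknown generator kind {kind!r}; choose from {sorted(_GENERATORS)}")
    if kind == "amperometry" and "segments" in params:
        segs = params["segments"]
        if segs and isinstance(segs[0], dict):
            params["segments"] = [AmperometrySegment(**s) for s in segs]
    return _GENERATORS[kind](seed=seed, **params)
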