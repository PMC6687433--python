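"""Simulation parameters derived from culture measurements.

The diffusion–production model needs a per-cell secretion rate, a gel
diffusion coefficient and a volumetric source term.  These are derived
here from bench measurements: the shuttle concentration accumulated by a
stationary-phase planktonic culture of known cell density over a known
time, the aqueous diffusion coefficient scaled by the fraction retained
in the gel, and the product of per-cell rate and volumetric cell density.

All arithmetic is unit-tracked: concentrations enter in mol L⁻¹ and cell
densities in cells mL⁻¹ (the units bench measurements are reported in);
rates come out in mol cell⁻¹ s⁻¹ and volumetric sources in mol cm⁻³ s⁻¹
(the units the solver consumes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "CultureMeasurement",
    "ProductionRateDiscrepancyWarning",
    "per_cell_production_rate",
    "gel_diffusion_coefficient",
    "volumetric_source",
    "round_sig",
]

ML_PER_L = 1000.0


class ProductionRateDiscrepancyWarning(UserWarning):
    """Recomputed per-cell rate differs grossly from an expected value."""


@dataclass(frozen=True)
class CultureMeasurement:
    """Shuttle accumulation by a planktonic culture.

    final_concentration : mol L⁻¹ accumulated over ``duration``
    cell_density : cells mL⁻¹
    duration : s
    """

    final_concentration: float
    cell_density: float
    duration: float

    def __post_init__(self) -> None:
        if self.final_concentration < 0:
            raise ValueError("final_concentration must be >= 0")
        if self.cell_density < 0:
            raise ValueError("cell_density must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


def per_cell_production_rate(
    m: CultureMeasurement,
    expected: float | None = None,
) -> float:
    """Per-cell secretion rate in mol cell⁻¹ s⁻¹.

    Computed as ``final_concentration / (cell_density per litre) /
    duration``: each cell contributes linearly to the accumulated pool, so
    the rate is the pool divided by cell-seconds per litre.

    If ``expected`` (mol cell⁻¹ s⁻¹) is supplied and the recomputed value
    differs from it by more than a factor of 10 in either direction, a
    :class:`ProductionRateDiscrepancyWarning` is emitted carrying the
    ratio — the recomputed value is still returned, never silently
    replaced.
    """
    if m.cell_density == 0:
        raise ZeroDivisionError(
            "cell_density is zero: per-cell rate undefined (no producers)"
        )
    density_per_l = m.cell_density * ML_PER_L
    rate = m.final_concentration / density_per_l / m.duration
    if expected is not None and expected > 0 and rate > 0:
        ratio = expected / rate
        if ratio > 10 or ratio < 0.1:
            warnings.warn(
                f"recomputed per-cell rate {rate:.3g} mol cell⁻¹ s⁻¹ differs "
                f"from the expected {expected:.3g} by a factor of {ratio:.3g}",
                ProductionRateDiscrepancyWarning,
                stacklevel=2,
            )
    return rate


def round_sig(x: float, sig_figs: int) -> float:
    """Round to a number of significant figures (reporting only)."""
    if x == 0:
        return 0.0
    if sig_figs < 1:
        raise ValueError("sig_figs must be >= 1")
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig_figs - 1))


def gel_diffusion_coefficient(
    d_water: float,
    retention_fraction: float,
    sig_figs: int | None = None,
) -> float:
    """Diffusion coefficient in the gel, cm² s⁻¹.

    Small molecules in dilute agarose diffuse at a fixed fraction of their
    aqueous coefficient (the gel porosity is large relative to the
    molecule).  ``sig_figs`` optionally rounds the result for reporting;
    rounding is never applied inside downstream computation.
    """
    if d_water <= 0:
        raise ValueError(f"d_water must be > 0, got {d_water}")
    if not 0 < retention_fraction <= 1:
        raise ValueError(
            f"retention_fraction must be in (0, 1], got {retention_fraction}"
        )
    d = d_water * retention_fraction
    return round_sig(d, sig_figs) if sig_figs is not None else d


def volumetric_source(per_cell_rate: float, cell_density_per_cm3: float) -> float:
    """Volumetric production term P, mol cm⁻³ s⁻¹.

    Product of per-cell rate (mol cell⁻¹ s⁻¹) and volumetric cell density
    (cells cm⁻³) inside the source region.
    """
    if per_cell_rate < 0 or cell_density_per_cm3 < 0:
        raise ValueError("per_cell_rate and cell_density must be >= 0")
    return per_cell_rate * cell_density_per_cm3
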