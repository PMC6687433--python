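"""Absolute metabolite quantification from summed-adduct EIC areas.

Integrated extracted-ion-chromatogram (EIC) areas — summed over the
adducts a compound produces in ESI — are interpreted against an external
standard curve (straight line fitted by ordinary least squares), with an
optional single-point isotope-spike recovery correction for losses during
sample work-up.

The calibration fit follows the statsmodels Model/Results convention:
``StandardCurveModel(points).fit()`` returns a :class:`StandardCurve`
carrying slope, intercept, R² and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationPoint",
    "StandardCurve",
    "StandardCurveModel",
    "Recovery",
    "QuantResult",
    "summed_adduct_area",
    "fit_standard_curve",
    "estimate_recovery",
    "quantify",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """One external-standard point: known concentration and its EIC area."""

    concentration: float  # nM
    area: float  # arbitrary units, summed over adducts

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if not np.isfinite(self.area):
            raise ValueError("area must be finite")


def summed_adduct_area(
    areas: dict[str, float], adducts: Sequence[str]
) -> float:
    """Sum EIC areas over the requested adducts.

    Raises ``KeyError`` naming the missing adducts and listing what was
    found, so a typo in an adduct label fails loudly.
    """
    missing = [a for a in adducts if a not in areas]
    if missing:
        raise KeyError(
            f"adducts {missing} not present; available: {sorted(areas)}"
        )
    return float(sum(areas[a] for a in adducts))


@dataclass(frozen=True)
class StandardCurve:
    """Fitted calibration line: area = slope·concentration + intercept."""

    slope: float  # area per nM
    intercept: float  # area
    r_squared: float
    n_points: int
    conc_min: float = 0.0
    conc_max: float = float("inf")

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a standard curve needs at least 2 points")

    @property
    def usable(self) -> bool:
        return self.slope > 0

    def predict_area(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept

    def summary(self) -> str:
        return (
            f"Standard curve ({self.n_points} points, "
            f"{self.conc_min:g}–{self.conc_max:g} nM)\n"
            f"  slope     {self.slope:.6g} area/nM\n"
            f"  intercept {self.intercept:.6g} area\n"
            f"  R²        {self.r_squared:.6f}"
        )


class StandardCurveModel:
    """Ordinary least-squares straight line through calibration points.

    Unweighted OLS with a free intercept by default; ``fit(through_zero=
    True)`` forces the line through the origin.  Requires at least two
    distinct concentrations (the design is degenerate otherwise).
    """

    def __init__(self, points: Sequence[CalibrationPoint]):
        if len(points) < 2:
            raise ValueError(
                f"need >= 2 calibration points, got {len(points)}"
            )
        self.points = list(points)
        self.conc = np.array([p.concentration for p in points], dtype=float)
        self.area = np.array([p.area for p in points], dtype=float)
        if len(np.unique(self.conc)) < 2:
            raise ValueError(
                "degenerate design: need >= 2 distinct concentrations"
            )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, conc_col: str = "conc_nM", area_col: str = "area"
    ) -> "StandardCurveModel":
        pts = [
            CalibrationPoint(c, a)
            for c, a in zip(df[conc_col].to_numpy(), df[area_col].to_numpy())
        ]
        return cls(pts)

    def fit(self, through_zero: bool = False) -> StandardCurve:
        x, y = self.conc, self.area
        if through_zero:
            design = x[:, None]
        else:
            design = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        slope = float(coef[0])
        intercept = 0.0 if through_zero else float(coef[1])
        resid = y - (slope * x + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return StandardCurve(
            slope=slope,
            intercept=intercept,
            r_squared=r2,
            n_points=len(x),
            conc_min=float(x.min()),
            conc_max=float(x.max()),
        )


def fit_standard_curve(
    points: Sequence[CalibrationPoint], through_zero: bool = False
) -> StandardCurve:
    """Functional wrapper around :class:`StandardCurveModel`."""
    return StandardCurveModel(points).fit(through_zero=through_zero)


@dataclass(frozen=True)
class Recovery:
    """Work-up recovery fraction from an isotope spike."""

    fraction: float
    over_recovery: bool  # fraction > 1 (reported as-is, flagged)


def estimate_recovery(spiked_known: float, measured: float) -> Recovery:
    """Recovery fraction from a known isotope-labelled spike.

    ``measured / spiked_known`` (both in nM); fractions above 1 are
    reported unclipped with ``over_recovery=True``.
    """
    if spiked_known <= 0:
        raise ValueError(f"spiked_known must be > 0, got {spiked_known}")
    frac = measured / spiked_known
    return Recovery(fraction=frac, over_recovery=frac > 1.0)


@dataclass(frozen=True)
class QuantResult:
    """Back-calculated concentration with data-quality flags."""

    concentration: float  # nM, recovery-corrected
    below_blank: bool  # area fell below the curve intercept
    extrapolated: bool  # outside the calibration range

    def flags(self) -> list[str]:
        out = []
        if self.below_blank:
            out.append("below_blank")
        if self.extrapolated:
            out.append("extrapolated")
        return out


def quantify(
    area: float, curve: StandardCurve, recovery: float | Recovery = 1.0
) -> QuantResult:
    """Back-calculate a concentration from a summed EIC area.

    ``((area − intercept) / slope) / recovery``.  Negative back-calculated
    concentrations (area below the blank/intercept) are reported as-is and
    flagged; values outside the calibration range are flagged as
    extrapolated.
    """
    if not curve.usable:
        raise ValueError(f"unusable curve: slope {curve.slope} <= 0")
    r = recovery.fraction if isinstance(recovery, Recovery) else float(recovery)
    if r <= 0:
        raise ValueError(f"recovery must be > 0, got {r}")
    raw = (area - curve.intercept) / curve.slope
    conc = raw / r
    return QuantResult(
        concentration=conc,
        below_blank=raw < 0,
        extrapolated=not (curve.conc_min <= raw <= curve.conc_max),
    )
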