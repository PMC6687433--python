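"""Four-parameter logistic (4PL) dose–response fitting.

The response (here, absorbance of a reduced colorimetric electron
acceptor) as a function of shuttle concentration x is modelled with the
OriginLab ``DoseResp`` parameterization of the 4PL:

    y = A1 + (A2 − A1) / (1 + 10^((log10(x0) − log10(x)) · p))

with A1 the lower asymptote, A2 the upper asymptote, x0 the EC₅₀ (the
concentration at half-maximal response) and p the Hill slope.  Fitting is
unweighted nonlinear least squares in (A1, A2, log10(x0), p); working on
the log₁₀ EC₅₀ axis keeps the optimiser well-scaled across decades of
concentration.  A deterministic multi-start grid over log10(x0) and p
guards against local minima.  Standard errors are asymptotic, from the
Jacobian at the optimum.

Follows the statsmodels convention: ``DoseResponseModel(data).fit()``
returns a :class:`DoseResponseResults` with parameters, standard errors,
diagnostics and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseError",
    "DoseResponseData",
    "DoseResponseModel",
    "DoseResponseResults",
    "dose_resp",
    "fit_dose_resp",
    "predict_response",
]

_HILL_STARTS = (0.5, 1.0, 2.0)
_N_LOGX0_STARTS = 5


class DoseResponseError(ValueError):
    """Invalid dose–response data or failed fit."""


def dose_resp(
    x: np.ndarray | float,
    a1: float,
    a2: float,
    log10_x0: float,
    hill: float,
) -> np.ndarray | float:
    """Evaluate the 4PL at concentration(s) x (> 0)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise DoseResponseError("concentration must be > 0 on the log axis")
    exponent = np.clip((log10_x0 - np.log10(x)) * hill, -300, 300)
    out = a1 + (a2 - a1) / (1.0 + 10.0**exponent)
    return out if out.ndim else float(out)


@dataclass
class DoseResponseData:
    """Dose–response observations; replicates enter as individual points.

    Zero-dose rows are split off into ``control_responses`` at
    construction — they cannot sit on the log-concentration axis, but
    they seed the lower-asymptote initial guess.
    """

    concentrations: np.ndarray  # nM, > 0
    responses: np.ndarray
    replicates: np.ndarray | None = None
    control_responses: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise DoseResponseError("concentrations and responses differ in length")
        if self.replicates is not None:
            self.replicates = np.asarray(self.replicates)
            if self.replicates.shape != self.concentrations.shape:
                raise DoseResponseError("replicate labels differ in length")
        zero = self.concentrations == 0
        if np.any(zero):
            self.control_responses = np.concatenate(
                [np.asarray(self.control_responses, dtype=float), self.responses[zero]]
            )
            keep = ~zero
            self.concentrations = self.concentrations[keep]
            self.responses = self.responses[keep]
            if self.replicates is not None:
                self.replicates = self.replicates[keep]
        if np.any(self.concentrations < 0):
            raise DoseResponseError("concentrations must be >= 0")
        if len(np.unique(self.concentrations)) < 4:
            raise DoseResponseError(
                "need >= 4 distinct positive concentrations to fit a 4PL"
            )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        conc_col: str = "conc_nM",
        response_col: str = "response",
        replicate_col: str | None = "replicate",
    ) -> "DoseResponseData":
        reps = None
        if replicate_col is not None and replicate_col in df.columns:
            reps = df[replicate_col].to_numpy()
        return cls(
            concentrations=df[conc_col].to_numpy(dtype=float),
            responses=df[response_col].to_numpy(dtype=float),
            replicates=reps,
        )


@dataclass
class DoseResponseResults:
    """Fitted 4PL parameters, asymptotic uncertainties and diagnostics."""

    a1: float
    a2: float
    log10_ec50: float
    hill: float
    bse: dict[str, float]  # asymptotic standard errors by parameter name
    rss: float
    n_obs: int
    converged: bool
    n_starts_tried: int = 0

    @property
    def ec50(self) -> float:
        return 10.0**self.log10_ec50

    @property
    def ec50_se(self) -> float:
        """Asymptotic SE of EC₅₀, delta method from the log₁₀ scale."""
        return self.ec50 * np.log(10.0) * self.bse["log10_ec50"]

    @property
    def params(self) -> dict[str, float]:
        return {
            "a1": self.a1,
            "a2": self.a2,
            "log10_ec50": self.log10_ec50,
            "hill": self.hill,
        }

    def predict(self, concentration: np.ndarray | float) -> np.ndarray | float:
        return dose_resp(concentration, self.a1, self.a2, self.log10_ec50, self.hill)

    def summary(self) -> str:
        lines = [
            "4PL dose-response fit (unweighted least squares)",
            f"  n = {self.n_obs}, RSS = {self.rss:.6g}, "
            f"converged = {self.converged}",
            f"  {'param':<11}{'estimate':>12}{'asympt. SE':>12}",
        ]
        for name, value in self.params.items():
            lines.append(f"  {name:<11}{value:>12.5g}{self.bse[name]:>12.3g}")
        lines.append(
            f"  EC50 = {self.ec50:.4g} nM (asymptotic SE {self.ec50_se:.3g})"
        )
        return "\n".join(lines)


class DoseResponseModel:
    """Nonlinear least-squares 4PL model for one dose–response dataset."""

    def __init__(self, data: DoseResponseData):
        self.data = data

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "DoseResponseModel":
        return cls(DoseResponseData.from_dataframe(df, **kwargs))

    def _starts(self, start: dict[str, float] | None):
        x, y = self.data.concentrations, self.data.responses
        if self.data.control_responses.size:
            a1_0 = float(np.mean(self.data.control_responses))
        else:
            a1_0 = float(np.min(y))
        a2_0 = float(np.max(y))
        if start is not None:
            yield (
                start.get("a1", a1_0),
                start.get("a2", a2_0),
                start.get("log10_ec50", float(np.median(np.log10(x)))),
                start.get("hill", 1.0),
            )
            return
        logx = np.log10(x)
        for lx0 in np.linspace(logx.min(), logx.max(), _N_LOGX0_STARTS):
            for p0 in _HILL_STARTS:
                yield (a1_0, a2_0, float(lx0), p0)

    def fit(self, start: dict[str, float] | None = None) -> DoseResponseResults:
        """Fit by multi-start trust-region least squares.

        The start grid (5 log₁₀-EC₅₀ values spanning the observed
        concentration range × Hill slopes 0.5/1/2) is traversed in a fixed
        order for determinism; the best converged solution by RSS wins.
        """
        x, y = self.data.concentrations, self.data.responses
        if np.ptp(y) == 0:
            raise DoseResponseError(
                "all responses are equal: 4PL parameters are unidentifiable"
            )

        def resid(theta):
            return dose_resp(x, *theta) - y

        best = None
        n_tried = 0
        for theta0 in self._starts(start):
            n_tried += 1
            sol = least_squares(resid, theta0, method="lm", max_nfev=2000)
            rss = 2.0 * sol.cost
            if sol.success and (best is None or rss < best[1] - 1e-15):
                best = (sol, rss)
        if best is None:
            raise DoseResponseError(
                f"4PL fit failed to converge from any of {n_tried} starts"
            )
        sol, rss = best
        a1, a2, lx0, hill = sol.x
        names = ("a1", "a2", "log10_ec50", "hill")
        dof = max(len(y) - 4, 1)
        sigma2 = rss / dof
        try:
            cov = sigma2 * np.linalg.inv(sol.jac.T @ sol.jac)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(4, np.nan)
        return DoseResponseResults(
            a1=float(a1),
            a2=float(a2),
            log10_ec50=float(lx0),
            hill=float(hill),
            bse=dict(zip(names, se.astype(float))),
            rss=float(rss),
            n_obs=len(y),
            converged=True,
            n_starts_tried=n_tried,
        )


def fit_dose_resp(
    data: DoseResponseData, start: dict[str, float] | None = None
) -> DoseResponseResults:
    """Functional wrapper around :class:`DoseResponseModel`."""
    return DoseResponseModel(data).fit(start=start)


def predict_response(
    fit: DoseResponseResults, concentration: np.ndarray | float
) -> np.ndarray | float:
    """Evaluate a fitted 4PL at positive concentration(s)."""
    return fit.predict(concentration)
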