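"""1-D diffusion–production model of a secreted redox shuttle.

A biofilm streak secreting a redox mediator into a gel is modelled as a
line source in one spatial dimension:

    ∂C/∂t = D ∂²C/∂x² + P(x)

with C the shuttle concentration (mol cm⁻³), D the gel diffusion
coefficient (cm² s⁻¹) and P(x) a non-negative volumetric production term
(mol cm⁻³ s⁻¹).  The domain is large (default 10 cm) relative to the
diffusion length so that the fixed far-field Dirichlet boundaries
(C = 0) do not influence the solution near the source.

The solver is an explicit forward-time centred-space (FTCS) scheme with
the production term added as ``P·dt`` each step.  FTCS is conditionally
stable: ``dt ≤ dx²/(2D)``; the solver refuses to run with a timestep above
that bound rather than go silently unstable.

For verification, :func:`plane_source_reference` provides the closed-form
solution for a continuous plane source in an infinite medium, against
which the solver converges at second order in dx.

Internal units are cm, s and mol cm⁻³ throughout; conversion to nM happens
only at reporting boundaries via :func:`mol_per_cm3_to_nM`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc

__all__ = [
    "DiffusionConfigError",
    "RectangularSource",
    "DiffusionConfig",
    "DiffusionModel",
    "ConcentrationField",
    "max_stable_timestep",
    "solve",
    "total_mass",
    "plane_source_reference",
    "mol_per_cm3_to_nM",
    "AUTO_DT_SAFETY",
]

#: "auto" timesteps use this fraction of the FTCS stability bound.
AUTO_DT_SAFETY = 0.4


class DiffusionConfigError(ValueError):
    """Invalid diffusion model configuration."""


def mol_per_cm3_to_nM(c: np.ndarray | float) -> np.ndarray | float:
    """Convert mol cm⁻³ to nM (mol cm⁻³ × 10³ → mol L⁻¹, × 10⁹ → nM)."""
    return np.asarray(c) * 1e12 if isinstance(c, np.ndarray) else c * 1e12


@dataclass(frozen=True)
class RectangularSource:
    """A biofilm streak as a rectangular volumetric source profile.

    The streak is characterised by its centre and width on the 1-D axis,
    a volumetric cell density, and a per-cell secretion rate; the
    volumetric production inside the streak is their product.  Results
    scale linearly with ``cell_density × per_cell_rate``, so these two are
    not separately identifiable from a concentration profile.
    """

    center: float  # cm
    width: float = 0.1  # cm
    cell_density: float = 1e9  # cells cm⁻³
    per_cell_rate: float = 4e-23  # mol cell⁻¹ s⁻¹

    def volumetric_rate(self) -> float:
        """Production rate inside the streak, mol cm⁻³ s⁻¹."""
        return self.cell_density * self.per_cell_rate

    def profile(self, positions: np.ndarray) -> np.ndarray:
        half = self.width / 2.0
        inside = np.abs(positions - self.center) <= half + 1e-12
        return np.where(inside, self.volumetric_rate(), 0.0)


@dataclass
class DiffusionConfig:
    """Configuration of the 1-D diffusion–production model.

    Parameters
    ----------
    domain_length : cm (default 10, large enough to keep the far-field
        boundaries inert at desk-scale simulation times)
    dx : cm, grid spacing; ``domain_length/dx`` must be a whole number of
        cells (default 0.01 → 1001 nodes on the 10 cm domain)
    dt : s, or ``"auto"`` for ``AUTO_DT_SAFETY × dx²/(2D)``
    t_end : s, total simulated time
    diffusion_coefficient : cm² s⁻¹
    source : a :class:`RectangularSource`, an explicit per-node array of
        volumetric rates (mol cm⁻³ s⁻¹), or None for no production
    boundary_value, initial_value : mol cm⁻³ (defaults 0)
    output_times : s, times at which profiles are recorded (snapped to the
        nearest timestep); defaults to 25 evenly spaced times plus t_end
    """

    t_end: float
    diffusion_coefficient: float
    domain_length: float = 10.0
    dx: float = 0.01
    dt: float | str = "auto"
    source: RectangularSource | np.ndarray | None = None
    boundary_value: float = 0.0
    initial_value: float = 0.0
    output_times: list[float] | None = None

    def __post_init__(self) -> None:
        if self.diffusion_coefficient <= 0:
            raise DiffusionConfigError(
                f"D must be > 0, got {self.diffusion_coefficient}"
            )
        if self.dx <= 0:
            raise DiffusionConfigError(f"dx must be > 0, got {self.dx}")
        if self.domain_length <= 0:
            raise DiffusionConfigError("domain_length must be > 0")
        if self.t_end <= 0:
            raise DiffusionConfigError("t_end must be > 0")
        n_cells = self.domain_length / self.dx
        if abs(n_cells - round(n_cells)) > 1e-9 * max(1.0, n_cells):
            raise DiffusionConfigError(
                f"domain_length/dx = {n_cells} is not a whole number of cells"
            )

    @property
    def n_nodes(self) -> int:
        return int(round(self.domain_length / self.dx)) + 1

    @property
    def positions(self) -> np.ndarray:
        return np.linspace(0.0, self.domain_length, self.n_nodes)

    def source_profile(self) -> np.ndarray:
        """Per-node volumetric production rates, validated non-negative."""
        x = self.positions
        if self.source is None:
            p = np.zeros_like(x)
        elif isinstance(self.source, RectangularSource):
            s = self.source
            if s.width < 0 or s.cell_density < 0 or s.per_cell_rate < 0:
                raise DiffusionConfigError("source parameters must be >= 0")
            if s.center - s.width / 2 < 0 or s.center + s.width / 2 > self.domain_length:
                raise DiffusionConfigError("source extends outside the domain")
            p = s.profile(x)
        else:
            p = np.asarray(self.source, dtype=float)
            if p.shape != x.shape:
                raise DiffusionConfigError(
                    f"source array length {p.shape} does not match grid "
                    f"({x.shape})"
                )
        if np.any(p < 0):
            raise DiffusionConfigError("source profile must be non-negative")
        return p

    def resolved_dt(self) -> float:
        bound = max_stable_timestep(self)
        if isinstance(self.dt, str):
            if self.dt != "auto":
                raise DiffusionConfigError(f"dt must be a number or 'auto', got {self.dt!r}")
            return AUTO_DT_SAFETY * bound
        dt = float(self.dt)
        if dt <= 0:
            raise DiffusionConfigError(f"dt must be > 0, got {dt}")
        if dt > bound * (1 + 1e-12):
            raise DiffusionConfigError(
                f"dt = {dt} s exceeds the FTCS stability bound dx²/(2D) = "
                f"{bound} s; refusing to run an unstable scheme"
            )
        return dt


def max_stable_timestep(config: DiffusionConfig) -> float:
    """FTCS stability bound dx²/(2D) in seconds."""
    return config.dx**2 / (2.0 * config.diffusion_coefficient)


@dataclass
class ConcentrationField:
    """Result of a diffusion–production simulation.

    ``values[i, j]`` is the concentration (mol cm⁻³) at ``times[i]``,
    ``positions[j]``.
    """

    positions: np.ndarray  # cm
    times: np.ndarray  # s, strictly increasing
    values: np.ndarray  # mol cm⁻³, shape (n_times, n_nodes)
    config: DiffusionConfig | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.values.shape != (len(self.times), len(self.positions)):
            raise ValueError("values shape does not match times × positions")

    def to_nM(self) -> np.ndarray:
        """Concentration values converted to nM."""
        return mol_per_cm3_to_nM(self.values)

    def profile_at(self, time: float) -> np.ndarray:
        """Profile (mol cm⁻³) at the recorded time closest to ``time``."""
        i = int(np.argmin(np.abs(self.times - time)))
        return self.values[i]

    def summary(self) -> dict:
        """Peak concentration (nM), its time and position, mass residual."""
        peak_idx = np.unravel_index(np.argmax(self.values), self.values.shape)
        out = {
            "peak_nM": float(mol_per_cm3_to_nM(self.values[peak_idx])),
            "peak_time_s": float(self.times[peak_idx[0]]),
            "peak_position_cm": float(self.positions[peak_idx[1]]),
            "final_time_s": float(self.times[-1]),
        }
        if self.config is not None:
            p = self.config.source_profile()
            expected = np.trapezoid(p, self.positions) * self.times[-1]
            actual = total_mass(self, len(self.times) - 1)
            out["mass_balance_residual"] = (
                float((actual - expected) / expected) if expected > 0 else 0.0
            )
        return out


class DiffusionModel:
    """Explicit finite-difference model for the diffusion–production PDE.

    Thin object wrapper over :func:`solve`; ``DiffusionModel(config).solve()``
    returns a :class:`ConcentrationField`.
    """

    def __init__(self, config: DiffusionConfig):
        self.config = config

    def solve(self) -> ConcentrationField:
        return solve(self.config)


def solve(config: DiffusionConfig) -> ConcentrationField:
    """Integrate the model with the FTCS scheme.

    Interior update: centred second difference for diffusion plus ``P·dt``;
    endpoint nodes are pinned to ``boundary_value`` throughout.  Raises
    :class:`DiffusionConfigError` if the requested dt exceeds the stability
    bound.
    """
    dt0 = config.resolved_dt()
    x = config.positions
    p = config.source_profile()
    D = config.diffusion_coefficient

    # land exactly on t_end: shrink dt to an integer number of steps
    n_steps = max(1, int(np.ceil(config.t_end / dt0 - 1e-9)))
    dt = config.t_end / n_steps
    r = D * dt / config.dx**2
    if config.output_times is None:
        out_times = list(np.linspace(0, config.t_end, 26)[1:])
    else:
        out_times = sorted(t for t in config.output_times if 0 < t <= config.t_end)
        if not out_times:
            raise DiffusionConfigError("output_times contains no time in (0, t_end]")
    out_steps = sorted({max(1, int(round(t / dt))) for t in out_times})
    out_steps = [s for s in out_steps if s <= n_steps]
    if out_steps[-1] != n_steps:
        out_steps.append(n_steps)

    c = np.full_like(x, float(config.initial_value))
    c[0] = c[-1] = config.boundary_value
    frames = np.empty((len(out_steps), len(x)))
    times = np.empty(len(out_steps))

    next_out = 0
    p_dt = p * dt
    for step in range(1, n_steps + 1):
        c[1:-1] += r * (c[2:] - 2.0 * c[1:-1] + c[:-2]) + p_dt[1:-1]
        c[0] = c[-1] = config.boundary_value
        if next_out < len(out_steps) and step == out_steps[next_out]:
            frames[next_out] = c
            times[next_out] = step * dt
            next_out += 1

    return ConcentrationField(positions=x, times=times, values=frames, config=config)


def total_mass(fld: ConcentrationField, time_index: int) -> float:
    """Trapezoidal integral of C over x at one recorded time.

    Units: mol cm⁻² (mol per unit cross-sectional area of the 1-D domain).
    """
    if not -len(fld.times) <= time_index < len(fld.times):
        raise IndexError(
            f"time_index {time_index} out of range for {len(fld.times)} frames"
        )
    return float(np.trapezoid(fld.values[time_index], fld.positions))


def plane_source_reference(q: float, D: float, x: float, t: float) -> float:
    """Closed-form concentration from a continuous plane source at x = 0.

    For a plane source of constant areal strength ``q`` (mol cm⁻² s⁻¹,
    split between both directions) switched on at t = 0 in an infinite
    medium, the time-integral of the instantaneous-source Green's function
    gives

        C(x, t) = q [ √(t/(πD)) e^(−x²/4Dt) − (|x|/2D) erfc(|x|/√(4Dt)) ]

    which at x = 0 reduces to ``q √(t/(πD))``.  Used as the analytical
    oracle for the finite-difference solver.
    """
    if D <= 0:
        raise ValueError(f"D must be > 0, got {D}")
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if t == 0:
        return 0.0
    ax = abs(x)
    return q * (
        np.sqrt(t / (np.pi * D)) * np.exp(-(ax**2) / (4 * D * t))
        - ax / (2 * D) * erfc(ax / np.sqrt(4 * D * t))
    )
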