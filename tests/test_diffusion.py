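"""Diffusion–production solver and its analytical oracle."""

import numpy as np
import pytest
from scipy.integrate import quad

from shuttlekit import diffusion as dif

from conftest import plane_source_config


def oracle_error(dx: float, t_end: float = 1e4, D: float = 5e-6, q: float = 1e-12):
    """Relative L∞ error of the solver vs the plane-source closed form,
    excluding the source cell."""
    cfg, centre = plane_source_config(dx=dx, t_end=t_end, D=D, q=q)
    fld = dif.solve(cfg)
    x = fld.positions - fld.positions[centre]
    ref = np.array([dif.plane_source_reference(q, D, xi, t_end) for xi in x])
    mask = np.ones(len(x), dtype=bool)
    mask[centre] = False
    return float(np.max(np.abs(fld.values[-1][mask] - ref[mask])) / ref.max())


class TestStability:
    @pytest.mark.parametrize(
        "dx, D, expected",
        [(0.01, 5e-6, 10.0), (0.1, 5e-6, 1000.0), (0.01, 1e-5, 5.0)],
    )
    def test_ftcs_bound(self, dx, D, expected):
        cfg = dif.DiffusionConfig(t_end=1.0, diffusion_coefficient=D, dx=dx)
        assert dif.max_stable_timestep(cfg) == pytest.approx(expected)

    def test_doubling_D_halves_bound(self):
        one = dif.DiffusionConfig(t_end=1.0, diffusion_coefficient=5e-6)
        two = dif.DiffusionConfig(t_end=1.0, diffusion_coefficient=1e-5)
        assert dif.max_stable_timestep(one) == pytest.approx(
            2 * dif.max_stable_timestep(two)
        )

    def test_auto_dt_uses_safety_factor(self):
        cfg = dif.DiffusionConfig(t_end=1.0, diffusion_coefficient=5e-6)
        assert cfg.resolved_dt() == pytest.approx(
            dif.AUTO_DT_SAFETY * dif.max_stable_timestep(cfg)
        )

    def test_unstable_dt_refused(self):
        cfg = dif.DiffusionConfig(
            t_end=100.0, diffusion_coefficient=5e-6, dt=11.0
        )
        with pytest.raises(dif.DiffusionConfigError, match="stability"):
            dif.solve(cfg)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"diffusion_coefficient": 0.0},
            {"diffusion_coefficient": -1e-6},
            {"diffusion_coefficient": 5e-6, "dx": 0.0},
            {"diffusion_coefficient": 5e-6, "dx": 0.03},  # 10/0.03 not whole
            {"diffusion_coefficient": 5e-6, "t_end": 0.0},
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(dif.DiffusionConfigError):
            dif.DiffusionConfig(t_end=kwargs.pop("t_end", 1.0), **kwargs)

    def test_source_outside_domain(self):
        cfg = dif.DiffusionConfig(
            t_end=1.0,
            diffusion_coefficient=5e-6,
            source=dif.RectangularSource(center=0.01, width=0.2),
        )
        with pytest.raises(dif.DiffusionConfigError, match="outside"):
            cfg.source_profile()


class TestSolve:
    def test_zero_source_stays_zero(self):
        cfg = dif.DiffusionConfig(
            t_end=100.0, diffusion_coefficient=5e-6, dx=0.1
        )
        fld = dif.solve(cfg)
        assert np.all(fld.values == 0.0)

    def test_uniform_source_grows_linearly(self):
        # before boundary influence, C = P·t at the centre
        n = dif.DiffusionConfig(
            t_end=100.0, diffusion_coefficient=5e-6, dx=0.1
        ).n_nodes
        p = np.full(n, 1e-12)
        cfg = dif.DiffusionConfig(
            t_end=100.0,
            diffusion_coefficient=5e-6,
            dx=0.1,
            source=p,
            output_times=[100.0],
        )
        fld = dif.solve(cfg)
        centre = n // 2
        assert fld.values[-1][centre] == pytest.approx(1e-10, rel=1e-9)

    def test_plane_source_matches_closed_form(self):
        # continuous plane source: centre value q·sqrt(t/(πD)), profile
        # within 2% relative L∞ excluding the source cell
        assert oracle_error(dx=0.01) < 0.02

    def test_centre_value_against_closed_form(self):
        cfg, centre = plane_source_config(dx=0.01)
        fld = dif.solve(cfg)
        assert fld.values[-1][centre] == pytest.approx(2.523e-8, rel=0.02)

    def test_second_order_convergence(self):
        ratio = oracle_error(dx=0.02) / oracle_error(dx=0.01)
        assert 3.0 <= ratio <= 5.0

    def test_symmetry(self):
        cfg, _ = plane_source_config(dx=0.02, t_end=2000.0)
        fld = dif.solve(cfg)
        final = fld.values[-1]
        assert np.allclose(final, final[::-1], rtol=1e-12, atol=final.max() * 1e-13)

    def test_positivity(self):
        cfg, _ = plane_source_config(dx=0.02, t_end=5000.0)
        fld = dif.solve(cfg)
        assert np.all(fld.values >= 0.0)

    def test_boundaries_pinned(self):
        cfg, _ = plane_source_config(dx=0.02, t_end=5000.0)
        fld = dif.solve(cfg)
        assert np.all(fld.values[:, 0] == 0.0)
        assert np.all(fld.values[:, -1] == 0.0)


class TestTotalMass:
    def test_zero_field(self):
        fld = dif.ConcentrationField(
            positions=np.linspace(0, 1, 11),
            times=np.array([1.0]),
            values=np.zeros((1, 11)),
        )
        assert dif.total_mass(fld, 0) == 0.0

    def test_uniform_field(self):
        fld = dif.ConcentrationField(
            positions=np.linspace(0, 2.0, 21),
            times=np.array([1.0]),
            values=np.full((1, 21), 3.0),
        )
        assert dif.total_mass(fld, 0) == pytest.approx(6.0)

    def test_index_out_of_range(self):
        fld = dif.ConcentrationField(
            positions=np.linspace(0, 1, 11),
            times=np.array([1.0]),
            values=np.zeros((1, 11)),
        )
        with pytest.raises(IndexError):
            dif.total_mass(fld, 3)

    def test_mass_balance_tracks_source_integral(self):
        # while the front is far from the boundary, mass = q·t within 0.5%
        q, t_end = 1e-12, 1e4
        cfg, _ = plane_source_config(q=q, t_end=t_end)
        fld = dif.solve(cfg)
        assert fld.values[-1][1] < 1e-6 * fld.values[-1].max()  # pre-boundary
        assert dif.total_mass(fld, -1) == pytest.approx(q * t_end, rel=0.005)


class TestPlaneSourceReference:
    def test_centre_closed_form(self):
        assert dif.plane_source_reference(1e-12, 5e-6, 0.0, 1e4) == pytest.approx(
            2.523e-8, rel=1e-3
        )

    def test_zero_time(self):
        for x in (0.0, 0.1, -1.0):
            assert dif.plane_source_reference(1e-12, 5e-6, x, 0.0) == 0.0

    def test_monotone_decreasing_in_distance(self):
        xs = np.linspace(0, 1.0, 50)
        vals = [dif.plane_source_reference(1e-12, 5e-6, x, 1e4) for x in xs]
        assert np.all(np.diff(vals) < 0)

    def test_even_in_x(self):
        a = dif.plane_source_reference(1e-12, 5e-6, 0.3, 1e4)
        b = dif.plane_source_reference(1e-12, 5e-6, -0.3, 1e4)
        assert a == b

    @pytest.mark.parametrize("x", [0.0, 0.05, 0.2])
    def test_against_quadrature_of_greens_function(self, x):
        # independent oracle: integrate the instantaneous plane-source
        # kernel over emission time; substituting u = sqrt(t − tau)
        # removes the integrable endpoint singularity:
        # ∫₀ᵗ G dτ = q/√(πD) ∫₀^√t exp(−x²/(4Du²)) du
        q, D, t = 1e-12, 5e-6, 1e4

        def kernel(u):
            if u == 0.0:
                return 0.0 if x != 0 else 1.0
            return np.exp(-(x**2) / (4 * D * u**2))

        integral, _ = quad(kernel, 0, np.sqrt(t))
        expected = q / np.sqrt(np.pi * D) * integral
        assert dif.plane_source_reference(q, D, x, t) == pytest.approx(
            expected, rel=1e-6
        )

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            dif.plane_source_reference(1e-12, 0.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            dif.plane_source_reference(1e-12, 5e-6, 0.0, -1.0)


class TestUnits:
    def test_mol_per_cm3_to_nM(self):
        # 1e-12 mol cm⁻³ = 1e-9 mol L⁻¹ = 1 nM
        assert dif.mol_per_cm3_to_nM(1e-12) == pytest.approx(1.0)

    def test_field_to_nM(self):
        fld = dif.ConcentrationField(
            positions=np.linspace(0, 1, 3),
            times=np.array([1.0]),
            values=np.full((1, 3), 4e-13),
        )
        assert fld.to_nM() == pytest.approx(np.full((1, 3), 0.4))
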