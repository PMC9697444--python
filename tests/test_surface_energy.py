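import itertools
import math

import numpy as np
import pytest
from scipy.optimize import least_squares

from pbrsurf import (
    AngleSet,
    ProbeLiquid,
    delta_g_cohesion,
    forward_angles,
    gamma_lw_from_apolar,
    solve_components,
)
from pbrsurf.errors import InputError, SolverError

from conftest import random_physical_components
from reference_tables import ALL_ROWS


class TestGammaLwFromApolar:
    @pytest.mark.parametrize(
        "theta_d, expected",
        [
            (0.0, 50.8),  # complete wetting: solid LW equals the liquid's
            (38.0, 50.8 * (1 + math.cos(math.radians(38))) ** 2 / 4),  # = 40.58
            (180.0 - 1e-9, 0.0),
        ],
    )
    def test_closed_form(self, theta_d, expected, liquids):
        got = gamma_lw_from_apolar(theta_d, liquids["diiodomethane"])
        assert got == pytest.approx(expected, abs=1e-6)

    def test_hand_value_at_38_degrees(self, liquids):
        assert gamma_lw_from_apolar(38.0, liquids["diiodomethane"]) == pytest.approx(40.6, abs=0.05)

    def test_polar_liquid_rejected(self, liquids):
        with pytest.raises(InputError):
            gamma_lw_from_apolar(38.0, liquids["water"])


class TestSolveComponents:
    def test_glass_reproduces_published_energy(self, liquids):
        res = solve_components(AngleSet("GS", 25, 26, 38), liquids)
        assert res.gamma_s == pytest.approx(50.9, abs=0.5)
        assert res.delta_g_coh == pytest.approx(30.4, abs=0.5)
        assert res.root_sign_flags == (False, False)

    def test_polycarbonate_needs_magnitude_convention(self, liquids):
        # strongly monopolar polymer: the acid square root solves negative
        res = solve_components(AngleSet("PC", 78, 70, 26), liquids)
        assert res.root_sign_flags[0] is True
        assert res.gamma_s == pytest.approx(57.1, abs=0.5)
        assert res.delta_g_coh == pytest.approx(-24.7, abs=0.5)

    def test_result_invariants(self, liquids):
        res = solve_components(AngleSet("GS", 25, 26, 38), liquids)
        assert res.gamma_ab == pytest.approx(2 * math.sqrt(res.gamma_plus * res.gamma_minus), abs=1e-9)
        assert res.gamma_s == pytest.approx(res.gamma_lw + res.gamma_ab, abs=1e-9)

    def test_missing_liquid_errors(self, liquids):
        with pytest.raises(InputError):
            solve_components(AngleSet("GS", 25, 26, 38), {"water": liquids["water"]})

    def test_degenerate_polar_pair_raises(self, liquids):
        # second polar liquid with acid/base roots proportional to water's
        fake = {
            "water": liquids["water"],
            "formamide": ProbeLiquid("formamide", 42.75, 30.0, 6.375, 6.375),
            "diiodomethane": liquids["diiodomethane"],
        }
        with pytest.raises(SolverError, match="singular|degenerate"):
            solve_components(AngleSet("X", 50, 50, 40), fake)


class TestForwardAngles:
    def test_self_wetting_apolar(self, liquids):
        angles = forward_angles((50.8, 0.0, 0.0), liquids)
        assert angles.theta_d == pytest.approx(0.0, abs=1e-6)

    def test_water_like_solid_fully_wetted_by_water(self, liquids):
        angles = forward_angles((21.8, 25.5, 25.5), liquids)
        assert angles.theta_w == pytest.approx(0.0, abs=1e-6)

    def test_inverse_of_inverse_identity(self, liquids):
        res = solve_components(AngleSet("GS", 25, 26, 38), liquids)
        angles = forward_angles(res, liquids)
        assert angles.theta_w == pytest.approx(25.0, abs=1e-6)
        assert angles.theta_f == pytest.approx(26.0, abs=1e-6)
        assert angles.theta_d == pytest.approx(38.0, abs=1e-6)

    def test_superwetting_components_clamp_to_zero_angle(self, liquids):
        # work of adhesion beyond 2*gamma_L means complete spreading
        angles = forward_angles((200.0, 0.0, 0.0), liquids)
        assert angles.theta_d == 0.0
        angles = forward_angles((21.8, 25.5, 25.5), liquids)  # water-like solid
        assert angles.theta_f == 0.0  # formamide spreads too

    def test_negative_components_rejected(self, liquids):
        with pytest.raises(InputError):
            forward_angles((40.0, -1.0, 5.0), liquids)


class TestRoundTrip:
    def test_thousand_random_component_sets_recover_exactly(self, rng, liquids):
        """Noise-free forward map then inversion is the identity to 1e-6."""
        for comps in random_physical_components(rng, 1000, liquids):
            angles = forward_angles(comps, liquids)
            res = solve_components(angles, liquids)
            assert res.gamma_lw == pytest.approx(comps[0], abs=1e-6)
            assert res.gamma_plus == pytest.approx(comps[1], abs=1e-6)
            assert res.gamma_minus == pytest.approx(comps[2], abs=1e-6)

    def test_agrees_with_nonlinear_least_squares_oracle(self, rng, liquids):
        """Independent oracle: minimize the three Young-Dupre residuals over
        (gamma_lw, a, b) >= 0; must coincide with the linear solve whenever
        no negative roots occur."""

        def residuals(x, angles):
            glw, a, b = x
            out = []
            for liq, theta in (
                (liquids["water"], angles.theta_w),
                (liquids["formamide"], angles.theta_f),
                (liquids["diiodomethane"], angles.theta_d),
            ):
                lhs = liq.gamma_total * (1 + math.cos(math.radians(theta)))
                rhs = 2 * (
                    math.sqrt(glw * liq.gamma_lw)
                    + a * math.sqrt(liq.gamma_minus)
                    + b * math.sqrt(liq.gamma_plus)
                )
                out.append(lhs - rhs)
            return out

        for comps in random_physical_components(rng, 40, liquids):
            angles = forward_angles(comps, liquids)
            res = solve_components(angles, liquids)
            if any(res.root_sign_flags):
                continue
            fit = least_squares(
                residuals, x0=[30.0, 1.0, 3.0], bounds=([0, 0, 0], np.inf), args=(angles,)
            )
            glw, a, b = fit.x
            assert res.gamma_lw == pytest.approx(glw, abs=1e-5)
            assert res.gamma_plus == pytest.approx(a * a, abs=1e-4)
            assert res.gamma_minus == pytest.approx(b * b, abs=1e-4)


class TestDeltaGCohesion:
    def test_water_like_solid_has_zero_cohesion_energy(self, water):
        # gamma_sw vanishes by symmetry when the solid's components equal water's
        from pbrsurf import SurfaceEnergyResult

        res = SurfaceEnergyResult(
            gamma_lw=21.8,
            gamma_plus=25.5,
            gamma_minus=25.5,
            gamma_ab=51.0,
            gamma_s=72.8,
            delta_g_coh=float("nan"),
        )
        assert delta_g_cohesion(res, water) == pytest.approx(0.0, abs=1e-9)

    def test_decreases_as_electron_donor_shrinks(self, liquids, water):
        # lowering gamma_minus with other components fixed makes the surface
        # more hydrophobic
        from pbrsurf import SurfaceEnergyResult

        values = []
        for gm in (50.0, 30.0, 15.0, 5.0, 0.5):
            res = SurfaceEnergyResult(
                gamma_lw=40.0,
                gamma_plus=0.5,
                gamma_minus=gm,
                gamma_ab=2 * math.sqrt(0.5 * gm),
                gamma_s=40.0 + 2 * math.sqrt(0.5 * gm),
                delta_g_coh=float("nan"),
            )
            values.append(delta_g_cohesion(res, water))
        assert all(a > b for a, b in zip(values, values[1:]))


class TestPublishedTableRegression:
    """The printed derived quantities must be attainable from the printed
    angles given their rounding to 1 degree: the printed value has to lie in
    the interval swept by +/-0.5 degree perturbations of each angle (with
    0.06 slack for the printed values' own rounding to 0.1)."""

    GRID = (-0.5, 0.0, 0.5)
    SLACK = 0.06

    @pytest.mark.parametrize("row", ALL_ROWS, ids=lambda r: r.surface_id)
    def test_row(self, row, liquids, water):
        gs, dg, tau = [], [], []
        for dw, df_, dd in itertools.product(self.GRID, repeat=3):
            aset = AngleSet(row.surface_id, row.theta_w + dw, row.theta_f + df_, row.theta_d + dd)
            res = solve_components(aset, liquids)
            gs.append(res.gamma_s)
            dg.append(res.delta_g_coh)
            tau.append(water.gamma_total * math.cos(math.radians(aset.theta_w)))
        assert min(gs) - self.SLACK <= row.gamma_s <= max(gs) + self.SLACK
        assert min(dg) - self.SLACK <= row.delta_g_coh <= max(dg) + self.SLACK
        if not row.skip_tau0:
            assert min(tau) - self.SLACK <= row.tau0 <= max(tau) + self.SLACK

    @pytest.mark.parametrize(
        "row", [r for r in ALL_ROWS if r.tight_gs or r.tight_dg], ids=lambda r: r.surface_id
    )
    def test_tight_rows_reproduce_within_half_mj(self, row, liquids):
        res = solve_components(AngleSet(row.surface_id, row.theta_w, row.theta_f, row.theta_d), liquids)
        if row.tight_gs:
            assert res.gamma_s == pytest.approx(row.gamma_s, abs=0.5)
        if row.tight_dg:
            assert res.delta_g_coh == pytest.approx(row.delta_g_coh, abs=0.5)
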