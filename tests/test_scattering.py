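"""Debye and orientational-grid curves, Guinier/R_XS/Kratky analyses."""

import numpy as np
import pytest

import igsas
from igsas.scattering import (
    ScatteringCurve,
    cross_section_fits,
    debye_curve,
    golden_spiral_directions,
    guinier_fit,
    kratky_dimensionless,
    orientational_grid_curve,
)
from tests.conftest import bare_model


class TestDebye:
    def test_two_beads_forward_scattering(self):
        m = bare_model(np.array([[0.0, 0, 0], [2.5, 0, 0]]))
        c = debye_curve(m, np.array([0.0]))
        assert c.i[0] == pytest.approx(4.0)     # (sum f)^2

    def test_two_beads_closed_form(self):
        m = bare_model(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        c = debye_curve(m, np.array([np.pi]))
        assert c.i[0] == pytest.approx(2.0, abs=1e-12)  # 2(1 + sin(pi)/pi)

    def test_sphere_form_factor(self):
        # closed-form solid-sphere oracle at the sample's equivalent radius,
        # QR <= 4; the comparison is on the coherent part (the flat
        # self-term floor, (1-A^2)/N, is a bead-discretization artefact)
        from igsas.models import lattice_ellipsoid
        pts = lattice_ellipsoid((3.0, 3.0, 3.0), 0.3)
        m = bare_model(pts)
        n = m.n_sites
        assert n >= 2000
        r_eff = m.radius_of_gyration() / np.sqrt(3.0 / 5.0)
        q = np.linspace(0.05, 4.0 / r_eff, 100)
        c = debye_curve(m, q, bin_width=0.005)
        x = q * r_eff
        ff = (3.0 * (np.sin(x) - x * np.cos(x)) / x ** 3) ** 2
        coherent = (c.i - n) / (c.i[0] - n)
        assert np.abs(coherent / ff - 1.0).max() < 0.02

    def test_binned_matches_exact(self, small_cloud):
        q = np.linspace(0.0, 1.5, 40)
        exact = debye_curve(small_cloud, q)
        binned = debye_curve(small_cloud, q, bin_width=0.01)
        assert np.abs(binned.i / exact.i - 1.0).max() < 1e-3

    def test_nonnegative_and_maximal_at_zero(self):
        rng = np.random.default_rng(2)
        q = np.linspace(0.0, 2.0, 60)
        for _ in range(10):
            m = bare_model(rng.normal(scale=3.0, size=(40, 3)))
            c = debye_curve(m, q)
            assert np.all(c.i >= -1e-9)
            assert np.argmax(c.i) == 0


class TestOrientationalGrid:
    def test_single_bead_flat(self):
        m = bare_model(np.array([[1.0, -2.0, 0.5]]))
        c = orientational_grid_curve(m, np.linspace(0, 1.5, 10), 1)
        assert np.allclose(c.i, 1.0)

    def test_grid_is_quasi_uniform_unit_sphere(self):
        d = golden_spiral_directions(500)
        assert np.allclose(np.linalg.norm(d, axis=1), 1.0)
        assert np.linalg.norm(d.mean(axis=0)) < 0.01

    def test_agrees_with_debye(self, small_cloud):
        q = np.linspace(0.01, 1.5, 30)
        ref = debye_curve(small_cloud, q)
        grid = orientational_grid_curve(small_cloud, q, 1000)
        assert np.abs(grid.i / ref.i - 1.0).max() < 0.005

    def test_rotation_isotropy(self, small_cloud):
        from scipy.spatial.transform import Rotation
        q = np.linspace(0.01, 1.5, 20)
        a = orientational_grid_curve(small_cloud, q, 1000)
        rot = Rotation.from_euler("zyx", [0.7, -0.4, 1.1]).as_matrix()
        m2 = small_cloud.with_positions(small_cloud.positions @ rot.T)
        b = orientational_grid_curve(m2, q, 1000)
        assert np.abs(a.i / b.i - 1.0).max() < 0.005

    def test_error_decreases_with_orientations_on_average(self, small_cloud):
        q = np.linspace(0.2, 1.5, 15)
        ref = debye_curve(small_cloud, q).i
        errs = []
        for n in (50, 100, 200, 400, 800):
            g = orientational_grid_curve(small_cloud, q, n).i
            errs.append(np.mean(np.abs(g / ref - 1.0)))
        # monotone decrease on average over the doublings
        assert np.mean(np.diff(np.log(errs))) < 0


class TestGuinier:
    def test_exact_guinier_curve_recovered(self):
        q = np.linspace(0.01, 0.5, 50)
        c = ScatteringCurve(q, 7.0 * np.exp(-(q * 2.3) ** 2 / 3.0))
        res = guinier_fit(c, (q[0], q[-1]))
        assert res.rg == pytest.approx(2.3, abs=1e-9)
        assert res.i0 == pytest.approx(7.0, rel=1e-9)
        assert res.valid

    def test_sphere_rg_closed_form(self, sphere_2000):
        rg_true = np.sqrt(3.0 / 5.0) * 3.0        # sqrt(3/5) R
        q = np.linspace(0.05, 1.0 / rg_true, 40)
        c = debye_curve(sphere_2000, q, bin_width=0.005)
        res = guinier_fit(c, (q[0], q[-1]))
        assert res.rg == pytest.approx(rg_true, rel=0.02)
        # the direct second moment of the bead coordinates is the oracle
        assert res.rg == pytest.approx(sphere_2000.radius_of_gyration(), rel=0.02)

    def test_window_without_points_raises(self):
        q = np.linspace(0.5, 1.0, 30)
        c = ScatteringCurve(q, np.exp(-q ** 2))
        with pytest.raises(ValueError, match="fewer than 3"):
            guinier_fit(c, (0.10, 0.22))

    def test_positive_slope_flagged_not_nan_silent(self):
        q = np.linspace(0.1, 0.3, 10)
        c = ScatteringCurve(q, np.exp(+q ** 2))
        res = guinier_fit(c, (0.1, 0.3))
        assert not res.valid

    def test_recovers_coordinate_rg_for_random_models(self):
        # property: window with max(Q RG) <= 1.0 recovers the bead-level RG
        rng = np.random.default_rng(5)
        for _ in range(5):
            m = bare_model(rng.normal(scale=2.5, size=(150, 3)))
            rg = m.radius_of_gyration()
            q = np.linspace(0.02, 1.0 / rg, 30)
            res = guinier_fit(debye_curve(m, q), (q[0], q[-1]))
            assert res.rg == pytest.approx(rg, rel=0.02)


class TestCrossSection:
    def test_exact_synthetic_line(self):
        rxs = 1.41
        q = np.linspace(0.2, 1.2, 200)
        iq = np.exp(-(rxs ** 2) * q ** 2 / 2.0) / q    # so ln(IQ) is the line
        c = ScatteringCurve(q, iq)
        res = cross_section_fits(c, ((0.22, 0.28), (0.50, 1.10)))
        assert res.rxs1 == pytest.approx(1.410, abs=1e-6)
        assert res.rxs2 == pytest.approx(1.410, abs=1e-6)

    def test_long_rod_cross_section(self):
        # solid cylinder: R_XS = R/sqrt(2); fit where QL >> 1 (the
        # asymptote for L = 30 is only clean beyond Q ~ 0.8 nm^-1)
        from tests.conftest import lattice_rod
        rod = bare_model(lattice_rod())
        q = np.linspace(0.75, 1.5, 120)
        c = debye_curve(rod, q, bin_width=0.01)
        res = cross_section_fits(c, ((0.8, 1.2), (1.3, 1.45)))
        assert res.rxs1 == pytest.approx(1.0 / np.sqrt(2.0), rel=0.05)

    def test_overlapping_windows_rejected(self):
        q = np.linspace(0.1, 1.2, 100)
        c = ScatteringCurve(q, np.exp(-q ** 2))
        with pytest.raises(ValueError, match="disjoint"):
            cross_section_fits(c, ((0.2, 0.6), (0.5, 1.1)))


class TestKratky:
    def test_guinier_limit_peak_analytic(self):
        q = np.linspace(1e-4, 3.0, 6000)
        c = ScatteringCurve(q, 5.0 * np.exp(-(q * 1.0) ** 2 / 3.0))
        k = kratky_dimensionless(c, 1.0, 5.0)
        assert k.peak_x == pytest.approx(np.sqrt(3.0), abs=1e-4)
        assert k.peak_height == pytest.approx(3.0 / np.e, abs=1e-4)

    def test_scale_invariance(self, small_cloud):
        q = np.linspace(0.01, 1.5, 100)
        c = debye_curve(small_cloud, q)
        k1 = kratky_dimensionless(c, 2.0, c.i[0])
        k2 = kratky_dimensionless(c.with_intensity(2.0 * c.i), 2.0, 2.0 * c.i[0])
        assert np.allclose(k1.y, k2.y)
        assert k1.peak_x == k2.peak_x

    def test_extended_model_lacks_resolved_double_peak(self, igg3_truth,
                                                       compact_truth):
        # the long-hinge antibody shows no resolved Kratky peak structure
        # (its Fab/Fc regions scatter independently), while the compact
        # control keeps one clear globular-type maximum
        from scipy.signal import find_peaks

        def strong_peaks(gt):
            q = np.linspace(0.005, 1.5, 400)
            c = debye_curve(gt.model, q, bin_width=0.02)
            k = kratky_dimensionless(c, gt.true_rg, c.i[0])
            sel = k.x <= 8.0
            pk, _ = find_peaks(k.y[sel], prominence=0.1 * k.y[sel].max())
            return len(pk)

        assert strong_peaks(igg3_truth) == 0
        assert strong_peaks(compact_truth) == 1
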