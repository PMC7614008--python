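"""Sparse spiral-array design: seeds, grid snapping, beam patterns, fields."""

import numpy as np
import pytest

from ulm3d import array_design as ad
from ulm3d.beamform import GaussianPulse


class TestSpiralSeeds:
    def test_count_and_radius_bound(self):
        params = ad.SpiralParams()
        seeds = ad.generate_spiral_seeds(params)
        assert seeds.shape == (256, 2)
        assert np.all(np.hypot(seeds[:, 0], seeds[:, 1]) <= params.aperture_width / 2 + 1e-12)

    def test_single_seed_at_origin(self):
        seeds = ad.generate_spiral_seeds(ad.SpiralParams(n_seeds=1))
        assert np.allclose(seeds, 0.0)

    def test_deterministic(self):
        a = ad.generate_spiral_seeds(ad.SpiralParams())
        b = ad.generate_spiral_seeds(ad.SpiralParams())
        assert np.array_equal(a, b)

    def test_radial_cdf_matches_tukey_density(self):
        """Empirical radial CDF tracks the integral of r w(r) (KS < 0.05)."""
        params = ad.SpiralParams()
        R = params.aperture_width / 2
        seeds = ad.generate_spiral_seeds(params)
        radii = np.sort(np.hypot(seeds[:, 0], seeds[:, 1]))
        # independent oracle: numerical integration of the target density
        r = np.linspace(0, R, 20001)
        dens = r * ad.tukey_taper(r / R, params.tukey_ratio)
        cdf = np.cumsum((dens[1:] + dens[:-1]) / 2)
        cdf = np.concatenate(([0.0], cdf / cdf[-1]))
        target = np.interp(radii, r, cdf)
        emp_hi = np.arange(1, len(radii) + 1) / len(radii)
        emp_lo = np.arange(0, len(radii)) / len(radii)
        ks = max(np.abs(emp_hi - target).max(), np.abs(emp_lo - target).max())
        assert ks < 0.05

    def test_golden_angle_increment(self):
        seeds = ad.generate_spiral_seeds(ad.SpiralParams(n_seeds=8))
        ang = np.degrees(np.arctan2(seeds[1:, 1], seeds[1:, 0]))
        n = np.arange(1, 8)
        expected = (ad.GOLDEN_ANGLE_DEG * n + 180) % 360 - 180
        assert np.allclose(((ang - expected + 180) % 360) - 180, 0.0, atol=1e-9)

    @pytest.mark.parametrize("bad", [
        dict(n_seeds=0), dict(aperture_width=-1.0), dict(tukey_ratio=1.5),
    ])
    def test_invalid_params(self, bad):
        with pytest.raises(ValueError):
            ad.SpiralParams(**bad)


class TestSnapping:
    def test_aperture1_distinct_elements(self):
        grid = ad.MatrixGrid()
        seeds = ad.generate_spiral_seeds(ad.SpiralParams())
        sel = ad.snap_seeds_to_grid(seeds, grid)
        assert len(sel) == 256
        assert len(set(sel)) == 256

    def test_exclusion_yields_disjoint_union(self, layout):
        t = layout.table
        ap1 = set(t[t.aperture == 1].element_id)
        ap2 = set(t[t.aperture == 2].element_id)
        assert len(ap1) == 256 and len(ap2) == 256
        assert not ap1 & ap2
        assert len(ap1 | ap2) == 512

    def test_no_inactive_rows_selected(self, layout):
        active = layout.table[layout.table.aperture > 0]
        assert not active.row.isin([9, 18, 27]).any()

    def test_seed_on_element_center_selects_it(self):
        grid = ad.MatrixGrid()
        table = grid.element_table()
        target = table[table.available].iloc[100]
        sel = ad.snap_seeds_to_grid(np.array([[target.x_m, target.y_m]]), grid)
        assert sel[0] == target.element_id

    def test_capacity_error(self):
        grid = ad.MatrixGrid(n_cols=2, n_rows=2, inactive_rows=())
        seeds = np.zeros((5, 2))
        with pytest.raises(ValueError):
            ad.snap_seeds_to_grid(seeds, grid)

    def test_design_deterministic(self, layout):
        again = ad.design_apertures()
        assert again.table.equals(layout.table)


class TestArrayFactor:
    def test_single_element_flat(self, medium):
        pat = ad.beam_pattern_cut(np.zeros((1, 2)), medium.wavelength,
                                  np.linspace(-60, 60, 241))
        assert np.allclose(pat.magnitude, 1.0)

    def test_unity_at_steering(self, layout, medium):
        pat = ad.beam_pattern_cut(layout.positions(), medium.wavelength,
                                  np.array([-10.0, 0.0, 10.0]), steering_deg=10.0)
        assert pat.magnitude[2] == pytest.approx(1.0, abs=1e-12)

    def test_uniform_line_matches_dirichlet(self, medium):
        """32-element uniform line equals the closed-form Dirichlet kernel."""
        n, d = 32, 300e-6
        y = (np.arange(n) - (n - 1) / 2) * d
        pos = np.column_stack([np.zeros(n), y])
        ang = np.linspace(-90, 90, 1801)
        pat = ad.beam_pattern_cut(pos, medium.wavelength, ang)
        u = np.sin(np.deg2rad(ang))
        x = np.pi * d * u / medium.wavelength
        with np.errstate(invalid="ignore", divide="ignore"):
            dirichlet = np.abs(np.where(np.abs(np.sin(x)) < 1e-300, n,
                                        np.sin(n * x) / np.sin(x))) / n
        assert np.max(np.abs(pat.magnitude - dirichlet)) < 1e-9

    def test_empty_elements_error(self, medium):
        with pytest.raises(ValueError):
            ad.array_factor(np.zeros((0, 2)), medium.wavelength,
                            np.array([0.0]), np.array([0.0]))


class TestGratingLobes:
    def test_full_matrix_row_defect_lobe(self, medium):
        """Three blank rows put the top grating lobe near 8 degrees."""
        rows = np.array([r for r in range(35) if r + 1 not in (9, 18, 27)])
        y = (rows - 17.0) * 300e-6
        pos = np.column_stack([np.zeros_like(y), y])
        ang = np.arange(-30.0, 30.0001, 0.02)
        pat = ad.beam_pattern_cut(pos, medium.wavelength, ang)
        excl = ad.predicted_grating_angle(medium.wavelength, 9 * 300e-6) / 2
        lobes = ad.find_grating_lobes(pat, mainlobe_exclusion_deg=excl)
        assert abs(abs(lobes[0][0]) - 8.0) <= 1.5

    def test_dirichlet_lobes_below_first_sidelobe(self, medium):
        n, d = 32, 300e-6
        y = (np.arange(n) - (n - 1) / 2) * d
        pos = np.column_stack([np.zeros(n), y])
        ang = np.arange(-90.0, 90.0001, 0.02)
        pat = ad.beam_pattern_cut(pos, medium.wavelength, ang)
        lobes = ad.find_grating_lobes(pat, mainlobe_exclusion_deg=2.0)
        # uniform-aperture first sidelobe of the Dirichlet kernel
        assert lobes[0][1] <= 0.2172 + 1e-3

    def test_isolated_mainlobe_gives_empty_list(self):
        ang = np.linspace(-10, 10, 201)
        mag = np.zeros_like(ang)
        mag[100] = 1.0
        pat = ad.BeamPattern(ang, mag, 404e-6)
        assert ad.find_grating_lobes(pat, mainlobe_exclusion_deg=1.0) == []

    def test_exclusion_covering_domain_error(self):
        ang = np.linspace(-10, 10, 201)
        pat = ad.BeamPattern(ang, np.ones_like(ang), 404e-6)
        with pytest.raises(ValueError):
            ad.find_grating_lobes(pat, mainlobe_exclusion_deg=30.0)


class TestTransmitField:
    def test_single_element_spherical_arrival(self, medium):
        pulse = GaussianPulse()
        r = 10e-3
        times = np.linspace(r / medium.c - 1e-6, r / medium.c + 1e-6, 161)
        snaps = ad.simulate_transmit_field(
            np.zeros((1, 2)), pulse, np.array([[0.0, 0.0, r]]), times,
            medium.c, normalize=False,
        )
        t_peak = times[np.abs(snaps[:, 0]).argmax()]
        assert t_peak == pytest.approx(r / medium.c, abs=2e-8)

    def test_mirror_symmetry(self, medium):
        pulse = GaussianPulse()
        pos = np.array([[1e-3, 0.0], [-1e-3, 0.0]])
        x = np.linspace(-4e-3, 4e-3, 41)
        pts = np.column_stack([x, np.zeros_like(x), np.full_like(x, 8e-3)])
        snap = ad.simulate_transmit_field(pos, pulse, pts, [8e-3 / medium.c],
                                          medium.c)[0]
        assert np.allclose(snap, snap[::-1], atol=1e-12)

    def test_linear_in_pulse_amplitude(self, medium):
        pts = np.array([[0.5e-3, 0.0, 12e-3]])
        t = [12e-3 / medium.c]
        pos = np.array([[0.0, 0.0], [1e-3, 1e-3]])
        s1 = ad.simulate_transmit_field(pos, GaussianPulse(amplitude=1.0), pts,
                                        t, medium.c, normalize=False)
        s3 = ad.simulate_transmit_field(pos, GaussianPulse(amplitude=3.0), pts,
                                        t, medium.c, normalize=False)
        assert np.allclose(s3, 3.0 * s1, rtol=1e-12)

    def test_zero_distance_rejected(self, medium):
        with pytest.raises(ValueError):
            ad.simulate_transmit_field(np.zeros((1, 2)), GaussianPulse(),
                                       np.array([[0.0, 0.0, 0.0]]), [0.0],
                                       medium.c)
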