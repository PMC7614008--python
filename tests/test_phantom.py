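"""Microvessel phantom: flow model, transport, and image formation."""

import numpy as np
import pandas as pd
import pytest

from ulm3d import phantom as ph
from ulm3d.beamform import (
    AcousticMedium,
    TransmitScheme,
    VoxelGrid,
)
from scipy.signal import hilbert


@pytest.fixture()
def spec():
    return ph.PhantomSpec()


class TestPoiseuille:
    def test_centerline_velocity_doubles_mean(self):
        assert ph.poiseuille_velocity(0.0, 100e-6, 44e-3) == pytest.approx(88e-3)

    def test_no_slip_at_wall(self):
        assert ph.poiseuille_velocity(100e-6, 100e-6, 44e-3) == 0.0

    def test_cross_section_mean_recovers_v_mean(self):
        """Area-weighted average of v(r) equals the nominal mean velocity."""
        R, vm = 100e-6, 44e-3
        r = np.linspace(0, R, 200001)
        v = ph.poiseuille_velocity(r, R, vm)
        mean = np.trapezoid(v * 2 * np.pi * r, r) / (np.pi * R**2)
        assert mean == pytest.approx(vm, rel=1e-3)

    def test_outside_lumen_rejected(self):
        with pytest.raises(ValueError):
            ph.poiseuille_velocity(101e-6, 100e-6, 44e-3)


class TestGeometry:
    def test_contact_region_separation_is_one_diameter(self, spec):
        y = np.linspace(-spec.contact_half_length, spec.contact_half_length, 101)
        c0 = ph.helix_centerline(spec, y, 0)
        c1 = ph.helix_centerline(spec, y, 1)
        d = np.linalg.norm(c0 - c1, axis=1)
        assert np.allclose(d, spec.tube_diameter, rtol=1e-9)

    def test_tubes_separate_at_the_ends(self, spec):
        c0 = ph.helix_centerline(spec, 4.8e-3, 0)
        c1 = ph.helix_centerline(spec, 4.8e-3, 1)
        assert np.linalg.norm(c0 - c1) > 2.5 * spec.tube_diameter

    def test_frame_is_orthonormal(self, spec):
        y = np.linspace(-4e-3, 4e-3, 17)
        t, n1, n2 = ph.helix_frame(spec, y, 0)
        for a, b in ((t, n1), (t, n2), (n1, n2)):
            assert np.allclose(np.einsum("ij,ij->i", a, b), 0.0, atol=1e-6)
        for a in (t, n1, n2):
            assert np.allclose(np.linalg.norm(a, axis=1), 1.0, atol=1e-9)


class TestTransport:
    def test_axial_displacement_per_volume_period(self, spec):
        """One 2-ms volume period at 11 mm/s mean moves an axial bubble 44 um."""
        state = ph.BubbleState(
            bubble_id=np.array([0]), tube=np.array([0]), y=np.array([0.0]),
            r_off=np.array([0.0]), psi=np.array([0.0]), amplitude=np.array([1.0]),
        )
        flow = ph.FlowSpec(mean_velocity=11e-3)
        p0 = ph.positions_of(state, spec)
        out = ph.advance_bubbles(state, spec, flow, dt=2e-3)
        p1 = ph.positions_of(out, spec)
        arc = np.linalg.norm(p1 - p0) \
            if out.n else None
        # arc-length displacement along the centerline, to chord accuracy
        assert arc == pytest.approx(2 * 11e-3 * 2e-3, rel=1e-3)

    def test_count_conserved_without_destruction(self, spec):
        rng = np.random.default_rng(0)
        state, _ = ph.inject_bubbles(spec, ph.BubblePopulation(injection_rate=2000.0),
                                     5e-3, rng, 0)
        n0 = state.n
        flow = ph.FlowSpec(44e-3)
        for _ in range(20):
            state = ph.advance_bubbles(state, spec, flow, dt=2e-3)
        assert state.n == n0  # 40 ms is far too short for any exit

    def test_trajectories_stay_inside_lumen(self, spec):
        rng = np.random.default_rng(1)
        traj = ph.simulate_bubbles(spec, ph.FlowSpec(44e-3),
                                   ph.BubblePopulation(injection_rate=10.0),
                                   100, 500.0, rng)
        for tube in (0, 1):
            sub = traj[traj.tube == tube]
            c = ph.helix_centerline(spec, sub.y.to_numpy(), tube)
            d = np.linalg.norm(sub[["x", "y", "z"]].to_numpy() - c, axis=1)
            assert np.all(d <= spec.tube_radius + 1e-9)

    def test_opposing_tubes_have_opposite_signs(self, spec):
        rng = np.random.default_rng(2)
        traj = ph.simulate_bubbles(spec, ph.FlowSpec(44e-3),
                                   ph.BubblePopulation(injection_rate=10.0),
                                   50, 500.0, rng)
        assert set(traj[traj.tube == 0].vy_sign) == {1.0}
        assert set(traj[traj.tube == 1].vy_sign) == {-1.0}

    def test_destruction_thins_population(self, spec):
        rng = np.random.default_rng(3)
        kw = dict(n_frames=200, frame_rate=500.0)
        full = ph.simulate_bubbles(spec, ph.FlowSpec(11e-3),
                                   ph.BubblePopulation(10.0, 0.0),
                                   rng=np.random.default_rng(3), **kw)
        thinned = ph.simulate_bubbles(spec, ph.FlowSpec(11e-3),
                                      ph.BubblePopulation(10.0, 2e-3),
                                      rng=np.random.default_rng(3), **kw)
        assert len(thinned) < len(full)


class TestPSFRendering:
    def _grid(self):
        return VoxelGrid.centered((0.0, 0.0, 25e-3), (4e-3, 4e-3, 3e-3),
                                  (100e-6,) * 3)

    def _one_bubble_traj(self, pos):
        return pd.DataFrame({
            "frame": [0], "bubble_id": [0], "tube": [0],
            "x": [pos[0]], "y": [pos[1]], "z": [pos[2]],
            "r_off": [0.0], "speed": [0.0], "vy_sign": [1.0], "amplitude": [1.0],
        })

    def test_peak_at_bubble_voxel_and_fwhm(self):
        grid = self._grid()
        psf = ph.PSFModel()
        pos = np.array([0.21e-3, -0.13e-3, 25.04e-3])
        seq, _ = ph.render_volume_psf(self._one_bubble_traj(pos), psf, grid, 1,
                                      500.0, np.random.default_rng(0),
                                      phase_decorrelation=False)
        vol = seq[0]
        idx = np.unravel_index(vol.argmax(), vol.shape)
        nearest = np.round(grid.world_to_index(pos)[0]).astype(int)
        assert np.array_equal(idx, nearest)
        from ulm3d.metrics import fwhm
        for axis in range(3):
            sl = [idx[0], idx[1], idx[2]]
            sl[axis] = slice(None)
            prof = vol[tuple(sl)]
            w = fwhm(grid.axis_coords(axis), prof)
            assert abs(w - psf.fwhm[axis]) < grid.spacing[axis]

    def test_zero_bubbles_zero_volume(self):
        grid = self._grid()
        empty = pd.DataFrame(columns=["frame", "bubble_id", "tube", "x", "y",
                                      "z", "r_off", "speed", "vy_sign",
                                      "amplitude"])
        a, b = ph.render_volume_psf(empty, ph.PSFModel(), grid, 2, 500.0,
                                    np.random.default_rng(0))
        assert not a.any() and not b.any()

    def test_fixed_seed_reproducible(self, spec):
        grid = self._grid()
        traj = self._one_bubble_traj([0.0, 0.0, 25e-3])
        kw = dict(spec=spec, clutter_amplitude=0.5, noise_sigma=0.01)
        a1, b1 = ph.render_volume_psf(traj, ph.PSFModel(), grid, 2, 500.0,
                                      np.random.default_rng(7), **kw)
        a2, b2 = ph.render_volume_psf(traj, ph.PSFModel(), grid, 2, 500.0,
                                      np.random.default_rng(7), **kw)
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)

    def test_aperture_noise_independent_but_signal_shared(self, spec):
        grid = self._grid()
        traj = self._one_bubble_traj([0.0, 0.0, 25e-3])
        a, b = ph.render_volume_psf(traj, ph.PSFModel(), grid, 1, 500.0,
                                    np.random.default_rng(0), spec=spec,
                                    noise_sigma=0.01)
        assert not np.array_equal(a, b)
        # the underlying signal is identical: differences are noise-sized
        assert np.abs(a - b).max() < 0.1


class TestRFSynthesis:
    def test_single_scatterer_arrival_time(self):
        """Echo peak sits at plane-wave delay plus return distance over c."""
        medium = AcousticMedium()
        scheme = TransmitScheme()
        elem = np.array([[2e-3, -1e-3]])
        scat = np.array([[1e-3, 0.5e-3, 20e-3]])
        ch = ph.synthesize_rf(scat, [1.0], elem, scheme, medium)
        for ia, ang in enumerate(scheme.angles_deg):
            d = ph.plane_wave_direction(ang)
            t_exp = (scat[0] @ d + np.linalg.norm(
                scat[0] - np.array([elem[0, 0], elem[0, 1], 0.0]))) / medium.c
            env = np.abs(hilbert(ch.data[ia, 0]))
            t_peak = ch.t0 + env.argmax() / ch.fs
            assert t_peak == pytest.approx(t_exp, abs=1.5 / ch.fs)

    def test_zero_scatterers_zero_data(self):
        ch = ph.synthesize_rf(np.zeros((0, 3)), np.zeros(0),
                              np.array([[0.0, 0.0]]), TransmitScheme(),
                              AcousticMedium())
        assert not ch.data.any()

    def test_linearity_in_amplitude(self):
        medium, scheme = AcousticMedium(), TransmitScheme()
        elem = np.array([[0.0, 0.0], [1e-3, 0.0]])
        scat = np.array([[0.0, 0.0, 25e-3]])
        c1 = ph.synthesize_rf(scat, [1.0], elem, scheme, medium)
        c2 = ph.synthesize_rf(scat, [2.0], elem, scheme, medium)
        assert np.allclose(c2.data, 2.0 * c1.data, rtol=1e-12)

    def test_scatterer_on_element_rejected(self):
        with pytest.raises(ValueError):
            ph.synthesize_rf(np.array([[0.0, 0.0, 0.0]]), [1.0],
                             np.array([[0.0, 0.0]]), TransmitScheme(),
                             AcousticMedium())
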