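"""Synthetic microvessel phantom: double-helix tubes, Poiseuille transport,
and two image-formation models.

The phantom emulates the in vitro target used throughout: two 200-um
cellulose tubes twisted into a double helix at 25 mm depth, carrying
opposing laminar flows with a mean microbubble velocity of 11 or 44 mm/s.
Microbubbles enter at a constant Poisson rate, ride the parabolic flow
profile at a fixed radial offset, and can be destroyed by each transmitted
pulse.  Image formation is available at two fidelities:

* ``render_volume_psf`` — fast surrogate: each bubble stamps a separable
  Gaussian point-spread function onto the voxel grid, plus a static clutter
  term shared by both apertures and per-aperture independent white noise;
* ``synthesize_rf`` — per-channel echo synthesis under a linear
  single-scattering point-target model, for end-to-end beamforming tests.

Both helices have radius equal to the tube radius and opposite phase about
a common axis, so the centerline separation is one tube diameter along the
whole length (a twisted pair in continuous contact, matching the contact
points seen on the physical phantom).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beamform import (
    AcousticMedium,
    ChannelDataSet,
    GaussianPulse,
    TransmitScheme,
    VoxelGrid,
    plane_wave_direction,
)

__all__ = [
    "PhantomSpec",
    "FlowSpec",
    "BubblePopulation",
    "PSFModel",
    "poiseuille_velocity",
    "helix_centerline",
    "helix_frame",
    "BubbleState",
    "inject_bubbles",
    "advance_bubbles",
    "simulate_bubbles",
    "render_volume_psf",
    "synthesize_rf",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Double-helix microvessel geometry.

    The helix axis runs along y at the given depth; the two tubes are
    opposite-phase helices about that axis.  Within ``contact_half_length``
    of the center the helix radius equals the tube radius, so the
    centerline separation is one tube diameter and the twisted tubes are in
    contact; toward the tube ends the radius flares smoothly to
    ``end_radius`` so the tubes separate at the inlets, as on the physical
    phantom, where the tube thickness is measured on an isolated section.
    """

    depth: float = 25e-3
    tube_diameter: float = 200e-6
    tube_length: float = 10e-3
    helix_pitch: float = 5e-3
    end_radius: float = 500e-6
    contact_half_length: float = 2.5e-3

    @property
    def tube_radius(self) -> float:
        return self.tube_diameter / 2.0

    @property
    def helix_radius(self) -> float:
        """Helix radius in the contact region (= tube radius)."""
        return self.tube_diameter / 2.0

    def helix_radius_at(self, y) -> np.ndarray:
        """Helix radius versus axial position (smoothstep flare at the ends)."""
        y = np.abs(np.asarray(y, dtype=float))
        c, half = self.contact_half_length, self.tube_length / 2.0
        t = np.clip((y - c) / max(half - c, 1e-12), 0.0, 1.0)
        s = 3.0 * t**2 - 2.0 * t**3
        return self.helix_radius + (self.end_radius - self.helix_radius) * s

    def arc_stretch(self, y=0.0) -> np.ndarray:
        """Centerline arc length per unit axial (y) distance, locally."""
        y = np.asarray(y, dtype=float)
        dy = 1e-7
        a = helix_centerline(self, np.atleast_1d(y) - dy, 0)
        b = helix_centerline(self, np.atleast_1d(y) + dy, 0)
        out = np.linalg.norm(b - a, axis=1) / (2 * dy)
        return float(out[0]) if np.ndim(y) == 0 else out


@dataclass(frozen=True)
class FlowSpec:
    """Laminar Poiseuille flow; tube 0 flows toward +y, tube 1 toward -y."""

    mean_velocity: float = 44e-3

    @property
    def peak_velocity(self) -> float:
        return 2.0 * self.mean_velocity


@dataclass(frozen=True)
class BubblePopulation:
    """Microbubble injection, destruction, and echogenicity parameters.

    ``injection_rate`` is per tube; ``destruction_prob`` applies per
    transmitted pulse (9 pulses per compounded volume at the default
    scheme).  Scattering amplitudes are log-normal about 1 with the given
    log-domain spread, providing the echo-size variability the
    volume-consistency track filter acts on.

    ``radius_fraction`` confines injected bubbles to a concentric disc of
    that fraction of the lumen radius: deformable tracers in laminar tube
    flow migrate away from the wall toward the axis, so the tracer
    distribution is narrower than the lumen itself.
    """

    injection_rate: float = 4.5
    destruction_prob: float = 5e-4
    amplitude_sigma: float = 0.2
    radius_fraction: float = 0.75


@dataclass(frozen=True)
class PSFModel:
    """Separable Gaussian point-spread function with peak 1."""

    fwhm: tuple[float, float, float] = (793e-6, 772e-6, 499e-6)

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fwhm):
            raise ValueError("PSF FWHMs must be positive")

    @property
    def sigma(self) -> np.ndarray:
        return np.asarray(self.fwhm) / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def poiseuille_velocity(r, R: float, v_mean: float):
    """Laminar profile v(r) = 2 v_mean (1 - (r/R)^2); v(0) = 2 v_mean, v(R) = 0."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > R):
        raise ValueError("radial offset must lie in [0, R]")
    out = 2.0 * v_mean * (1.0 - (r / R) ** 2)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def helix_centerline(spec: PhantomSpec, y, tube: int) -> np.ndarray:
    """Centerline point(s) of one tube at axial coordinate(s) y."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    k = 2.0 * np.pi / spec.helix_pitch
    phase = k * y + np.pi * tube
    r = spec.helix_radius_at(y)
    pts = np.column_stack(
        [
            r * np.cos(phase),
            y,
            spec.depth + r * np.sin(phase),
        ]
    )
    return pts


def helix_frame(spec: PhantomSpec, y, tube: int):
    """Tangent and two normals of the centerline at axial coordinate(s) y.

    Returns (tangent, n1, n2), each (len(y), 3), orthonormal.  The tangent
    points toward +y for both tubes; flow direction carries the sign.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    dy = 1e-7
    tangent = (helix_centerline(spec, y + dy, tube)
               - helix_centerline(spec, y - dy, tube)) / (2 * dy)
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    # radial direction of the helix, orthogonalized against the tangent
    k = 2.0 * np.pi / spec.helix_pitch
    phase = k * y + np.pi * tube
    n1 = np.column_stack([np.cos(phase), np.zeros_like(y), np.sin(phase)])
    n1 -= (np.einsum("ij,ij->i", n1, tangent))[:, None] * tangent
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
    n2 = np.cross(tangent, n1)
    return tangent, n1, n2


# ---------------------------------------------------------------------------
# Bubble transport
# ---------------------------------------------------------------------------

@dataclass
class BubbleState:
    """Columnar state of the live bubble population."""

    bubble_id: np.ndarray  # int
    tube: np.ndarray  # int, 0 or 1
    y: np.ndarray  # axial coordinate along the helix axis
    r_off: np.ndarray  # radial offset from the centerline
    psi: np.ndarray  # azimuth of the offset in the (n1, n2) frame
    amplitude: np.ndarray

    @property
    def n(self) -> int:
        return self.y.size

    def select(self, keep: np.ndarray) -> "BubbleState":
        return BubbleState(*(getattr(self, f)[keep] for f in
                             ("bubble_id", "tube", "y", "r_off", "psi", "amplitude")))

    @classmethod
    def empty(cls) -> "BubbleState":
        z = np.zeros(0)
        return cls(z.astype(int), z.astype(int), z.copy(), z.copy(), z.copy(), z.copy())


def positions_of(state: BubbleState, spec: PhantomSpec) -> np.ndarray:
    """World coordinates of all bubbles in ``state``."""
    pts = np.zeros((state.n, 3))
    for tube in (0, 1):
        m = state.tube == tube
        if not m.any():
            continue
        c = helix_centerline(spec, state.y[m], tube)
        _, n1, n2 = helix_frame(spec, state.y[m], tube)
        off = (
            state.r_off[m, None] * np.cos(state.psi[m])[:, None] * n1
            + state.r_off[m, None] * np.sin(state.psi[m])[:, None] * n2
        )
        pts[m] = c + off
    return pts


def speeds_of(state: BubbleState, spec: PhantomSpec, flow: FlowSpec) -> np.ndarray:
    return poiseuille_velocity(state.r_off, spec.tube_radius, flow.mean_velocity)


def inject_bubbles(
    spec: PhantomSpec,
    pop: BubblePopulation,
    dt: float,
    rng: np.random.Generator,
    next_id: int,
) -> tuple[BubbleState, int]:
    """Poisson arrivals at each tube inlet, uniform over the cross-section."""
    parts = []
    for tube in (0, 1):
        n_new = rng.poisson(pop.injection_rate * dt)
        if n_new == 0:
            continue
        inlet = -spec.tube_length / 2.0 if tube == 0 else spec.tube_length / 2.0
        r = pop.radius_fraction * spec.tube_radius * np.sqrt(rng.uniform(size=n_new))
        parts.append(
            BubbleState(
                bubble_id=next_id + np.arange(n_new),
                tube=np.full(n_new, tube),
                y=np.full(n_new, inlet),
                r_off=r,
                psi=rng.uniform(0, 2 * np.pi, size=n_new),
                amplitude=rng.lognormal(0.0, pop.amplitude_sigma, size=n_new),
            )
        )
        next_id += n_new
    if not parts:
        return BubbleState.empty(), next_id
    merged = BubbleState(
        *(np.concatenate([getattr(p, f) for p in parts]) for f in
          ("bubble_id", "tube", "y", "r_off", "psi", "amplitude"))
    )
    return merged, next_id


def advance_bubbles(
    state: BubbleState,
    spec: PhantomSpec,
    flow: FlowSpec,
    dt: float,
    pulses: int = 0,
    destruction_prob: float = 0.0,
    rng: np.random.Generator | None = None,
) -> BubbleState:
    """Move bubbles along their tube by v(r) dt; apply exits and destruction.

    The arc-length displacement v(r) dt is converted to an axial advance via
    the constant helix stretch factor; tube 1 advances toward -y.  Bubbles
    beyond the tube ends are removed; each of ``pulses`` insonation events
    destroys a bubble independently with ``destruction_prob``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if state.n == 0:
        return state
    v = speeds_of(state, spec, flow)
    direction = np.where(state.tube == 0, 1.0, -1.0)
    y = state.y + direction * v * dt / spec.arc_stretch(state.y)
    out = BubbleState(state.bubble_id, state.tube, y, state.r_off,
                      state.psi, state.amplitude)
    keep = np.abs(y) <= spec.tube_length / 2.0
    if pulses > 0 and destruction_prob > 0.0:
        if rng is None:
            raise ValueError("destruction requires an RNG")
        survive = (1.0 - destruction_prob) ** pulses
        keep &= rng.uniform(size=state.n) < survive
    return out.select(keep)


def simulate_bubbles(
    spec: PhantomSpec,
    flow: FlowSpec,
    pop: BubblePopulation,
    n_frames: int,
    frame_rate: float,
    rng: np.random.Generator,
    pulses_per_frame: int = 9,
    burn_in: float | None = None,
) -> pd.DataFrame:
    """Simulate the bubble population over ``n_frames`` compounded volumes.

    A burn-in period (default: one tube transit at the mean velocity) fills
    the tubes before frame 0 so the recorded sequence is stationary.
    Returns a trajectory table with one row per (frame, bubble):
    (frame, bubble_id, tube, x, y, z, r_off, speed, vy_sign, amplitude).
    """
    dt = 1.0 / frame_rate
    if burn_in is None:
        burn_in = spec.tube_length * spec.arc_stretch(0.0) / flow.mean_velocity
    state = BubbleState.empty()
    next_id = 0
    rows = []
    n_burn = int(np.ceil(burn_in * frame_rate))
    for frame in range(-n_burn, n_frames):
        new, next_id = inject_bubbles(spec, pop, dt, rng, next_id)
        if new.n:
            state = BubbleState(
                *(np.concatenate([getattr(state, f), getattr(new, f)]) for f in
                  ("bubble_id", "tube", "y", "r_off", "psi", "amplitude"))
            )
        state = advance_bubbles(
            state, spec, flow, dt,
            pulses=pulses_per_frame, destruction_prob=pop.destruction_prob, rng=rng,
        )
        if frame >= 0 and state.n:
            pts = positions_of(state, spec)
            v = speeds_of(state, spec, flow)
            sign = np.where(state.tube == 0, 1.0, -1.0)
            rows.append(pd.DataFrame({
                "frame": frame,
                "bubble_id": state.bubble_id,
                "tube": state.tube,
                "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
                "r_off": state.r_off,
                "speed": v,
                "vy_sign": sign,
                "amplitude": state.amplitude,
            }))
    if not rows:
        return pd.DataFrame(columns=["frame", "bubble_id", "tube", "x", "y", "z",
                                     "r_off", "speed", "vy_sign", "amplitude"])
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Image formation: fast PSF surrogate
# ---------------------------------------------------------------------------

def _static_clutter(
    spec: PhantomSpec,
    grid: VoxelGrid,
    amplitude: float,
    rng: np.random.Generator,
    shell: float = 200e-6,
) -> np.ndarray:
    """Static speckle concentrated near the tube walls, drawn once."""
    if amplitude == 0.0:
        return np.zeros(grid.shape, dtype=np.float32)
    from scipy.ndimage import gaussian_filter

    speckle = gaussian_filter(rng.standard_normal(grid.shape), sigma=1.0)
    pts = grid.voxel_centers()
    dmin = np.full(pts.shape[0], np.inf)
    ys = np.linspace(-spec.tube_length / 2, spec.tube_length / 2, 256)
    for tube in (0, 1):
        c = helix_centerline(spec, ys, tube)
        # distance from each voxel to the sampled centerline
        for start in range(0, pts.shape[0], 16384):
            blk = pts[start:start + 16384]
            d = np.sqrt(((blk[:, None, :] - c[None, :, :]) ** 2).sum(-1)).min(axis=1)
            dmin[start:start + 16384] = np.minimum(dmin[start:start + 16384], d)
    mask = np.exp(-0.5 * ((dmin - spec.tube_radius) / shell) ** 2).reshape(grid.shape)
    clutter = np.abs(speckle) * mask
    peak = clutter.max()
    if peak > 0:
        clutter *= amplitude / peak
    return clutter.astype(np.float32)


def render_volume_psf(
    traj: pd.DataFrame,
    psf: PSFModel,
    grid: VoxelGrid,
    n_frames: int,
    frame_rate: float,
    rng: np.random.Generator,
    spec: PhantomSpec | None = None,
    clutter_amplitude: float = 0.0,
    noise_sigma: float = 0.0,
    support_sigmas: float = 4.0,
    phase_decorrelation: bool = True,
):
    """Render bubble trajectories into two per-aperture volume sequences.

    Each volume is the sum of per-bubble Gaussian PSF stamps, a static
    clutter term shared by the two apertures, and aperture-independent white
    noise.  Returns (seq_aperture1, seq_aperture2) as float32 arrays of shape
    (n_frames, nx, ny, nz).

    With ``phase_decorrelation`` each stamp carries a random polarity drawn
    independently per bubble and frame.  A microbubble moving a substantial
    fraction of a wavelength between volumes returns echoes of essentially
    independent phase, so the slow-time mean of its complex beamformed
    signal is zero; the random sign reproduces that property in this
    real-valued surrogate, and without it the sequence would acquire a
    static occupancy pedestal that no clutter filter should be asked to
    distinguish from real echoes.  Both apertures see the same polarity
    (they image the same field).
    """
    sig = psf.sigma
    spacing = np.asarray(grid.spacing)
    half = np.maximum((support_sigmas * sig / spacing).astype(int), 1)
    base = np.zeros((n_frames,) + grid.shape, dtype=np.float32)
    axes = [grid.axis_coords(i) for i in range(3)]
    for row in traj.itertuples(index=False):
        f = int(row.frame)
        if not 0 <= f < n_frames:
            continue
        pos = np.array([row.x, row.y, row.z])
        idx = grid.world_to_index(pos)[0]
        lo = np.maximum(np.round(idx).astype(int) - half, 0)
        hi = np.minimum(np.round(idx).astype(int) + half + 1, grid.shape)
        if np.any(lo >= hi):
            continue
        profs = [
            np.exp(-0.5 * ((axes[a][lo[a]:hi[a]] - pos[a]) / sig[a]) ** 2)
            for a in range(3)
        ]
        polarity = (1.0 if rng.random() < 0.5 else -1.0) if phase_decorrelation else 1.0
        stamp = polarity * row.amplitude * (
            profs[0][:, None, None] * profs[1][None, :, None] * profs[2][None, None, :]
        )
        base[f, lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += stamp.astype(np.float32)
    if clutter_amplitude > 0.0:
        if spec is None:
            raise ValueError("clutter rendering requires the phantom spec")
        base += _static_clutter(spec, grid, clutter_amplitude, rng)[None]
    seqs = []
    for _ in range(2):
        seq = base.copy()
        if noise_sigma > 0.0:
            seq += noise_sigma * rng.standard_normal(seq.shape, dtype=np.float32)
        seqs.append(seq)
    return seqs[0], seqs[1]


# ---------------------------------------------------------------------------
# Image formation: per-channel RF synthesis
# ---------------------------------------------------------------------------

def synthesize_rf(
    scatterers: np.ndarray,
    amplitudes: np.ndarray,
    element_positions: np.ndarray,
    scheme: TransmitScheme,
    medium: AcousticMedium,
    fs: float | None = None,
    t_span: tuple[float, float] | None = None,
) -> ChannelDataSet:
    """Single-scattering echo synthesis for steered plane-wave transmissions.

    For each transmission and element, the echo is the transmit pulse delayed
    by the plane-wave time of flight to the scatterer plus the return path,
    weighted by amplitude / return distance.  The time origin is the instant
    the wavefront passes the array center.

    scatterers : (S, 3) positions; amplitudes : (S,).
    """
    scatterers = np.atleast_2d(np.asarray(scatterers, dtype=float))
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    elem = np.column_stack([element_positions, np.zeros(len(element_positions))])
    if fs is None:
        fs = 8.0 * medium.f0
    if fs < 4.0 * medium.f0:
        raise ValueError("sampling rate must be at least 4 x f0")
    pulse = scheme.pulse
    if t_span is None:
        if scatterers.size:
            zmax = scatterers[:, 2].max()
            zmin = scatterers[:, 2].min()
            margin = pulse.duration + 2e-6
            t_span = (max(2.0 * zmin / medium.c - margin, 0.0),
                      2.0 * zmax / medium.c + margin + 2 * np.max(
                          np.abs(scatterers[:, :2])) / medium.c if scatterers.size
                      else 1e-6)
        else:
            t_span = (0.0, 1e-6)
    n_samp = int(np.ceil((t_span[1] - t_span[0]) * fs)) + 1
    t = t_span[0] + np.arange(n_samp) / fs
    data = np.zeros((scheme.n_angles, len(elem), n_samp))
    if scatterers.size == 0:
        return ChannelDataSet(data, fs, t_span[0], np.asarray(element_positions),
                              scheme.angles_deg)
    dist = np.sqrt(((elem[:, None, :] - scatterers[None, :, :]) ** 2).sum(-1))
    if np.any(dist == 0):
        raise ValueError("scatterer coincides with an element")
    for ia, ang in enumerate(scheme.angles_deg):
        d = plane_wave_direction(ang)
        tx = scatterers @ d / medium.c  # (S,)
        delay = tx[None, :] + dist / medium.c  # (E, S)
        for s in range(scatterers.shape[0]):
            data[ia] += (amplitudes[s] / dist[:, s])[:, None] * pulse(
                t[None, :] - delay[:, s][:, None]
            )
    return ChannelDataSet(data, fs, t_span[0], np.asarray(element_positions),
                          scheme.angles_deg)
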