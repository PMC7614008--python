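"""3-D plane-wave delay-and-sum beamforming and coherent compounding.

Steered plane waves are transmitted from the sparse aperture; each
transmission is beamformed onto a voxel grid with the two-way delay law

    tau(voxel, element) = [plane-wave delay to voxel + |voxel - element|] / c

and the nine steered volumes are coherently compounded (complex mean) into
one imaging volume per frame.  The transmit delay is referenced to the array
plane's center with wavefront normal (sin ax, sin ay, sqrt(1 - sin^2 - sin^2)),
the same convention the phantom module uses when synthesizing echoes, so the
two stages are consistent by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "water_sound_speed",
    "GaussianPulse",
    "AcousticMedium",
    "TransmitScheme",
    "VoxelGrid",
    "VolumeSequence",
    "ChannelDataSet",
    "plane_wave_direction",
    "das_plane_wave",
    "coherent_compound",
    "beamform_frame",
    "envelope",
    "to_db",
]


def water_sound_speed(temperature_c: float = 25.0) -> float:
    """Speed of sound in pure water (m/s), Marczak (1997) polynomial fit."""
    t = temperature_c
    return (
        1.402385e3
        + 5.038813 * t
        - 5.799136e-2 * t**2
        + 3.287156e-4 * t**3
        - 1.398845e-6 * t**4
        + 2.787860e-9 * t**5
    )


@dataclass(frozen=True)
class GaussianPulse:
    """Gaussian-windowed sinusoid; ``n_cycles`` carrier periods at half maximum.

    The envelope FWHM equals n_cycles / f0, i.e. the pulse carries three
    cycles within its half-maximum width for the default imaging pulse.
    """

    f0: float = 3.7e6
    n_cycles: float = 3.0
    amplitude: float = 1.0

    @property
    def sigma_t(self) -> float:
        fwhm = self.n_cycles / self.f0
        return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    @property
    def duration(self) -> float:
        """Practical support (+- 4 sigma) of the envelope."""
        return 8.0 * self.sigma_t

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (
            self.amplitude
            * np.cos(2.0 * np.pi * self.f0 * t)
            * np.exp(-(t**2) / (2.0 * self.sigma_t**2))
        )


@dataclass(frozen=True)
class AcousticMedium:
    """Propagation medium; defaults to water at 25 degrees C."""

    c: float = water_sound_speed(25.0)
    f0: float = 3.7e6

    @property
    def wavelength(self) -> float:
        return self.c / self.f0


def _default_angles() -> tuple[tuple[float, float], ...]:
    return tuple(itertools.product((-10.0, 0.0, 10.0), repeat=2))


@dataclass(frozen=True)
class TransmitScheme:
    """Compounded plane-wave scheme: 9 steering angles, PRF 4500 Hz."""

    angles_deg: tuple[tuple[float, float], ...] = field(default_factory=_default_angles)
    prf: float = 4500.0
    pulse: GaussianPulse = field(default_factory=GaussianPulse)

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)

    @property
    def volume_rate(self) -> float:
        return self.prf / self.n_angles


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid; ``origin`` is the center of voxel (0, 0, 0).

    Axis order is (x, y, z) with z the depth; volumes are indexed
    volume[ix, iy, iz].
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def voxel_centers(self) -> np.ndarray:
        """(M, 3) coordinates of all voxel centers, C-order over (x, y, z)."""
        ax = [self.axis_coords(i) for i in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    @classmethod
    def centered(cls, center, extent, spacing) -> "VoxelGrid":
        """Grid of the given physical extent centered on ``center``."""
        center = np.asarray(center, dtype=float)
        extent = np.asarray(extent, dtype=float)
        spacing = np.asarray(spacing, dtype=float)
        shape = np.maximum(np.round(extent / spacing).astype(int) + 1, 1)
        origin = center - (shape - 1) / 2.0 * spacing
        return cls(tuple(origin), tuple(spacing), tuple(int(s) for s in shape))


@dataclass
class VolumeSequence:
    """Slow-time stack of 3-D volumes: data[frame, ix, iy, iz]."""

    data: np.ndarray
    grid: VoxelGrid
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass
class ChannelDataSet:
    """Per-transmission, per-element RF time series.

    data[transmission, element, sample]; ``t0`` is the time of the first
    sample relative to the transmit reference (wavefront through the array
    center at t = 0).
    """

    data: np.ndarray
    fs: float
    t0: float
    element_positions: np.ndarray  # (N, 2) in the array plane
    angles_deg: tuple[tuple[float, float], ...]

    def analytic(self) -> np.ndarray:
        return hilbert(self.data, axis=-1)


def plane_wave_direction(angle_deg: tuple[float, float]) -> np.ndarray:
    """Unit wavefront normal for steering (alpha_x, alpha_y) in degrees."""
    sx = np.sin(np.deg2rad(angle_deg[0]))
    sy = np.sin(np.deg2rad(angle_deg[1]))
    sz2 = 1.0 - sx**2 - sy**2
    if sz2 <= 0:
        raise ValueError("steering angles place the wavefront outside visible space")
    return np.array([sx, sy, np.sqrt(sz2)])


def das_plane_wave(
    analytic_data: np.ndarray,
    fs: float,
    t0: float,
    element_positions: np.ndarray,
    angle_deg: tuple[float, float],
    grid: VoxelGrid,
    medium: AcousticMedium,
    apodization: np.ndarray | None = None,
    chunk: int = 8192,
) -> np.ndarray:
    """Delay-and-sum one plane-wave transmission onto a voxel grid.

    analytic_data : (n_elements, n_samples) complex analytic channel signals.
    Fractional-sample access uses linear interpolation; delays falling outside
    the recording contribute zero.  Returns a complex volume on ``grid``.
    """
    n_elem, n_samp = analytic_data.shape
    elem = np.column_stack([element_positions, np.zeros(n_elem)])
    if apodization is None:
        apodization = np.ones(n_elem)
    d = plane_wave_direction(angle_deg)
    voxels = grid.voxel_centers()
    out = np.zeros(voxels.shape[0], dtype=complex)
    for start in range(0, voxels.shape[0], chunk):
        vox = voxels[start : start + chunk]
        tx = vox @ d / medium.c  # plane-wave delay to voxel
        diff = vox[:, None, :] - elem[None, :, :]
        rx = np.sqrt(np.einsum("mnk,mnk->mn", diff, diff)) / medium.c
        s = (tx[:, None] + rx - t0) * fs
        i0 = np.floor(s).astype(int)
        frac = s - i0
        valid = (i0 >= 0) & (i0 < n_samp - 1)
        i0c = np.clip(i0, 0, n_samp - 2)
        rows = np.broadcast_to(np.arange(n_elem)[None, :], i0c.shape)
        vals = (
            analytic_data[rows, i0c] * (1.0 - frac)
            + analytic_data[rows, i0c + 1] * frac
        )
        vals = np.where(valid, vals, 0.0)
        out[start : start + chunk] = vals @ apodization.astype(complex)
    return out.reshape(grid.shape)


def coherent_compound(volumes: np.ndarray) -> np.ndarray:
    """Complex mean across the steering-angle axis (axis 0)."""
    volumes = np.asarray(volumes)
    if volumes.ndim < 2:
        raise ValueError("expected a stack of volumes")
    return volumes.mean(axis=0)


def beamform_frame(
    channels: ChannelDataSet,
    grid: VoxelGrid,
    medium: AcousticMedium,
    apodization: np.ndarray | None = None,
) -> np.ndarray:
    """Beamform all transmissions of one frame and compound them."""
    analytic = channels.analytic()
    vols = np.stack(
        [
            das_plane_wave(
                analytic[i],
                channels.fs,
                channels.t0,
                channels.element_positions,
                ang,
                grid,
                medium,
                apodization,
            )
            for i, ang in enumerate(channels.angles_deg)
        ]
    )
    return coherent_compound(vols)


def envelope(volume: np.ndarray) -> np.ndarray:
    """Voxelwise magnitude of a complex (or real) beamformed volume."""
    return np.abs(volume)


def to_db(amplitude: np.ndarray, ref: float | None = None) -> np.ndarray:
    """Amplitude to dB re ``ref`` (defaults to the array maximum)."""
    amplitude = np.asarray(amplitude, dtype=float)
    if ref is None:
        ref = amplitude.max()
    if ref <= 0:
        raise ValueError("reference level must be positive")
    with np.errstate(divide="ignore"):
        return 20.0 * np.log10(amplitude / ref)
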