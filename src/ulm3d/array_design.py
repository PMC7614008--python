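"""Density-tapered spiral sparse-array design and beam-pattern analysis.

A 2-D matrix probe offers a 32 x 35 grid of 300-um elements in which three
rows (9, 18, 27, 1-based) are unavailable, leaving 1024 usable elements.
Two complementary 256-element sparse apertures are selected from that grid by
snapping the seeds of a density-tapered Fermat spiral to the nearest free
elements.  The module also provides the far-field array factor, a
grating-lobe search, and a point-source transmitted-field simulator used to
characterize the plane-wave field radiated by the sparse aperture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GOLDEN_ANGLE_DEG",
    "MatrixGrid",
    "SpiralParams",
    "ArrayLayout",
    "BeamPattern",
    "tukey_taper",
    "generate_spiral_seeds",
    "snap_seeds_to_grid",
    "design_apertures",
    "array_factor",
    "beam_pattern_cut",
    "find_grating_lobes",
    "predicted_grating_angle",
    "simulate_transmit_field",
]

#: Golden angle in degrees; successive Fermat-spiral seeds advance by this azimuth.
GOLDEN_ANGLE_DEG = 360.0 * (1.0 - 1.0 / ((1.0 + np.sqrt(5.0)) / 2.0))


# ---------------------------------------------------------------------------
# Grid and layout containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatrixGrid:
    """Gridded 2-D matrix-array geometry with unavailable (wiring) rows.

    Rows in ``inactive_rows`` are 1-based, matching probe data sheets.
    """

    n_cols: int = 32
    n_rows: int = 35
    pitch_x: float = 300e-6
    pitch_y: float = 300e-6
    inactive_rows: tuple[int, ...] = (9, 18, 27)

    def __post_init__(self) -> None:
        if self.pitch_x <= 0 or self.pitch_y <= 0:
            raise ValueError("element pitches must be positive")
        if self.n_cols <= 0 or self.n_rows <= 0:
            raise ValueError("grid dimensions must be positive")

    @property
    def n_available(self) -> int:
        return self.n_cols * (self.n_rows - len(self.inactive_rows))

    def element_table(self) -> pd.DataFrame:
        """All grid positions with availability flags.

        The array is centered on the origin; x runs along columns, y along
        rows, and element positions are at cell centers.
        """
        rows, cols = np.meshgrid(
            np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij"
        )
        rows = rows.ravel()
        cols = cols.ravel()
        x = (cols - (self.n_cols - 1) / 2.0) * self.pitch_x
        y = (rows - (self.n_rows - 1) / 2.0) * self.pitch_y
        available = ~np.isin(rows + 1, self.inactive_rows)
        return pd.DataFrame(
            {
                "element_id": np.arange(rows.size),
                "row": rows + 1,
                "col": cols + 1,
                "x_m": x,
                "y_m": y,
                "available": available,
            }
        )


@dataclass(frozen=True)
class SpiralParams:
    """Parameters of the ungridded density-tapered spiral."""

    n_seeds: int = 256
    aperture_width: float = 10.4e-3
    tukey_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if self.aperture_width <= 0:
            raise ValueError("aperture_width must be positive")
        if not 0.0 <= self.tukey_ratio <= 1.0:
            raise ValueError("tukey_ratio must lie in [0, 1]")


@dataclass
class ArrayLayout:
    """Element table of the designed sparse array.

    ``table`` has one row per grid element with columns
    (element_id, row, col, x_m, y_m, aperture) where aperture is 0 (unused),
    1, or 2.
    """

    grid: MatrixGrid
    table: pd.DataFrame

    def positions(self, aperture: int | None = None) -> np.ndarray:
        """(N, 2) element coordinates; restrict to one aperture if given."""
        t = self.table
        if aperture is None:
            t = t[t["aperture"] > 0]
        else:
            t = t[t["aperture"] == aperture]
        return t[["x_m", "y_m"]].to_numpy()

    @property
    def n_active(self) -> int:
        return int((self.table["aperture"] > 0).sum())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grid: MatrixGrid | None = None) -> "ArrayLayout":
        return cls(grid=grid or MatrixGrid(), table=pd.read_csv(path))


@dataclass
class BeamPattern:
    """Sampled far-field pattern along a 1-D angular cut.

    ``magnitude`` is linear and normalized so the value at the steering
    direction is 1.
    """

    angles_deg: np.ndarray
    magnitude: np.ndarray
    wavelength: float
    steering_deg: float = 0.0


# ---------------------------------------------------------------------------
# Spiral seeds and grid snapping
# ---------------------------------------------------------------------------

def tukey_taper(x: np.ndarray, ratio: float) -> np.ndarray:
    """Radial Tukey taper on [0, 1]: flat to 1-ratio, cosine roll-off to 0."""
    x = np.asarray(x, dtype=float)
    w = np.ones_like(x)
    if ratio > 0:
        edge = 1.0 - ratio
        tail = x > edge
        w[tail] = 0.5 * (1.0 + np.cos(np.pi * (x[tail] - edge) / ratio))
    w[x > 1.0] = 0.0
    return w


def generate_spiral_seeds(params: SpiralParams) -> np.ndarray:
    """Seeds of the density-tapered Fermat spiral, ordered center outward.

    Azimuths advance by the golden angle; radii are placed by inverting the
    cumulative distribution of the target areal density r * w(r), where w is
    the Tukey taper over [0, aperture_width / 2].  Fully deterministic.

    Returns an (n_seeds, 2) array of x, y coordinates in meters.
    """
    R = params.aperture_width / 2.0
    n = np.arange(params.n_seeds)
    theta = np.deg2rad(GOLDEN_ANGLE_DEG) * n

    r_grid = np.linspace(0.0, R, 4096)
    density = r_grid * tukey_taper(r_grid / R, params.tukey_ratio)
    cdf = np.concatenate(([0.0], np.cumsum((density[1:] + density[:-1]) / 2.0)))
    cdf /= cdf[-1]
    # quantiles n/N: the first seed sits at the origin like the n=0 Fermat seed
    radii = np.interp(n / params.n_seeds, cdf, r_grid)

    return np.column_stack([radii * np.cos(theta), radii * np.sin(theta)])


def snap_seeds_to_grid(
    seeds: np.ndarray,
    grid: MatrixGrid,
    excluded: Sequence[int] = (),
) -> np.ndarray:
    """Map each seed to the nearest free grid element, one-to-one.

    Seeds are processed in generation order (center outward).  Candidate
    elements are the available ones not in ``excluded`` and not already
    taken by an earlier seed.  Distance ties are broken by lower row, then
    lower column.  Returns the selected element_ids in seed order.
    """
    seeds = np.asarray(seeds, dtype=float)
    table = grid.element_table()
    free = table["available"].to_numpy().copy()
    free[np.isin(table["element_id"].to_numpy(), np.asarray(excluded, dtype=int))] = False
    if free.sum() < len(seeds):
        raise ValueError(
            f"only {int(free.sum())} free elements for {len(seeds)} seeds"
        )
    xy = table[["x_m", "y_m"]].to_numpy()
    rowcol = table[["row", "col"]].to_numpy()
    chosen = np.empty(len(seeds), dtype=int)
    for i, s in enumerate(seeds):
        d2 = np.einsum("ij,ij->i", xy - s, xy - s)
        d2[~free] = np.inf
        best = d2.min()
        cand = np.flatnonzero(d2 <= best * (1 + 1e-12) + 1e-30)
        if len(cand) > 1:  # deterministic tie-break
            order = np.lexsort((rowcol[cand, 1], rowcol[cand, 0]))
            cand = cand[order]
        chosen[i] = cand[0]
        free[cand[0]] = False
    return chosen


def design_apertures(
    grid: MatrixGrid | None = None, params: SpiralParams | None = None
) -> ArrayLayout:
    """Design the two complementary sparse apertures.

    The same spiral seeds are snapped twice: Aperture 1 on the free grid,
    Aperture 2 on the grid with Aperture 1 excluded, yielding 2 x 256
    disjoint elements (512 in total).
    """
    grid = grid or MatrixGrid()
    params = params or SpiralParams()
    seeds = generate_spiral_seeds(params)
    ap1 = snap_seeds_to_grid(seeds, grid)
    ap2 = snap_seeds_to_grid(seeds, grid, excluded=ap1)
    table = grid.element_table()
    aperture = np.zeros(len(table), dtype=int)
    aperture[ap1] = 1
    aperture[ap2] = 2
    table = table.assign(aperture=aperture)
    return ArrayLayout(grid=grid, table=table)


# ---------------------------------------------------------------------------
# Array factor and grating lobes
# ---------------------------------------------------------------------------

def array_factor(
    positions: np.ndarray,
    wavelength: float,
    u: np.ndarray,
    v: np.ndarray,
    steering: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """One-way array factor over direction cosines (u, v).

    magnitude = |sum_e exp(i 2 pi / lambda * (x_e (u - u0) + y_e (v - v0)))|,
    normalized by its value at the steering direction (= element count), so
    the main lobe is exactly 1.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.shape[0] == 0:
        raise ValueError("element set is empty")
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    k = 2.0 * np.pi / wavelength
    du = u - steering[0]
    dv = v - steering[1]
    phase = k * (
        positions[:, 0][:, None] * du.ravel()[None, :]
        + positions[:, 1][:, None] * dv.ravel()[None, :]
    )
    af = np.abs(np.exp(1j * phase).sum(axis=0)) / positions.shape[0]
    return af.reshape(np.broadcast(u, v).shape)


def beam_pattern_cut(
    positions: np.ndarray,
    wavelength: float,
    angles_deg: np.ndarray,
    axis: str = "y",
    steering_deg: float = 0.0,
) -> BeamPattern:
    """Array-factor cut along one lateral direction (u for x, v for y)."""
    angles_deg = np.asarray(angles_deg, dtype=float)
    s = np.sin(np.deg2rad(angles_deg))
    s0 = np.sin(np.deg2rad(steering_deg))
    if axis == "x":
        mag = array_factor(positions, wavelength, s, np.zeros_like(s), (s0, 0.0))
    elif axis == "y":
        mag = array_factor(positions, wavelength, np.zeros_like(s), s, (0.0, s0))
    else:
        raise ValueError("axis must be 'x' or 'y'")
    return BeamPattern(angles_deg, mag, wavelength, steering_deg)


def find_grating_lobes(
    pattern: BeamPattern, mainlobe_exclusion_deg: float
) -> list[tuple[float, float]]:
    """Local maxima outside the main-lobe exclusion zone, amplitude-descending.

    Returns (angle_deg, amplitude) tuples with amplitudes relative to the
    pattern's own main lobe.
    """
    from scipy.signal import find_peaks

    ang = pattern.angles_deg
    span = ang.max() - ang.min()
    if 2 * mainlobe_exclusion_deg >= span:
        raise ValueError("exclusion zone covers the whole angular domain")
    peaks, _ = find_peaks(pattern.magnitude)
    keep = np.abs(ang[peaks] - pattern.steering_deg) > mainlobe_exclusion_deg
    peaks = peaks[keep]
    order = np.argsort(pattern.magnitude[peaks])[::-1]
    return [(float(ang[p]), float(pattern.magnitude[p])) for p in peaks[order]]


def predicted_grating_angle(wavelength: float, period: float) -> float:
    """First grating angle (degrees) of a defect with the given spatial period."""
    s = wavelength / period
    if s >= 1.0:
        raise ValueError("no grating lobe in visible space for this period")
    return float(np.degrees(np.arcsin(s)))


# ---------------------------------------------------------------------------
# Transmitted-field simulation (point-source superposition)
# ---------------------------------------------------------------------------

def simulate_transmit_field(
    positions: np.ndarray,
    pulse,
    field_points: np.ndarray,
    times: np.ndarray,
    c: float,
    steering: tuple[float, float] = (0.0, 0.0),
    normalize: bool = True,
) -> np.ndarray:
    """Plane-wave field snapshots from a point-source superposition.

    Each element at (x_e, y_e, 0) fires ``pulse`` delayed by the plane-wave
    steering law referenced to the array center; the field at a point is the
    sum of the delayed waveforms attenuated by 1 / distance.  Snapshots are
    each normalized to their own maximum absolute value when ``normalize``.

    positions : (N, 2) element coordinates in the array plane.
    field_points : (M, 3) observation points.
    times : (T,) snapshot times.
    Returns an (T, M) array.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    pts = np.atleast_2d(np.asarray(field_points, dtype=float))
    times = np.atleast_1d(np.asarray(times, dtype=float))
    elem = np.column_stack([positions, np.zeros(len(positions))])
    diff = pts[None, :, :] - elem[:, None, :]  # (N, M, 3)
    dist = np.sqrt(np.einsum("nmk,nmk->nm", diff, diff))
    if np.any(dist == 0):
        raise ValueError("field grid contains an element position (zero distance)")
    sx, sy = np.sin(np.deg2rad(steering[0])), np.sin(np.deg2rad(steering[1]))
    tx_delay = (positions[:, 0] * sx + positions[:, 1] * sy) / c  # (N,)
    arrival = tx_delay[:, None] + dist / c
    out = np.empty((len(times), pts.shape[0]))
    for it, t in enumerate(times):
        snap = (pulse(t - arrival) / dist).sum(axis=0)
        if normalize:
            m = np.abs(snap).max()
            if m > 0:
                snap = snap / m
        out[it] = snap
    return out
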