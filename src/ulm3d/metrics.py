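"""Resolution metrics and rendering: FWHM / -20 dB widths, orthogonal tube
sections, opposing-flow peak separation, localization precision, MIPs.

Profile widths follow the linear-interpolation convention: the width at a
level is the distance between the two crossings of that level found by
linearly interpolating between the samples that straddle it on either side
of the (unique) peak; ties at the peak are broken by the centroid of the
tied plateau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EmptySectionError",
    "NotSeparableError",
    "ProfileMeasurement",
    "profile_peak",
    "width_at_rel_level",
    "fwhm",
    "width_at_level",
    "measure_profile",
    "orthogonal_section",
    "peak_to_peak_separation",
    "localization_precision",
    "sr_histogram",
    "render_mips",
    "render_depth_encoded",
]


class EmptySectionError(ValueError):
    """The requested slab contains no points."""


class NotSeparableError(ValueError):
    """The velocity profile does not contain lobes of both signs."""


@dataclass(frozen=True)
class ProfileMeasurement:
    fwhm: float
    width_20db: float
    peak_position: float
    peak_value: float


def profile_peak(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Peak position (plateau centroid) and a representative peak index."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    top = np.flatnonzero(y == y.max())
    return float(x[top].mean()), int(top[len(top) // 2])


def width_at_rel_level(x: np.ndarray, y: np.ndarray, rel_level: float) -> float:
    """Width of a unimodal profile at ``rel_level`` x peak, by interpolation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("profile needs at least 3 samples")
    _, ipk = profile_peak(x, y)
    level = rel_level * y.max()

    def _crossing(indices) -> float:
        prev = ipk
        for i in indices:
            if y[i] < level:
                # interpolate between i (below) and prev (above)
                frac = (level - y[i]) / (y[prev] - y[i])
                return float(x[i] + frac * (x[prev] - x[i]))
            prev = i
        raise ValueError("profile does not cross the level on one side")

    left = _crossing(range(ipk - 1, -1, -1))
    right = _crossing(range(ipk + 1, len(y)))
    return abs(right - left)


def fwhm(x: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum of a 1-D profile."""
    return width_at_rel_level(x, y, 0.5)


def width_at_level(x: np.ndarray, y: np.ndarray, level_db: float) -> float:
    """Width at ``level_db`` (e.g. -20) relative to the profile peak."""
    return width_at_rel_level(x, y, 10.0 ** (level_db / 20.0))


def measure_profile(x: np.ndarray, y: np.ndarray) -> ProfileMeasurement:
    peak_pos, ipk = profile_peak(x, y)
    return ProfileMeasurement(
        fwhm=fwhm(x, y),
        width_20db=width_at_level(x, y, -20.0),
        peak_position=peak_pos,
        peak_value=float(np.asarray(y)[ipk]),
    )


# ---------------------------------------------------------------------------
# Orthogonal tube sections
# ---------------------------------------------------------------------------

def _section_basis(axis_dir: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane horizontal/vertical unit vectors for a given tube axis."""
    d = np.asarray(axis_dir, dtype=float)
    d = d / np.linalg.norm(d)
    z = np.array([0.0, 0.0, 1.0])
    h = np.cross(d, z)
    if np.linalg.norm(h) < 1e-12:  # axis along depth: use the lateral plane
        h = np.array([1.0, 0.0, 0.0])
        v = np.array([0.0, 1.0, 0.0])
        return h, v
    h /= np.linalg.norm(h)
    v = np.cross(h, d)
    return h, v


def estimate_axis(points: np.ndarray) -> np.ndarray:
    """Local tube direction as the principal component of the points."""
    pts = np.atleast_2d(points)
    c = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    return vt[0]


def orthogonal_section(
    points: np.ndarray,
    axis_point: np.ndarray,
    axis_dir: np.ndarray,
    section_length: float = 0.5e-3,
    bin_size: float = 20e-6,
    smooth_bins: float = 1.0,
    extent: float | None = None,
):
    """Project a tube section onto the plane orthogonal to its axis.

    Points with axial offset s in [0, section_length) relative to
    ``axis_point`` are projected onto in-plane horizontal/vertical axes; the
    projected positions are histogrammed on a ``bin_size`` grid (optionally
    Gaussian-smoothed by ``smooth_bins`` bins, the rendering kernel of the
    super-resolved image) and 1-D maximum-intensity profiles are taken in
    both directions.

    Returns a dict with keys 'coords' (M, 2), 'image', 'h', 'v',
    'profile_h', 'profile_v'.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = np.asarray(axis_dir, dtype=float)
    d = d / np.linalg.norm(d)
    s = (pts - np.asarray(axis_point)) @ d
    sel = (s >= 0.0) & (s < section_length)
    if not sel.any():
        raise EmptySectionError("no points in the requested tube section")
    h, v = _section_basis(d)
    rel = pts[sel] - np.asarray(axis_point)
    coords = np.column_stack([rel @ h, rel @ v])
    if extent is None:
        pad = 5 * bin_size
        lo = coords.min(axis=0) - pad
        hi = coords.max(axis=0) + pad
    else:
        lo = np.array([-extent / 2.0, -extent / 2.0])
        hi = -lo
    nbins = np.maximum(np.ceil((hi - lo) / bin_size).astype(int), 3)
    edges = [lo[a] + bin_size * np.arange(nbins[a] + 1) for a in range(2)]
    image, _, _ = np.histogram2d(coords[:, 0], coords[:, 1], bins=edges)
    if smooth_bins > 0:
        from scipy.ndimage import gaussian_filter

        image = gaussian_filter(image, sigma=smooth_bins)
    centers_h = edges[0][:-1] + bin_size / 2.0
    centers_v = edges[1][:-1] + bin_size / 2.0
    return {
        "coords": coords,
        "image": image,
        "h": centers_h,
        "v": centers_v,
        "profile_h": image.max(axis=1),
        "profile_v": image.max(axis=0),
    }


# ---------------------------------------------------------------------------
# Opposing-flow peak separation
# ---------------------------------------------------------------------------

def peak_to_peak_separation(
    points: np.ndarray,
    signed_speeds: np.ndarray,
    plane_point: np.ndarray,
    plane_normal: np.ndarray,
    slab_thickness: float = 0.5e-3,
    bin_size: float = 20e-6,
    smooth_bins: float = 1.0,
) -> float:
    """Distance between the extrema of the opposing velocity lobes.

    Velocity samples within the slab around the slicing plane are projected
    onto the in-plane direction joining the centroids of the positive and
    negative lobes; the signed 1-D velocity profile (per-bin mean) is built
    at ``bin_size`` resolution and the separation is the distance between
    its maximum and minimum locations.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    v = np.asarray(signed_speeds, dtype=float)
    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    s = (pts - np.asarray(plane_point)) @ n
    sel = np.abs(s) <= slab_thickness / 2.0
    pts, v = pts[sel], v[sel]
    if pts.size == 0 or (v > 0).sum() == 0 or (v < 0).sum() == 0:
        raise NotSeparableError("slab lacks velocity lobes of both signs")
    inplane = pts - np.outer(s[sel], n)
    axis = inplane[v > 0].mean(axis=0) - inplane[v < 0].mean(axis=0)
    axis = axis / np.linalg.norm(axis)
    u = inplane @ axis
    lo, hi = u.min() - bin_size, u.max() + bin_size
    nb = max(int(np.ceil((hi - lo) / bin_size)), 3)
    idx = np.clip(((u - lo) / bin_size).astype(int), 0, nb - 1)
    vsum = np.bincount(idx, weights=v, minlength=nb)
    cnt = np.bincount(idx, minlength=nb)
    with np.errstate(invalid="ignore"):
        prof = np.where(cnt > 0, vsum / np.maximum(cnt, 1), 0.0)
    if smooth_bins > 0:
        from scipy.ndimage import gaussian_filter1d

        prof = gaussian_filter1d(prof, sigma=smooth_bins)
    centers = lo + bin_size * (np.arange(nb) + 0.5)
    if prof.max() <= 0 or prof.min() >= 0:
        raise NotSeparableError("projected profile has lobes of one sign only")
    return float(abs(centers[np.argmax(prof)] - centers[np.argmin(prof)]))


def localization_precision(positions: np.ndarray) -> dict:
    """Std of repeated localizations of a static target, per axis and worst."""
    pts = np.atleast_2d(np.asarray(positions, dtype=float))
    std = pts.std(axis=0, ddof=1)
    return {
        "std_x": float(std[0]),
        "std_y": float(std[1]),
        "std_z": float(std[2]),
        "worst": float(std.max()),
    }


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def sr_histogram(points: np.ndarray, grid) -> np.ndarray:
    """Super-resolved image as a 3-D localization-count histogram."""
    from .beamform import VoxelGrid  # noqa: F401  (typing aid)

    counts = np.zeros(grid.shape)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        return counts
    idx = np.round(grid.world_to_index(pts)).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
    np.add.at(counts, tuple(idx[ok].T), 1)
    return counts


def render_mips(volume: np.ndarray, grid, path=None, dynamic_range_db: float = 30.0):
    """Three maximum-intensity projections with a fixed dynamic range."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    amp = np.abs(volume)
    ref = amp.max() if amp.max() > 0 else 1.0
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    labels = [("y", "z"), ("x", "z"), ("x", "y")]
    for ax, axis, (l0, l1) in zip(axes, range(3), labels):
        mip = amp.max(axis=axis)
        with np.errstate(divide="ignore"):
            img = np.clip(20 * np.log10(mip / ref), -dynamic_range_db, 0)
        ax.imshow(img.T, origin="lower", cmap="gray",
                  vmin=-dynamic_range_db, vmax=0, aspect="auto")
        ax.set_xlabel(l0)
        ax.set_ylabel(l1)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def render_depth_encoded(points: np.ndarray, path=None):
    """Depth-encoded 3-D scatter of localizations (color = depth)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = np.atleast_2d(np.asarray(points, dtype=float))
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    if pts.size:
        sc = ax.scatter(pts[:, 0] * 1e3, pts[:, 1] * 1e3, pts[:, 2] * 1e3,
                        c=pts[:, 2] * 1e3, s=2, cmap="viridis")
        fig.colorbar(sc, ax=ax, label="depth (mm)")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_zlabel("z (mm)")
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
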