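"""Frame-to-frame nearest-neighbor microbubble tracking and velocity mapping.

Detections in consecutive frames are paired greedily by ascending Euclidean
distance under two gates: a search window allowing at most 100 mm/s, and a
size-consistency rule rejecting candidate pairs whose above-threshold echo
volumes deviate by more than 50% (the next-closest candidate is then tried).
Each accepted pair's speed is displacement x frame rate, signed by the
y-component of the displacement, and deposited at the pair midpoint on a
fine velocity grid where co-located samples are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beamform import VoxelGrid
from .localize import Detection

__all__ = [
    "Pair",
    "VelocityMap",
    "volume_deviation",
    "pair_frames",
    "pair_sequence",
    "accumulate_velocity_map",
    "track_statistics",
    "participation_from_counts",
    "pairs_to_frame",
]

#: Default search-window speed limit (m/s).
V_MAX_DEFAULT = 100e-3
#: Default maximum relative deviation of echo volumes within a pair.
VOLUME_DEV_DEFAULT = 0.5


@dataclass(frozen=True)
class Pair:
    """An accepted frame-to-frame pairing with its velocity estimate."""

    frame: int
    det_a: Detection
    det_b: Detection
    displacement: tuple[float, float, float]
    speed: float
    signed_speed: float

    @property
    def midpoint(self) -> np.ndarray:
        return (np.asarray(self.det_a.position) + np.asarray(self.det_b.position)) / 2.0


def volume_deviation(v_earlier: float, v_later: float, symmetric: bool = False) -> float:
    """Relative echo-volume deviation between the two frames of a pair.

    Default convention normalizes by the earlier frame's volume; the
    symmetric option normalizes by the mean.
    """
    if v_earlier <= 0:
        raise ValueError("reference echo volume must be positive")
    if symmetric:
        return abs(v_earlier - v_later) / ((v_earlier + v_later) / 2.0)
    return abs(v_earlier - v_later) / v_earlier


def pair_frames(
    dets_n: list[Detection],
    dets_n1: list[Detection],
    frame_rate: float,
    v_max: float = V_MAX_DEFAULT,
    max_volume_dev: float = VOLUME_DEV_DEFAULT,
    symmetric_dev: bool = False,
) -> list[Pair]:
    """Pair detections of frame n with frame n+1.

    Candidates within the search radius v_max / frame_rate are visited in
    ascending distance; a candidate is accepted when both endpoints are
    unassigned and the echo volumes agree within ``max_volume_dev``.  A
    rejected nearest candidate is thereby replaced by the next-closest one
    that passes the same size comparison.  The assignment is one-to-one.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if not dets_n or not dets_n1:
        return []
    pa = np.array([d.position for d in dets_n])
    pb = np.array([d.position for d in dets_n1])
    dist = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    radius = v_max / frame_rate
    ii, jj = np.nonzero(dist <= radius)
    order = np.argsort(dist[ii, jj], kind="stable")
    used_a = np.zeros(len(dets_n), dtype=bool)
    used_b = np.zeros(len(dets_n1), dtype=bool)
    pairs: list[Pair] = []
    for k in order:
        i, j = ii[k], jj[k]
        if used_a[i] or used_b[j]:
            continue
        dev = volume_deviation(
            dets_n[i].region_volume, dets_n1[j].region_volume, symmetric_dev
        )
        if dev > max_volume_dev:
            continue
        used_a[i] = used_b[j] = True
        disp = pb[j] - pa[i]
        speed = float(np.linalg.norm(disp) * frame_rate)
        sign = 1.0 if disp[1] >= 0 else -1.0
        pairs.append(
            Pair(
                frame=dets_n[i].frame,
                det_a=dets_n[i],
                det_b=dets_n1[j],
                displacement=tuple(float(v) for v in disp),
                speed=speed,
                signed_speed=sign * speed,
            )
        )
    return pairs


def pair_sequence(
    detections_by_frame: dict[int, list[Detection]],
    frame_rate: float,
    v_max: float = V_MAX_DEFAULT,
    max_volume_dev: float = VOLUME_DEV_DEFAULT,
) -> list[Pair]:
    """Pair every consecutive frame transition of a detection sequence."""
    pairs: list[Pair] = []
    frames = sorted(detections_by_frame)
    for f in frames:
        if f + 1 in detections_by_frame:
            pairs.extend(
                pair_frames(
                    detections_by_frame[f],
                    detections_by_frame[f + 1],
                    frame_rate,
                    v_max=v_max,
                    max_volume_dev=max_volume_dev,
                )
            )
    return pairs


@dataclass
class VelocityMap:
    """Per-cell mean signed velocity with sample counts on a regular grid."""

    grid: VoxelGrid
    velocity_sum: np.ndarray
    counts: np.ndarray

    @property
    def mean_velocity(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.counts > 0, self.velocity_sum / self.counts, np.nan)


def accumulate_velocity_map(pairs: list[Pair], grid: VoxelGrid) -> VelocityMap:
    """Deposit each pair's signed speed at its midpoint cell; cells average."""
    vsum = np.zeros(grid.shape)
    counts = np.zeros(grid.shape, dtype=int)
    for p in pairs:
        idx = np.round(grid.world_to_index(p.midpoint)[0]).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(grid.shape)):
            continue
        vsum[tuple(idx)] += p.signed_speed
        counts[tuple(idx)] += 1
    return VelocityMap(grid=grid, velocity_sum=vsum, counts=counts)


def participation_from_counts(n_localizations: int, n_pairs: int) -> float:
    """Tracking percentage when each pair links two distinct localizations."""
    if n_localizations == 0:
        return 0.0
    return min(100.0, 200.0 * n_pairs / n_localizations)


def track_statistics(
    detections_by_frame: dict[int, list[Detection]], pairs: list[Pair]
) -> dict:
    """Summary of localization and tracking yield.

    Reports the localization and pair counts, the percentage of
    localizations participating in at least one pair, and the per-frame
    localization histogram.
    """
    n_loc = sum(len(v) for v in detections_by_frame.values())
    participants = set()
    for p in pairs:
        participants.add(id(p.det_a))
        participants.add(id(p.det_b))
    pct = 100.0 * len(participants) / n_loc if n_loc else 0.0
    hist = {f: len(v) for f, v in sorted(detections_by_frame.items())}
    counts = np.array(list(hist.values())) if hist else np.zeros(0)
    return {
        "n_localizations": n_loc,
        "n_pairs": len(pairs),
        "participation_pct": pct,
        "participation_from_counts_pct": participation_from_counts(n_loc, len(pairs)),
        "localizations_per_frame_mean": float(counts.mean()) if counts.size else 0.0,
        "localizations_per_frame": hist,
    }


def pairs_to_frame(pairs: list[Pair]) -> pd.DataFrame:
    """Tabulate pairs as a pandas DataFrame (positions in m, speed in mm/s)."""
    return pd.DataFrame(
        {
            "frame": [p.frame for p in pairs],
            "x0_m": [p.det_a.position[0] for p in pairs],
            "y0_m": [p.det_a.position[1] for p in pairs],
            "z0_m": [p.det_a.position[2] for p in pairs],
            "x1_m": [p.det_b.position[0] for p in pairs],
            "y1_m": [p.det_b.position[1] for p in pairs],
            "z1_m": [p.det_b.position[2] for p in pairs],
            "speed_mm_s": [p.speed * 1e3 for p in pairs],
            "signed_speed_mm_s": [p.signed_speed * 1e3 for p in pairs],
        }
    )
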