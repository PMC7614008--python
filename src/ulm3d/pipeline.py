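"""End-to-end pipeline orchestration, configuration, and file I/O.

One YAML-serializable configuration drives the whole chain:

    design -> simulate -> (beamform) -> SVD filter -> ASAP -> threshold
           -> localize -> track -> velocity map -> metrics

All randomness flows from the single ``seed``; rerunning a config reproduces
identical outputs.  Stage products are written as CSV (tables), HDF5
(volume sequences, with axis spacing metadata), and JSON (metrics, singular
value spectra, provenance).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import array_design, clutter, localize, metrics, phantom, track
from .beamform import (
    AcousticMedium,
    TransmitScheme,
    VoxelGrid,
    beamform_frame,
)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "save_volume_sequence",
    "load_volume_sequence",
]

log = logging.getLogger("ulm3d")


@dataclass
class PipelineConfig:
    """All tunable parameters of the processing chain (SI units)."""

    seed: int = 0
    mode: str = "psf"  # 'psf' (fast surrogate) or 'rf' (channel synthesis)
    mean_velocity: float = 44e-3
    n_frames: int = 600
    # phantom geometry / population
    tube_diameter: float = 200e-6
    depth: float = 25e-3
    tube_length: float = 10e-3
    helix_pitch: float = 5e-3
    end_radius: float = 500e-6
    contact_half_length: float = 2.5e-3
    injection_rate: float = 4.5
    destruction_prob: float = 5e-4
    amplitude_sigma: float = 0.2
    radius_fraction: float = 0.75
    # imaging
    psf_fwhm: tuple[float, float, float] = (793e-6, 772e-6, 499e-6)
    voxel_size: float = 100e-6
    grid_extent: tuple[float, float, float] = (2.6e-3, 11e-3, 2.6e-3)
    clutter_amplitude: float = 0.5
    noise_sigma: float = 0.005
    # clutter filtering
    svd_low: int = 1
    svd_high: int | None = None
    asap_window: int = 2
    threshold_db: float = -6.0
    # localization / tracking
    localization_method: str = "core_centroid"
    core_level: float = 0.7
    min_volume_factor: float = 0.05
    v_max: float = 100e-3
    max_volume_dev: float = 0.5
    sr_bin: float = 20e-6
    # outputs
    write_volumes: bool = False

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[f.name] = v
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- derived stage objects -------------------------------------------
    def phantom_spec(self) -> phantom.PhantomSpec:
        return phantom.PhantomSpec(
            depth=self.depth,
            tube_diameter=self.tube_diameter,
            tube_length=self.tube_length,
            helix_pitch=self.helix_pitch,
            end_radius=self.end_radius,
            contact_half_length=self.contact_half_length,
        )

    def voxel_grid(self) -> VoxelGrid:
        return VoxelGrid.centered(
            center=(0.0, 0.0, self.depth),
            extent=self.grid_extent,
            spacing=(self.voxel_size,) * 3,
        )


def save_volume_sequence(path, data: np.ndarray, grid: VoxelGrid,
                         frame_rate: float) -> None:
    """Write a volume sequence as HDF5 with (frame, z, y, x) axis order."""
    import h5py

    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset(
            "volumes", data=np.transpose(data, (0, 3, 2, 1)), compression="gzip"
        )
        ds.attrs["axes"] = "frame,z,y,x"
        ds.attrs["origin_m"] = grid.origin
        ds.attrs["spacing_m"] = grid.spacing
        ds.attrs["frame_rate_hz"] = frame_rate


def load_volume_sequence(path):
    import h5py

    with h5py.File(path, "r") as fh:
        ds = fh["volumes"]
        data = np.transpose(ds[...], (0, 3, 2, 1))
        grid = VoxelGrid(
            origin=tuple(ds.attrs["origin_m"]),
            spacing=tuple(ds.attrs["spacing_m"]),
            shape=data.shape[1:],
        )
        return data, grid, float(ds.attrs["frame_rate_hz"])


def _beamform_sequences(cfg, traj, spec, layout, scheme, medium, grid):
    """RF route: synthesize channels per frame, beamform each aperture."""
    seqs = {1: [], 2: []}
    for f in range(cfg.n_frames):
        sub = traj[traj["frame"] == f]
        pts = sub[["x", "y", "z"]].to_numpy()
        amps = sub["amplitude"].to_numpy()
        for ap in (1, 2):
            pos = layout.positions(ap)
            if len(pts):
                ch = phantom.synthesize_rf(pts, amps, pos, scheme, medium)
                vol = beamform_frame(ch, grid, medium)
            else:
                vol = np.zeros(grid.shape, dtype=complex)
            seqs[ap].append(vol)
    return (np.stack(seqs[1]).astype(np.complex64),
            np.stack(seqs[2]).astype(np.complex64))


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute the full chain and write stage outputs under ``outdir``.

    Returns a results dict with the detections/pairs tables, velocity map,
    and the metrics summary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    rng = np.random.default_rng(cfg.seed)
    scheme = TransmitScheme()
    medium = AcousticMedium()
    frame_rate = scheme.volume_rate

    log.info("stage design: spiral apertures (config %s)", cfg.config_hash())
    layout = array_design.design_apertures()
    layout.to_csv(outdir / "array_layout.csv")

    spec = cfg.phantom_spec()
    flow = phantom.FlowSpec(mean_velocity=cfg.mean_velocity)
    pop = phantom.BubblePopulation(
        injection_rate=cfg.injection_rate,
        destruction_prob=cfg.destruction_prob,
        amplitude_sigma=cfg.amplitude_sigma,
        radius_fraction=cfg.radius_fraction,
    )
    log.info("stage simulate: %d frames at %.0f Hz", cfg.n_frames, frame_rate)
    traj = phantom.simulate_bubbles(
        spec, flow, pop, cfg.n_frames, frame_rate, rng,
        pulses_per_frame=scheme.n_angles,
    )
    traj.to_csv(outdir / "ground_truth_tracks.csv", index=False)

    grid = cfg.voxel_grid()
    psf = phantom.PSFModel(fwhm=cfg.psf_fwhm)
    if cfg.mode == "psf":
        seq_a, seq_b = phantom.render_volume_psf(
            traj, psf, grid, cfg.n_frames, frame_rate, rng,
            spec=spec, clutter_amplitude=cfg.clutter_amplitude,
            noise_sigma=cfg.noise_sigma,
        )
    elif cfg.mode == "rf":
        seq_a, seq_b = _beamform_sequences(cfg, traj, spec, layout, scheme,
                                           medium, grid)
    else:
        raise ValueError(f"unknown mode {cfg.mode!r}")

    log.info("stage filter: SVD [%d, %s) then ASAP window %d",
             cfg.svd_low, cfg.svd_high, cfg.asap_window)
    spectra = {
        "aperture1": clutter.singular_values(seq_a, n_values=32).tolist(),
        "aperture2": clutter.singular_values(seq_b, n_values=32).tolist(),
    }
    with open(outdir / "singular_values.json", "w") as fh:
        json.dump(spectra, fh)
    # overwrite in place so only one extra sequence is alive at a time
    seq_a = clutter.svd_filter(seq_a, cfg.svd_low, cfg.svd_high)
    seq_b = clutter.svd_filter(seq_b, cfg.svd_low, cfg.svd_high)
    combined = clutter.asap_combine(seq_a, seq_b, cfg.asap_window)
    del seq_a, seq_b
    if cfg.write_volumes:
        save_volume_sequence(outdir / "combined.h5", combined, grid, frame_rate)

    # robust amplitude reference: the median of per-frame maxima tracks the
    # typical microbubble echo and is insensitive to one unusually bright
    # bubble, unlike the global sequence maximum
    frame_max = combined.reshape(cfg.n_frames, -1).max(axis=1)  # ASAP output >= 0
    ref = float(max(np.median(frame_max), 0.25 * frame_max.max()))
    level_rel = 10.0 ** (cfg.threshold_db / 20.0)
    psf_ref = localize.psf_volume_from_fwhm(cfg.psf_fwhm, level_rel)
    log.info("stage localize: threshold %.0f dB re sequence max", cfg.threshold_db)
    dets_by_frame: dict[int, list] = {}
    for f in range(cfg.n_frames):
        vol = combined[f]
        mask = clutter.intensity_threshold(vol, cfg.threshold_db, ref=ref)
        dets = localize.localize_volume(vol, mask, grid, frame=f,
                                        method=cfg.localization_method,
                                        core_level=cfg.core_level)
        # below-threshold flicker produces few-voxel fragments; a genuine
        # microbubble echo cannot be much smaller than the PSF level set
        vmin = cfg.min_volume_factor * psf_ref.psf_volume
        dets = [d for d in dets if d.region_volume >= vmin]
        dets_by_frame[f] = localize.reject_multibubble(dets, psf_ref)
    all_dets = [d for v in dets_by_frame.values() for d in v]
    localize.detections_to_frame(all_dets).to_csv(
        outdir / "detections.csv", index=False)

    log.info("stage track: v_max %.0f mm/s", cfg.v_max * 1e3)
    pairs = track.pair_sequence(dets_by_frame, frame_rate,
                                v_max=cfg.v_max, max_volume_dev=cfg.max_volume_dev)
    track.pairs_to_frame(pairs).to_csv(outdir / "pairs.csv", index=False)
    sr_grid = VoxelGrid.centered(
        center=(0.0, 0.0, cfg.depth),
        extent=cfg.grid_extent,
        spacing=(cfg.sr_bin,) * 3,
    )
    vmap = track.accumulate_velocity_map(pairs, sr_grid)

    results = {
        "layout": layout,
        "trajectories": traj,
        "detections_by_frame": dets_by_frame,
        "detections": all_dets,
        "pairs": pairs,
        "velocity_map": vmap,
        "grid": grid,
        "combined_max": ref,
    }
    summary = summarize(cfg, spec, results)
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    results["metrics"] = summary
    return results


def summarize(cfg: PipelineConfig, spec, results) -> dict:
    """Resolution and tracking metrics of one pipeline run."""
    stats = track.track_statistics(results["detections_by_frame"], results["pairs"])
    out = {
        "config_hash": cfg.config_hash(),
        "n_localizations": stats["n_localizations"],
        "n_pairs": stats["n_pairs"],
        "participation_pct": stats["participation_pct"],
        "localizations_per_frame_mean": stats["localizations_per_frame_mean"],
    }
    dets = results["detections"]
    pts = np.array([d.position for d in dets]) if dets else np.zeros((0, 3))

    # super-resolved tube width, measured on 0.5-mm sections of the tube
    # ends, where the flare isolates the two tubes.  Individual sections of
    # a short acquisition see only a handful of distinct bubbles, so the
    # projected sections of both tubes' isolated ends are pooled (in
    # tube-local cross-section coordinates) into one image before the MIP
    # profiles are measured.
    fwhms, w20s = [], []
    pooled = []
    for tube in (0, 1):
        for y0 in (3.5e-3, 4.0e-3, 4.5e-3):
            for sgn in (-1.0, 1.0):
                ys = sgn * y0 - (0.5e-3 if sgn > 0 else 0.0)
                axis_point = phantom.helix_centerline(spec, ys, tube)[0]
                axis_dir = phantom.helix_frame(spec, ys, tube)[0][0]
                try:
                    sec = metrics.orthogonal_section(
                        pts, axis_point, axis_dir, bin_size=cfg.sr_bin,
                        extent=0.8e-3,
                    )
                except metrics.EmptySectionError:
                    continue
                keep = np.linalg.norm(sec["coords"], axis=1) < 0.3e-3
                pooled.append(sec["coords"][keep])
    if pooled:
        coords = np.concatenate(pooled)
        if len(coords) >= 30:
            image, hh, vv = np.histogram2d(
                coords[:, 0], coords[:, 1],
                bins=[np.arange(-0.4e-3, 0.4e-3, cfg.sr_bin)] * 2,
            )
            from scipy.ndimage import gaussian_filter

            image = gaussian_filter(image, sigma=1.0)
            ch = hh[:-1] + cfg.sr_bin / 2.0
            for prof in (image.max(axis=1), image.max(axis=0)):
                try:
                    fwhms.append(metrics.fwhm(ch, prof))
                    w20s.append(metrics.width_at_level(ch, prof, -20.0))
                except ValueError:
                    pass
        out["sr_section_points"] = int(len(coords))
    out["sr_fwhm_um"] = float(np.mean(fwhms) * 1e6) if fwhms else None
    out["sr_width20_um"] = float(np.mean(w20s) * 1e6) if w20s else None

    # opposing-flow separation, pooled over the whole contact region: each
    # velocity sample is projected onto the local inter-tube axis at its own
    # axial position, and the separation is the distance between the
    # velocity-weighted centroids of the positive- and negative-flow lobes.
    # A single 0.5-mm slab of a short acquisition holds too few distinct
    # bubble transits for a stable per-slab profile.
    pairs = results["pairs"]
    if pairs:
        mids = np.array([p.midpoint for p in pairs])
        speeds = np.array([p.signed_speed for p in pairs])
        sel = np.abs(mids[:, 1]) <= 0.9 * spec.contact_half_length
        m, vv = mids[sel], speeds[sel]
        out["peak_to_peak_um"] = None
        if len(m) and (vv > 0).any() and (vv < 0).any():
            c0 = phantom.helix_centerline(spec, m[:, 1], 0)
            c1 = phantom.helix_centerline(spec, m[:, 1], 1)
            axis = c0 - c1
            axis /= np.linalg.norm(axis, axis=1, keepdims=True)
            u = np.einsum("ij,ij->i", m - (c0 + c1) / 2, axis)
            wp, wn = np.clip(vv, 0, None), np.clip(-vv, 0, None)
            sep = (u * wp).sum() / wp.sum() - (u * wn).sum() / wn.sum()
            out["peak_to_peak_um"] = float(sep * 1e6)
            out["peak_to_peak_n_samples"] = int(sel.sum())
        sp = np.abs(speeds)
        out["speed_mm_s_mean"] = float(sp.mean() * 1e3)
        out["speed_mm_s_p95"] = float(np.percentile(sp, 95) * 1e3)
    else:
        out["peak_to_peak_um"] = None
    return out
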