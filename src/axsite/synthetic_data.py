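"""Synthetic photometry sessions, synaptosome fields, and axon volumes.

Every generator returns both the rendered data and a :class:`GroundTruth`
record, so the downstream processing stages (``photometry``, ``puncta2d``,
``puncta3d``) can be validated against known truth without any microscope or
rig recordings.  All randomness is drawn from a single ``numpy`` generator
seeded per call; identical configurations and seeds give bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

__all__ = [
    "PhotometrySimConfig",
    "PunctaSimConfig3D",
    "SynaptosomeSimConfig",
    "ParticleClass",
    "GroundTruth",
    "PhotometryRecording",
    "LabeledField2D",
    "LabeledVolume3D",
    "evoked_kernel",
    "simulate_photometry_session",
    "simulate_axon_volume",
    "simulate_synaptosome_field",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class PhotometryRecording:
    """Raw multiplexed photometry session at the acquisition rate.

    ``mux`` is the excitation-multiplexing square wave (1 = 470-nm phase,
    0 = 405-nm isosbestic phase); ``trig`` is 1 during each optogenetic
    stimulation light-on window.
    """

    sample_rate_hz: float
    time_s: np.ndarray
    fluor: np.ndarray
    mux: np.ndarray
    trig: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time_s)
        if not (len(self.fluor) == len(self.mux) == len(self.trig) == n):
            raise ValueError("time_s, fluor, mux, trig must have equal length")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")


@dataclass
class LabeledField2D:
    """Multi-channel 2D image (synaptosome field) with pixel calibration."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    labels: list[dict] | None = None

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")


@dataclass
class LabeledVolume3D:
    """Multi-channel 3D volume with (z, y, x) voxel calibration in microns."""

    channels: dict[str, np.ndarray]
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be > 0")


@dataclass
class GroundTruth:
    """What the generator actually rendered.

    Only the fields relevant to the producing generator are populated.
    """

    # photometry
    true_evoked_amplitudes_pct: np.ndarray | None = None
    stim_onsets_s: np.ndarray | None = None
    # 3D volumes
    true_blob_centroids_um: np.ndarray | None = None  # (n, 3) in (z, y, x)
    true_blob_volumes_um3: np.ndarray | None = None
    true_blob_host: list | None = None  # axon channel name or None per blob
    true_axon_length_um: dict | None = None  # per axon channel
    true_axon_masks: dict | None = None
    # 2D fields
    particle_labels: list | None = None  # dicts: center, radius_px, th/vamp2/bassoon


# ---------------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------------


@dataclass
class PhotometrySimConfig:
    """Conditions of a simulated dual-wavelength photometry session.

    Defaults mirror the in-vivo recording design: 2-kHz acquisition with the
    two excitation wavelengths alternated at 100 Hz (full cycle), 0.5-s
    optogenetic pulse trains delivered 20 s apart and repeated 8 times.
    """

    duration_s: float = 172.0
    sample_rate_hz: float = 2000.0
    mux_rate_hz: float = 100.0
    stim_onsets_s: Sequence[float] = tuple(20.0 * (k + 1) for k in range(8))
    stim_duration_s: float = 0.5
    evoked_amplitude_pct: float = 10.0
    tau_rise_s: float = 0.08
    tau_decay_s: float = 0.4
    bleach_tau_s: float = 2000.0
    background_fraction: float = 0.1
    motion_amplitude: float = 0.0
    noise_sd: float = 1.0
    f0_470: float = 100.0
    f0_405: float = 80.0
    seed: int = 0

    def validate(self) -> None:
        if self.sample_rate_hz <= 0 or self.mux_rate_hz <= 0:
            raise ValueError("rates must be > 0")
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background_fraction must be in [0, 1)")
        spp = self.sample_rate_hz / (2.0 * self.mux_rate_hz)
        if abs(spp - round(spp)) > 1e-9 or round(spp) < 1:
            raise ValueError("sample_rate_hz must be an even multiple of mux_rate_hz")
        on = np.asarray(self.stim_onsets_s, dtype=float)
        if on.size:
            if np.any(np.diff(on) < self.stim_duration_s):
                raise ValueError(
                    "stimulation onsets must be strictly increasing and "
                    "separated by at least stim_duration_s (overlap)"
                )
            if on[0] < 0 or on[-1] + self.stim_duration_s > self.duration_s:
                raise ValueError("stimulations must fit inside the record")


def evoked_kernel(t: np.ndarray, tau_rise_s: float, tau_decay_s: float) -> np.ndarray:
    """Difference-of-exponentials indicator transient, normalized to peak 1.

    ``h(t) = (1 - exp(-t/tau_r)) * exp(-t/tau_d)`` for t >= 0, the standard
    kinetic form for a fluorescent sensor with finite rise and decay.
    """
    t = np.asarray(t, dtype=float)
    h = np.where(t >= 0, (1.0 - np.exp(-np.maximum(t, 0) / tau_rise_s)) * np.exp(-np.maximum(t, 0) / tau_decay_s), 0.0)
    t_peak = tau_rise_s * math.log1p(tau_decay_s / tau_rise_s)
    h_peak = (1.0 - math.exp(-t_peak / tau_rise_s)) * math.exp(-t_peak / tau_decay_s)
    return h / h_peak


def simulate_photometry_session(cfg: PhotometrySimConfig) -> tuple[PhotometryRecording, GroundTruth]:
    """Render a raw 2-kHz multiplexed session.

    470-phase samples carry ``F0 * bleach * (1 + evoked)``; 405-phase samples
    carry ``F0 * bleach`` with NO evoked component.  A common low-frequency
    motion term and an additive non-sensor background are injected into both
    phases, followed by white Gaussian noise.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.sample_rate_hz))
    t = np.arange(n) / cfg.sample_rate_hz

    if math.isfinite(cfg.bleach_tau_s):
        bleach = np.exp(-t / cfg.bleach_tau_s)
    else:
        bleach = np.ones_like(t)

    onsets = np.asarray(cfg.stim_onsets_s, dtype=float)
    amps = np.full(onsets.shape, cfg.evoked_amplitude_pct, dtype=float)
    evoked = np.zeros_like(t)
    for onset, amp in zip(onsets, amps):
        i0 = int(round(onset * cfg.sample_rate_hz))
        # render the transient over ~8 decay constants
        i1 = min(n, i0 + int(round(8 * (cfg.tau_rise_s + cfg.tau_decay_s) * cfg.sample_rate_hz)))
        evoked[i0:i1] += (amp / 100.0) * evoked_kernel(t[i0:i1] - onset, cfg.tau_rise_s, cfg.tau_decay_s)

    # shared low-frequency motion artifact (0.2-2 Hz random sinusoids)
    if cfg.motion_amplitude > 0:
        freqs = rng.uniform(0.2, 2.0, size=4)
        phases = rng.uniform(0, 2 * np.pi, size=4)
        weights = rng.uniform(0.5, 1.0, size=4)
        weights /= np.linalg.norm(weights)
        motion = cfg.motion_amplitude * np.sum(
            [w * np.sin(2 * np.pi * f * t + p) for f, p, w in zip(freqs, phases, weights)], axis=0
        )
    else:
        motion = np.zeros_like(t)

    f = cfg.background_fraction
    bg470 = f / (1.0 - f) * cfg.f0_470
    bg405 = f / (1.0 - f) * cfg.f0_405

    f470 = bg470 + cfg.f0_470 * bleach * (1.0 + evoked) + motion
    f405 = bg405 + cfg.f0_405 * bleach + motion

    spp = int(round(cfg.sample_rate_hz / (2.0 * cfg.mux_rate_hz)))
    cycle = np.concatenate([np.ones(spp), np.zeros(spp)])
    mux = np.tile(cycle, n // (2 * spp) + 1)[:n]

    fluor = np.where(mux == 1, f470, f405)
    if cfg.noise_sd > 0:
        fluor = fluor + rng.normal(0.0, cfg.noise_sd, size=n)

    trig = np.zeros(n)
    for onset in onsets:
        i0 = int(round(onset * cfg.sample_rate_hz))
        i1 = min(n, i0 + int(round(cfg.stim_duration_s * cfg.sample_rate_hz)))
        trig[i0:i1] = 1.0

    rec = PhotometryRecording(
        sample_rate_hz=cfg.sample_rate_hz,
        time_s=t,
        fluor=fluor,
        mux=mux,
        trig=trig,
        metadata={"seed": cfg.seed},
    )
    gt = GroundTruth(true_evoked_amplitudes_pct=amps, stim_onsets_s=onsets)
    return rec, gt


# ---------------------------------------------------------------------------
# 3D axon volumes
# ---------------------------------------------------------------------------


@dataclass
class PunctaSimConfig3D:
    """Conditions of a simulated striatal axon volume.

    Two axon channels ("axonA", "axonB"), each a constant-radius tube along a
    smooth random polyline, plus one punctum channel with on-axon blobs at
    ``puncta_density_per_um`` per micron of axon and uniform background blobs
    at ``off_axon_puncta_per_um3``.  Blobs are isotropic Gaussians whose
    half-maximum volume equals the drawn true volume (the point-spread blur
    is folded into the rendered width).
    """

    shape_vox: tuple[int, int, int] = (16, 256, 256)
    voxel_size_um: tuple[float, float, float] = (0.2, 0.05, 0.05)
    axon_count: int = 2
    axon_radius_um: float = 0.3
    axon_length_um: float = 12.0
    puncta_density_per_um: float = 0.4
    off_axon_puncta_per_um3: float = 0.05
    blob_volume_um3_range: tuple[float, float] = (0.004, 0.009)
    blob_min_separation_um: float = 0.4
    blob_radial_jitter_um: float = 0.05
    psf_sigma_um: float = 0.06
    snr: float = 10.0
    axon_intensity: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be > 0")
        if self.puncta_density_per_um < 0 or self.off_axon_puncta_per_um3 < 0:
            raise ValueError("densities must be >= 0")
        vmin, vmax = self.blob_volume_um3_range
        if not (0 < vmin <= vmax):
            raise ValueError("blob volume range must be positive and ordered")
        if self.axon_count not in (1, 2):
            raise ValueError("axon_count must be 1 or 2")
        extent = [s * v for s, v in zip(self.shape_vox, self.voxel_size_um)]
        margin = self.axon_radius_um + 0.3
        if extent[1] < 4 * margin or extent[2] < 4 * margin or extent[0] < 2 * margin:
            raise ValueError("axon geometry does not fit in the volume")


def _random_polyline(
    rng: np.random.Generator,
    extent_um: tuple[float, float, float],
    length_um: float,
    y_range: tuple[float, float],
    margin_um: float,
) -> np.ndarray:
    """Smooth random polyline (z, y, x) confined to a y-band of the volume."""
    step = 0.2
    z_mid = extent_um[0] / 2.0
    y0 = rng.uniform(y_range[0] + margin_um, y_range[1] - margin_um)
    x0 = rng.uniform(margin_um, margin_um + 0.1 * extent_um[2])
    pts = [np.array([z_mid, y0, x0])]
    theta = rng.uniform(-0.3, 0.3)  # heading in the xy plane, ~ +x
    n_steps = int(round(length_um / step))
    for _ in range(n_steps):
        theta += rng.normal(0.0, 0.08)
        z, y, x = pts[-1]
        # steer back toward the allowed band near boundaries
        xc, yc = extent_um[2] / 2.0, 0.5 * (y_range[0] + y_range[1])
        nxt = np.array(
            [
                z + rng.normal(0.0, 0.01),
                y + step * math.sin(theta),
                x + step * math.cos(theta),
            ]
        )
        if not (margin_um < nxt[2] < extent_um[2] - margin_um) or not (
            y_range[0] + margin_um < nxt[1] < y_range[1] - margin_um
        ):
            theta = math.atan2(yc - y, xc - x) + rng.normal(0.0, 0.1)
            nxt = np.array(
                [
                    z + rng.normal(0.0, 0.01),
                    y + step * math.sin(theta),
                    x + step * math.cos(theta),
                ]
            )
        nxt[0] = min(max(nxt[0], margin_um), extent_um[0] - margin_um)
        pts.append(nxt)
    return np.array(pts)


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def _tube_mask(
    shape_vox: tuple[int, int, int],
    voxel_size_um: tuple[float, float, float],
    polyline: np.ndarray,
    radius_um: float,
) -> np.ndarray:
    """Boolean mask of voxels whose center lies within ``radius_um`` of the polyline."""
    vz, vy, vx = voxel_size_um
    lo = polyline.min(axis=0) - radius_um
    hi = polyline.max(axis=0) + radius_um
    iz0 = max(int(lo[0] / vz) - 1, 0)
    iz1 = min(int(hi[0] / vz) + 2, shape_vox[0])
    iy0 = max(int(lo[1] / vy) - 1, 0)
    iy1 = min(int(hi[1] / vy) + 2, shape_vox[1])
    ix0 = max(int(lo[2] / vx) - 1, 0)
    ix1 = min(int(hi[2] / vx) + 2, shape_vox[2])
    zz, yy, xx = np.meshgrid(
        (np.arange(iz0, iz1) + 0.5) * vz,
        (np.arange(iy0, iy1) + 0.5) * vy,
        (np.arange(ix0, ix1) + 0.5) * vx,
        indexing="ij",
    )
    coords = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
    # densify the polyline so chord error is negligible vs the voxel size
    seg = np.diff(polyline, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    dense = [polyline[0]]
    for p, s, L in zip(polyline[:-1], seg, seglen):
        k = max(int(math.ceil(L / (0.4 * min(voxel_size_um)))), 1)
        for j in range(1, k + 1):
            dense.append(p + s * j / k)
    tree = cKDTree(np.array(dense))
    dist, _ = tree.query(coords, workers=-1)
    sub = (dist <= radius_um).reshape(zz.shape)
    mask = np.zeros(shape_vox, dtype=bool)
    mask[iz0:iz1, iy0:iy1, ix0:ix1] = sub
    return mask


def _render_blob(
    vol: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    center_um: np.ndarray,
    sigma_um: float,
    amplitude: float,
) -> None:
    """Add an isotropic (physical units) Gaussian blob in place."""
    vz, vy, vx = voxel_size_um
    r = 4.0 * sigma_um
    iz0 = max(int((center_um[0] - r) / vz), 0)
    iz1 = min(int((center_um[0] + r) / vz) + 2, vol.shape[0])
    iy0 = max(int((center_um[1] - r) / vy), 0)
    iy1 = min(int((center_um[1] + r) / vy) + 2, vol.shape[1])
    ix0 = max(int((center_um[2] - r) / vx), 0)
    ix1 = min(int((center_um[2] + r) / vx) + 2, vol.shape[2])
    z = (np.arange(iz0, iz1) + 0.5) * vz - center_um[0]
    y = (np.arange(iy0, iy1) + 0.5) * vy - center_um[1]
    x = (np.arange(ix0, ix1) + 0.5) * vx - center_um[2]
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    vol[iz0:iz1, iy0:iy1, ix0:ix1] += amplitude * np.exp(
        -(zz**2 + yy**2 + xx**2) / (2.0 * sigma_um**2)
    )


_HALF_MAX = math.sqrt(2.0 * math.log(2.0))  # half-max radius of a Gaussian, in sigmas


def _sigma_for_volume(volume_um3: float) -> float:
    """Gaussian sigma whose half-maximum isosurface encloses ``volume_um3``."""
    r_half = (3.0 * volume_um3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    return r_half / _HALF_MAX


def simulate_axon_volume(cfg: PunctaSimConfig3D) -> tuple[LabeledVolume3D, GroundTruth]:
    """Render axon tube channels plus a punctum channel with known truth.

    On-axon blob count per channel is ``round(density * true length)`` exactly;
    blob centers sit near the tube axis with at least
    ``blob_min_separation_um`` of arclength between neighbours.  Background
    blobs are uniform over the volume and carry host ``None``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    vz, vy, vx = cfg.voxel_size_um
    extent = tuple(s * v for s, v in zip(cfg.shape_vox, cfg.voxel_size_um))
    margin = cfg.axon_radius_um + 0.3

    noise_scale = cfg.noise_sd if cfg.noise_sd > 0 else 1.0
    names = ["axonA", "axonB"][: cfg.axon_count]
    bands = (
        [(0.0, extent[1])]
        if cfg.axon_count == 1
        else [(0.0, extent[1] / 2.0), (extent[1] / 2.0, extent[1])]
    )

    channels: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    lengths: dict[str, float] = {}
    polylines: dict[str, np.ndarray] = {}
    for name, band in zip(names, bands):
        poly = _random_polyline(rng, extent, cfg.axon_length_um, band, margin)
        mask = _tube_mask(cfg.shape_vox, cfg.voxel_size_um, poly, cfg.axon_radius_um)
        clean = mask.astype(float) * cfg.axon_intensity * cfg.snr * noise_scale
        sigma_vox = [cfg.psf_sigma_um / v for v in cfg.voxel_size_um]
        clean = gaussian_filter(clean, sigma_vox)
        channels[name] = clean
        masks[name] = mask
        lengths[name] = _polyline_length(poly)
        polylines[name] = poly

    puncta = np.zeros(cfg.shape_vox, dtype=float)
    centroids: list[np.ndarray] = []
    volumes: list[float] = []
    hosts: list = []
    amp = cfg.snr * noise_scale

    for name in names:
        poly = polylines[name]
        seg = np.diff(poly, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        arccum = np.concatenate([[0.0], np.cumsum(seglen)])
        total = arccum[-1]
        n_on = int(round(cfg.puncta_density_per_um * total))
        placed: list[float] = []
        tries = 0
        while len(placed) < n_on and tries < 200 * max(n_on, 1):
            s = rng.uniform(0.0, total)
            if all(abs(s - p) >= cfg.blob_min_separation_um for p in placed):
                placed.append(s)
            tries += 1
        if len(placed) < n_on:
            raise ValueError("could not place on-axon blobs with the requested separation")
        for s in placed:
            i = int(np.searchsorted(arccum, s, side="right")) - 1
            i = min(i, len(seg) - 1)
            frac = (s - arccum[i]) / seglen[i]
            center = poly[i] + frac * seg[i]
            # small radial jitter, truncated so the blob stays well inside the tube
            jitter = rng.normal(0.0, cfg.blob_radial_jitter_um, size=3)
            norm = np.linalg.norm(jitter)
            cap = 2.0 * cfg.blob_radial_jitter_um
            if norm > cap:
                jitter *= cap / norm
            center = center + jitter
            v = rng.uniform(*cfg.blob_volume_um3_range)
            _render_blob(puncta, cfg.voxel_size_um, center, _sigma_for_volume(v), amp)
            centroids.append(center)
            volumes.append(v)
            hosts.append(name)

    vol_um3 = extent[0] * extent[1] * extent[2]
    n_off = int(round(cfg.off_axon_puncta_per_um3 * vol_um3))
    for _ in range(n_off):
        center = np.array(
            [
                rng.uniform(0.3, extent[0] - 0.3),
                rng.uniform(0.3, extent[1] - 0.3),
                rng.uniform(0.3, extent[2] - 0.3),
            ]
        )
        v = rng.uniform(*cfg.blob_volume_um3_range)
        _render_blob(puncta, cfg.voxel_size_um, center, _sigma_for_volume(v), amp)
        centroids.append(center)
        volumes.append(v)
        hosts.append(None)

    if cfg.noise_sd > 0:
        for name in names:
            channels[name] = channels[name] + rng.normal(0.0, cfg.noise_sd, cfg.shape_vox)
        puncta = puncta + rng.normal(0.0, cfg.noise_sd, cfg.shape_vox)

    channels["puncta"] = puncta
    vol3d = LabeledVolume3D(channels=channels, voxel_size_um=cfg.voxel_size_um)
    gt = GroundTruth(
        true_blob_centroids_um=np.array(centroids) if centroids else np.zeros((0, 3)),
        true_blob_volumes_um3=np.array(volumes),
        true_blob_host=hosts,
        true_axon_length_um=lengths,
        true_axon_masks=masks,
    )
    return vol3d, gt


# ---------------------------------------------------------------------------
# 2D synaptosome fields
# ---------------------------------------------------------------------------


@dataclass
class ParticleClass:
    """One mixture component of the synaptosome population."""

    fraction: float
    th: bool
    vamp2: bool
    bassoon: bool


@dataclass
class SynaptosomeSimConfig:
    """Conditions of a simulated synaptosome field.

    Particles are disks with per-channel intensity ``pos_intensity`` when the
    particle class is positive for that marker, rendered over a uniform
    background, blurred by a Gaussian PSF, with additive Gaussian noise.
    """

    shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.05
    n_particles: int = 60
    radius_px_range: tuple[float, float] = (2.5, 4.5)
    class_mix: tuple[ParticleClass, ...] = (
        ParticleClass(0.6, True, True, True),
        ParticleClass(0.2, True, True, False),
        ParticleClass(0.1, False, True, False),
        ParticleClass(0.1, True, False, False),
    )
    pos_intensity: float = 120.0
    background: float = 10.0
    noise_sd: float = 2.0
    psf_sigma_px: float = 1.0
    max_retries_per_particle: int = 200
    seed: int = 0

    def validate(self) -> None:
        total = sum(c.fraction for c in self.class_mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class mixture fractions must sum to 1")
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")


def simulate_synaptosome_field(cfg: SynaptosomeSimConfig) -> tuple[LabeledField2D, GroundTruth]:
    """Render a TH/VAMP2/bassoon field of disk particles with known labels."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.shape
    rmax = cfg.radius_px_range[1]
    min_sep = 2.0 * rmax + 4.0
    margin = rmax + 3.0

    fracs = np.array([c.fraction for c in cfg.class_mix])
    counts = np.floor(fracs * cfg.n_particles).astype(int)
    # distribute the remainder deterministically to the largest classes
    for i in np.argsort(-fracs)[: cfg.n_particles - counts.sum()]:
        counts[i] += 1

    centers: list[tuple[float, float]] = []
    labels: list[dict] = []
    for cls, cnt in zip(cfg.class_mix, counts):
        for _ in range(cnt):
            for _try in range(cfg.max_retries_per_particle):
                cy = rng.uniform(margin, h - margin)
                cx = rng.uniform(margin, w - margin)
                if all((cy - y) ** 2 + (cx - x) ** 2 >= min_sep**2 for y, x in centers):
                    break
            else:
                raise ValueError("could not place particles without excessive overlap")
            r = rng.uniform(*cfg.radius_px_range)
            centers.append((cy, cx))
            labels.append(
                {
                    "center": (cy, cx),
                    "radius_px": r,
                    "th": cls.th,
                    "vamp2": cls.vamp2,
                    "bassoon": cls.bassoon,
                }
            )

    yy, xx = np.mgrid[:h, :w]
    channels = {}
    for ch, key in (("TH", "th"), ("VAMP2", "vamp2"), ("bassoon", "bassoon")):
        img = np.full((h, w), cfg.background, dtype=float)
        for lab in labels:
            if lab[key]:
                cy, cx = lab["center"]
                disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= lab["radius_px"] ** 2
                img[disk] += cfg.pos_intensity
        if cfg.psf_sigma_px > 0:
            img = gaussian_filter(img, cfg.psf_sigma_px)
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, (h, w))
        channels[ch] = img

    field2d = LabeledField2D(channels=channels, pixel_size_um=cfg.pixel_size_um, labels=labels)
    return field2d, GroundTruth(particle_labels=labels)
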