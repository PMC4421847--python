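"""Synthetic two-detector diffraction data with the statistical structure
the pipeline assumes.

Two analytic Fraunhofer sources are provided: cuboid particles (products
of sinc^2 factors, the model the beam-center fit assumes) and assemblies
of circular disks (Airy-type amplitudes with interference between disks,
the standard centering-validation object).  Both are evaluated in closed
form on the detector grid, so they double as exact oracles independent of
any object-grid discretization.

`record_run` then pushes noiseless patterns through the detector forward
model: attenuation of the small-angle detector, Poisson photon noise,
saturation clipping at the pixel full well (~2500 photons at 5.5 keV),
the post-saturation one-photon readout-port offset, Gaussian dark noise,
and splitting into raw per-panel stacks written to an HDF5 run file.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import j1

from .geometry import (
    Attenuator,
    BeamCenter,
    BeamParameters,
    DetectorModel,
    attenuator_transmission,
    pixel_to_scattering,
    single_panel_detector,
)
from .preprocess import Frame
from .runfile import RunWriter

# ---------------------------------------------------------------------------
# Object models
# ---------------------------------------------------------------------------


@dataclass
class CuboidModel:
    """Cuboid particle face-on to the beam: edge lengths 2A x 2B (nm),
    rotated in-plane by theta (degrees), peak intensity K (photons)."""

    A: float
    B: float
    theta: float = 0.0
    K: float = 1.0
    center: BeamCenter | None = None

    def __post_init__(self) -> None:
        if self.A <= 0 or self.B <= 0 or self.K <= 0:
            raise ValueError("A, B, K must be > 0")


@dataclass
class DiskAssemblyModel:
    """One or several uniform disks of a common diameter (nm) at given
    positions (nm, in the object plane); per-disk density weights."""

    diameter: float
    positions: np.ndarray  # (n, 2) nm
    density: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.diameter <= 0 or len(self.positions) < 1:
            raise ValueError("need diameter > 0 and >= 1 disk")
        if self.density is None:
            self.density = np.ones(len(self.positions))

    @property
    def n_disks(self) -> int:
        return len(self.positions)


@dataclass
class NoiseModel:
    """Detector noise: per-pixel Gaussian readout noise (photons), pixel
    saturation limit, post-saturation readout-port offset, Poisson flag."""

    dark_sigma: float = 0.3
    saturation_limit: float = 2500.0
    port_offset: float = 1.0
    poisson: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dark_sigma < 0 or self.saturation_limit <= 0:
            raise ValueError("dark_sigma >= 0 and saturation_limit > 0 required")


# ---------------------------------------------------------------------------
# Analytic renderers
# ---------------------------------------------------------------------------


def sinc(x: np.ndarray) -> np.ndarray:
    """sin(x)/x with sinc(0) = 1 (note: numpy's sinc is sin(pi x)/(pi x))."""
    return np.sinc(np.asarray(x) / np.pi)


def jinc(x: np.ndarray) -> np.ndarray:
    """2 J1(x)/x with jinc(0) = 1; first zero at x = 3.8317."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-12
    out[nz] = 2.0 * j1(x[nz]) / x[nz]
    return out


def _scattering_grid(det: DetectorModel, beam: BeamParameters, center: BeamCenter, theta: float = 0.0):
    ny, nx = det.shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
    s = pixel_to_scattering(pts, center, det, beam, theta)
    return s[:, 0].reshape(ny, nx), s[:, 1].reshape(ny, nx)


def render_cuboid(
    model: CuboidModel,
    det: DetectorModel,
    beam: BeamParameters,
    center: BeamCenter | None = None,
) -> Frame:
    """Noiseless Fraunhofer pattern of a cuboid:
    I = K sinc^2(2 pi A Sx') sinc^2(2 pi B Sy'), Sx'/Sy' in the frame
    rotated by theta.  I(center) = K; zeros on Sx' = k/(2A), k != 0."""
    c = center or model.center or det.nominal_center
    sx, sy = _scattering_grid(det, beam, c, model.theta)
    inten = model.K * sinc(2 * np.pi * model.A * sx) ** 2 * sinc(2 * np.pi * model.B * sy) ** 2
    return Frame(inten, np.zeros(det.shape, np.uint8), detector=det.name)


def render_disks(
    model: DiskAssemblyModel,
    det: DetectorModel,
    beam: BeamParameters,
    center: BeamCenter | None = None,
) -> Frame:
    """Noiseless pattern of a disk assembly:
    I = |sum_k rho_k F_disk(S) exp(2 pi i S.r_k)|^2 with the circular-
    aperture amplitude F_disk = area * jinc(pi D |S|).  Exactly
    centrosymmetric (Friedel) because the object is real."""
    c = center or det.nominal_center
    sx, sy = _scattering_grid(det, beam, c)
    smag = np.hypot(sx, sy)
    f_disk = (np.pi * (model.diameter / 2.0) ** 2) * jinc(np.pi * model.diameter * smag)
    amp = np.zeros(sx.shape, dtype=complex)
    for rho, (rx, ry) in zip(model.density, model.positions):
        amp += rho * np.exp(2j * np.pi * (sx * rx + sy * ry))
    inten = np.abs(f_disk * amp) ** 2
    return Frame(inten, np.zeros(det.shape, np.uint8), detector=det.name)


def render_density_map(
    density: np.ndarray,
    det: DetectorModel,
    beam: BeamParameters,
    center: BeamCenter | None = None,
) -> Frame:
    """Grid-transform alternative to the analytic renderers: diffraction
    intensity of an arbitrary real-space density sampled on a grid whose
    extent matches the detector (|DFT|^2, beam center at `center`).

    The real-space pixel of an N-pixel detector axis is 1/(N*a) nm with
    `a` the per-pixel scattering increment.  Used for phase-retrieval
    fixtures; the analytic renderers stay the oracles for geometry."""
    ny, nx = det.shape
    density = np.asarray(density, dtype=float)
    if density.shape != (ny, nx):
        raise ValueError("density grid must match the detector shape")
    c = center or det.nominal_center
    f = np.fft.fft2(np.fft.ifftshift(density))
    inten = np.abs(np.fft.fftshift(f)) ** 2
    # shift the pattern so its symmetry center lands on the beam center
    dy = c.y - (ny // 2)
    dx = c.x - (nx // 2)
    ky = np.fft.fftshift(np.fft.fftfreq(ny))[:, None]
    kx = np.fft.fftshift(np.fft.fftfreq(nx))[None, :]
    if abs(dy) > 1e-12 or abs(dx) > 1e-12:
        spec = np.fft.fft2(inten)
        wy = np.exp(-2j * np.pi * np.fft.fftfreq(ny) * dy)[:, None]
        wx = np.exp(-2j * np.pi * np.fft.fftfreq(nx) * dx)[None, :]
        inten = np.real(np.fft.ifft2(spec * wy * wx))
    return Frame(np.maximum(inten, 0.0), np.zeros(det.shape, np.uint8), detector=det.name)


# ---------------------------------------------------------------------------
# Recording: noise, saturation, port offsets, HDF5 output
# ---------------------------------------------------------------------------


def split_panels(intensity: np.ndarray, det: DetectorModel) -> np.ndarray:
    """Inverse of assembly for translation-placed panels: cut the assembled
    image into the raw per-panel stack.  Photons falling into inter-panel
    gaps are lost, as on the physical detector."""
    if any(abs(r) > 1e-9 for r in det.panel_rotations):
        raise ValueError("split_panels requires translation-only panels")
    pr, pc = det.panel_shape
    out = np.empty((det.n_panels, pr, pc), dtype=float)
    for k, (r0, c0) in enumerate(det.panel_offsets):
        rr, cc = int(round(r0)), int(round(c0))
        out[k] = intensity[rr : rr + pr, cc : cc + pc]
    return out


def _sensor_shadow(det: DetectorModel) -> np.ndarray:
    """Pixels that record nothing: central aperture hole or beamstop shadow."""
    ny, nx = det.shape
    mask = np.zeros((ny, nx), dtype=bool)
    c = det.nominal_center
    if det.aperture_halfwidth is not None:
        mask |= det.aperture_mask()
    if det.beamstop_halfwidth is not None:
        h = det.beamstop_halfwidth * 1e3 / det.pixel_size
        yy, xx = np.mgrid[0:ny, 0:nx]
        mask |= np.maximum(np.abs(xx - c.x), np.abs(yy - c.y)) <= h
    return mask


def record_run(
    patterns: dict[str, list[Frame]],
    detectors: dict[str, DetectorModel],
    beam: BeamParameters,
    noise: NoiseModel,
    out_run,
    out_dark=None,
    attenuator: Attenuator | None = None,
    n_darks: int = 100,
) -> None:
    """Record noiseless patterns as a raw run file (+ dark-frame stack).

    Per frame and detector: multiply the small-angle ("dual") detector by
    the attenuator transmission; Poisson-sample; clip at the saturation
    limit; from the frame *after* the first saturation event in a readout
    port onward, add the port offset to all pixels of that port; add
    Gaussian dark noise; zero the aperture/beamstop shadow; split into raw
    panels.  Randomness derives from one master seed: stream i feeds frame
    i, streams n_frames..n_frames+n_darks-1 feed the dark stack.
    """
    names = sorted(detectors)
    n_frames = len(next(iter(patterns.values())))
    for name in names:
        if len(patterns.get(name, [])) != n_frames:
            raise ValueError("all detectors need the same number of frames")
    root = np.random.SeedSequence(noise.seed)
    streams = root.spawn(n_frames + n_darks)
    shadows = {n: _sensor_shadow(detectors[n]) for n in names}
    trans = 1.0
    if attenuator is not None:
        trans = attenuator_transmission(attenuator, beam)
    saturated_since: dict[tuple[str, tuple[int, int]], int] = {}
    with RunWriter(out_run, detectors, beam, attenuator, kind="raw", seed=noise.seed) as w:
        for i in range(n_frames):
            rng = np.random.default_rng(streams[i])
            stacks = {}
            for name in names:
                det = detectors[name]
                img = patterns[name][i].intensity.astype(float).copy()
                if name == "dual":
                    img *= trans
                if noise.poisson:
                    img = rng.poisson(np.maximum(img, 0.0)).astype(float)
                sat = img > noise.saturation_limit
                img[sat] = noise.saturation_limit
                for port in det.port_ids():
                    key = (name, port)
                    rsl, csl = det.port_region(port)
                    if key in saturated_since and saturated_since[key] < i:
                        img[rsl, csl] += noise.port_offset
                    if key not in saturated_since and sat[rsl, csl].any():
                        saturated_since[key] = i
                if noise.dark_sigma > 0:
                    img += rng.normal(0.0, noise.dark_sigma, img.shape)
                img[shadows[name]] = 0.0
                stacks[name] = split_panels(img, det)
            w.add_raw_frame(stacks, pulse_id=i)
    if out_dark is not None:
        with RunWriter(out_dark, detectors, beam, attenuator, kind="raw", seed=noise.seed) as w:
            for j in range(n_darks):
                rng = np.random.default_rng(streams[n_frames + j])
                stacks = {}
                for name in names:
                    det = detectors[name]
                    img = rng.normal(0.0, noise.dark_sigma, det.shape)
                    img[shadows[name]] = 0.0
                    stacks[name] = split_panels(img, det)
                w.add_raw_frame(stacks, pulse_id=j)


# ---------------------------------------------------------------------------
# Centering-validation protocol
# ---------------------------------------------------------------------------


def fig10_protocol(
    n_models: int,
    seed: int,
    out_run,
    out_truth,
    det: DetectorModel | None = None,
    beam: BeamParameters | None = None,
    diameter: float = 140.0,
    max_shift: float = 10.0,
    n_disks_range: tuple[int, int] = (1, 5),
    field_of_view: float = 500.0,
    peak_photons: float = 2500.0,
) -> pd.DataFrame:
    """Disk-assembly centering benchmark.

    Renders ``n_models`` patterns of assemblies of 140 nm disks placed
    uniformly in a ``field_of_view`` nm square, each with a true beam
    center shifted uniformly within +-``max_shift`` pixels of the nominal
    center; scales the global maximum intensity to ``peak_photons`` (the
    pixel full well) and applies Poisson noise.  Writes the raw run file
    and a ground-truth CSV; returns the truth table.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    det = det or single_panel_detector("octal", (256, 256))
    beam = beam or BeamParameters(5.52)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    ny, nx = det.shape
    base = BeamCenter((nx - 1) // 2, (ny - 1) // 2, det.name)  # integer nominal
    frames, rows = [], []
    for i in range(n_models):
        n_disks = int(rng.integers(n_disks_range[0], n_disks_range[1] + 1))
        pos = rng.uniform(-field_of_view / 2, field_of_view / 2, (n_disks, 2))
        dx, dy = rng.uniform(-max_shift, max_shift, 2)
        c = BeamCenter(base.x + dx, base.y + dy, det.name)
        fr = render_disks(DiskAssemblyModel(diameter, pos), det, beam, center=c)
        frames.append(fr)
        rows.append({"frame_id": f"{i:05d}", "true_x": c.x, "true_y": c.y, "n_disks": n_disks})
    gmax = max(fr.intensity.max() for fr in frames)
    for fr in frames:
        fr.intensity *= peak_photons / gmax
    noise = NoiseModel(dark_sigma=0.0, poisson=True, seed=seed)
    record_run({det.name: frames}, {det.name: det}, beam, noise, out_run, out_dark=None)
    truth = pd.DataFrame(rows)
    truth.to_csv(out_truth, index=False)
    return truth
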