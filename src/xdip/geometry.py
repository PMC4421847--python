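"""Detector and beam geometry for tandem two-detector CXDI.

The experiment records single-shot far-field diffraction on two multi-panel
CCD detectors placed in tandem on the beam axis: a wide-angle detector
("octal", eight sensor panels around a central aperture, camera length
1.6 m) and a small-angle detector ("dual", two panels behind the aperture
at 3.2 m, protected by a beamstop and an aluminium attenuator).  Every
processing stage shares the coordinate conventions defined here.

Conventions
-----------
* Pixel coordinates are 0-based with pixel centers at integer coordinates;
  ``x`` is the column index, ``y`` the row index.  Arrays are indexed
  ``[y, x]``.  Beam centers are fractional.
* Units are carried per field: keV (photon energy), nm (wavelength,
  resolution), m (camera length), um (pixel size, attenuator thickness),
  mm (aperture/beamstop half-widths), mrad (panel rotations), degrees
  (in-plane pattern rotation), nm^-1 (scattering vectors).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml

#: hc in keV.nm; wavelength[nm] = HC_KEV_NM / E[keV]
HC_KEV_NM = 1.2398419

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BeamParameters:
    """X-ray beam description.

    Parameters
    ----------
    photon_energy : float
        Photon energy in keV (experiments here run at 5.52 keV).
    pulse_scale : float
        Nominal photons available to the simulator for scaling rendered
        patterns; has no meaning for measured data.
    """

    photon_energy: float
    pulse_scale: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.photon_energy) or self.photon_energy <= 0:
            raise ValueError("photon_energy must be finite and > 0")

    @property
    def wavelength(self) -> float:
        """Wavelength in nm."""
        return HC_KEV_NM / self.photon_energy


@dataclass(frozen=True)
class BeamCenter:
    """Direct-beam position in a detector's assembled-image coordinates."""

    x: float
    y: float
    detector: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("beam center must be finite")

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class Attenuator:
    """Metal attenuator in front of the small-angle detector."""

    material: str = "aluminium"
    thickness: float = 0.0  # um

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise ValueError("thickness must be >= 0")


@dataclass
class DetectorModel:
    """Multi-panel detector: layout, readout ports and pixel geometry.

    A detector is a set of identical rectangular sensor panels placed on a
    common assembled pixel grid by per-panel offsets (pixels) and small
    in-plane rotations (mrad).  Each panel is read out through ``n_ports``
    independent amplifier strips that divide the panel's row dimension; the
    strip is the unit over which post-saturation readout offsets appear.
    """

    name: str
    camera_length: float  # m
    pixel_size: float  # um
    panel_shape: tuple[int, int]  # (rows, cols) per sensor panel
    panel_offsets: Sequence[tuple[float, float]]  # (row, col) of panel origin
    panel_rotations: Sequence[float] | None = None  # mrad, per panel
    aperture_halfwidth: float | None = None  # mm; central hole (octal)
    beamstop_halfwidth: float | None = None  # mm; central shadow (dual)
    n_ports: int = 8
    port_edge_depth: int = 50  # columns of the high-angle edge ROI

    def __post_init__(self) -> None:
        if self.camera_length <= 0 or self.pixel_size <= 0:
            raise ValueError("camera_length and pixel_size must be > 0")
        if self.panel_rotations is None:
            self.panel_rotations = [0.0] * self.n_panels
        if len(self.panel_rotations) != self.n_panels:
            raise ValueError("panel_rotations length mismatch")
        if self.panel_shape[0] % self.n_ports != 0:
            raise ValueError("panel rows must divide evenly into ports")

    @property
    def n_panels(self) -> int:
        return len(self.panel_offsets)

    @property
    def shape(self) -> tuple[int, int]:
        """Assembled-image shape (rows, cols) covering all panels."""
        rows = max(int(round(r)) + self.panel_shape[0] for r, _ in self.panel_offsets)
        cols = max(int(round(c)) + self.panel_shape[1] for _, c in self.panel_offsets)
        return rows, cols

    @property
    def nominal_center(self) -> BeamCenter:
        ny, nx = self.shape
        return BeamCenter((nx - 1) / 2.0, (ny - 1) / 2.0, self.name)

    # -- readout-port bookkeeping ------------------------------------------

    def port_ids(self) -> list[tuple[int, int]]:
        """All ports as (panel_index, strip_index)."""
        return [(p, s) for p in range(self.n_panels) for s in range(self.n_ports)]

    def port_region(self, port: tuple[int, int]) -> tuple[slice, slice]:
        """Assembled-coordinate (row, col) slices of one readout port.

        Valid for panels placed by translation (rotations are at the mrad
        level and applied as translations below ``assemble``'s threshold).
        """
        panel, strip = port
        rows_per = self.panel_shape[0] // self.n_ports
        r0 = int(round(self.panel_offsets[panel][0])) + strip * rows_per
        c0 = int(round(self.panel_offsets[panel][1]))
        return slice(r0, r0 + rows_per), slice(c0, c0 + self.panel_shape[1])

    def port_edge_roi(self, port: tuple[int, int]) -> tuple[slice, slice]:
        """High-angle edge ROI of a port (~64 x 50 px block at the port end
        farther from the detector center), used to histogram background."""
        rsl, csl = self.port_region(port)
        _, ncols = self.shape
        det_cx = (ncols - 1) / 2.0
        if abs(csl.stop - 1 - det_cx) >= abs(csl.start - det_cx):
            edge = slice(csl.stop - self.port_edge_depth, csl.stop)
        else:
            edge = slice(csl.start, csl.start + self.port_edge_depth)
        return rsl, edge

    def aperture_halfwidth_px(self) -> float:
        if self.aperture_halfwidth is None:
            raise ValueError(f"detector {self.name!r} has no aperture")
        return self.aperture_halfwidth * 1e3 / self.pixel_size

    def aperture_mask(self) -> np.ndarray:
        """Boolean mask of the central square aperture on the assembled grid."""
        h = self.aperture_halfwidth_px()
        ny, nx = self.shape
        c = self.nominal_center
        yy, xx = np.mgrid[0:ny, 0:nx]
        return np.maximum(np.abs(xx - c.x), np.abs(yy - c.y)) <= h


# ---------------------------------------------------------------------------
# Coordinate conversions
# ---------------------------------------------------------------------------


def rotation_matrix(theta_deg: float) -> np.ndarray:
    """In-plane rotation taking detector axes into the pattern frame."""
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, s], [-s, c]])


def scattering_scale(det: DetectorModel, beam: BeamParameters) -> float:
    """nm^-1 of scattering vector per pixel: a = pixel / (lambda * L).

    Small-angle (flat Ewald sphere) approximation: the scattering vector is
    linear in the pixel offset from the direct beam.
    """
    return (det.pixel_size * 1e-6) / (beam.wavelength * 1e-9 * det.camera_length) * 1e-9


def pixel_to_scattering(
    p: np.ndarray,
    center: BeamCenter,
    det: DetectorModel,
    beam: BeamParameters,
    theta: float = 0.0,
) -> np.ndarray:
    """Map pixel coordinates (x, y) to scattering vectors (nm^-1).

    ``S = a * R(theta) @ (p - center)`` with ``a = pixel/(lambda*L)``;
    ``theta`` (degrees) rotates into the pattern frame, e.g. the particle
    edge direction in a Fraunhofer fit.
    """
    if center.detector and center.detector != det.name:
        raise ValueError("center and detector refer to different detectors")
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite pixel coordinates")
    d = p - center.xy
    return scattering_scale(det, beam) * d @ rotation_matrix(theta).T


def scattering_to_pixel(
    s: np.ndarray,
    center: BeamCenter,
    det: DetectorModel,
    beam: BeamParameters,
    theta: float = 0.0,
) -> np.ndarray:
    """Inverse of :func:`pixel_to_scattering`."""
    s = np.asarray(s, dtype=float)
    a = scattering_scale(det, beam)
    return (s / a) @ rotation_matrix(theta) + center.xy


def resolution_at(
    p: np.ndarray, center: BeamCenter, det: DetectorModel, beam: BeamParameters
) -> np.ndarray:
    """Full-period resolution d (nm) at pixel(s) p: d = lambda / (2 sin th),
    2*th = atan(r/L), with r the physical radius of p from the beam center.

    Raises at the direct-beam position instead of returning infinity.
    """
    p = np.asarray(p, dtype=float)
    r_px = np.hypot(*(p - center.xy).T) if p.ndim > 1 else np.hypot(*(p - center.xy))
    if np.any(r_px == 0):
        raise ValueError("resolution undefined at the direct-beam position")
    r_m = r_px * det.pixel_size * 1e-6
    two_theta = np.arctan(r_m / det.camera_length)
    return beam.wavelength / (2.0 * np.sin(two_theta / 2.0))


# ---------------------------------------------------------------------------
# Attenuator physics
# ---------------------------------------------------------------------------

# Aluminium total mass attenuation coefficients (with coherent scattering),
# NIST Hubbell & Seltzer tabulation, above the Al K edge (1.56 keV).
# Log-log interpolated; density 2.70 g/cm^3.
_AL_E_KEV = np.array([2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 15.0, 20.0, 30.0])
_AL_MU_RHO = np.array(
    [2263.0, 788.0, 360.5, 193.4, 115.3, 50.33, 26.23, 7.955, 3.441, 1.128]
)  # cm^2/g
_AL_DENSITY = 2.70  # g/cm^3


def aluminium_mu_rho(energy_kev: float) -> float:
    """Al mass attenuation coefficient (cm^2/g), log-log interpolation."""
    if not (_AL_E_KEV[0] <= energy_kev <= _AL_E_KEV[-1]):
        raise ValueError(
            f"photon energy {energy_kev} keV outside tabulated range "
            f"[{_AL_E_KEV[0]}, {_AL_E_KEV[-1]}] keV"
        )
    return float(
        np.exp(np.interp(np.log(energy_kev), np.log(_AL_E_KEV), np.log(_AL_MU_RHO)))
    )


def attenuator_transmission(att: Attenuator, beam: BeamParameters) -> float:
    """Fraction of beam transmitted: T = exp(-mu(E) * t), in (0, 1]."""
    if att.material.lower() not in ("aluminium", "aluminum", "al"):
        raise ValueError(f"no attenuation data for material {att.material!r}")
    mu_lin = aluminium_mu_rho(beam.photon_energy) * _AL_DENSITY  # 1/cm
    return float(np.exp(-mu_lin * att.thickness * 1e-4))


# ---------------------------------------------------------------------------
# Stock detector layouts
# ---------------------------------------------------------------------------


def single_panel_detector(
    name: str = "octal",
    shape: tuple[int, int] = (256, 256),
    camera_length: float = 1.6,
    pixel_size: float = 50.0,
    n_ports: int = 8,
) -> DetectorModel:
    """Gapless one-panel detector at the given geometry.

    Used by simulation protocols that work directly in assembled pixel
    coordinates (no panel structure).
    """
    return DetectorModel(
        name=name,
        camera_length=camera_length,
        pixel_size=pixel_size,
        panel_shape=shape,
        panel_offsets=[(0.0, 0.0)],
        n_ports=n_ports,
    )


def octal_demo(camera_length: float = 1.6, pixel_size: float = 50.0) -> DetectorModel:
    """Desk-scale wide-angle detector: four quadrant panels of 120x120 px on
    a 256x256 grid, 16-px central cross gap, 1.0 mm (20 px) aperture."""
    ps = (120, 120)
    offs = [(0.0, 0.0), (0.0, 136.0), (136.0, 0.0), (136.0, 136.0)]
    return DetectorModel(
        name="octal",
        camera_length=camera_length,
        pixel_size=pixel_size,
        panel_shape=ps,
        panel_offsets=offs,
        aperture_halfwidth=1.0,
    )


def dual_demo(camera_length: float = 3.2, pixel_size: float = 50.0) -> DetectorModel:
    """Desk-scale small-angle detector: two 120x256 panels on a 256x256 grid
    with an 16-px central horizontal gap and a 0.2 mm (4 px) beamstop."""
    ps = (120, 256)
    offs = [(0.0, 0.0), (136.0, 0.0)]
    return DetectorModel(
        name="dual",
        camera_length=camera_length,
        pixel_size=pixel_size,
        panel_shape=ps,
        panel_offsets=offs,
        beamstop_halfwidth=0.2,
    )


def mpccd_like(kind: str = "octal") -> DetectorModel:
    """Full-scale layouts with the real sensor tile size (512 x 1024 px of
    50 um, eight readout ports per sensor).  Panel placement is schematic:
    octal = eight tiles in a 4 x 2 ring around a 4.0 mm half-width aperture,
    dual = two tiles stacked behind a 1.0 mm half-width beamstop."""
    if kind == "octal":
        ps = (512, 1024)
        gap = 8.0
        offs = []
        for i in range(4):
            offs.append((i * (512 + gap), 0.0))
            offs.append((i * (512 + gap), 1024 + gap + 160))
        return DetectorModel(
            name="octal",
            camera_length=1.6,
            pixel_size=50.0,
            panel_shape=ps,
            panel_offsets=offs,
            aperture_halfwidth=4.0,
        )
    if kind == "dual":
        return DetectorModel(
            name="dual",
            camera_length=3.2,
            pixel_size=50.0,
            panel_shape=(512, 1024),
            panel_offsets=[(0.0, 0.0), (512 + 8.0, 0.0)],
            beamstop_halfwidth=1.0,
        )
    raise ValueError(kind)


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------


def detector_to_dict(det: DetectorModel) -> dict:
    return {
        "name": det.name,
        "camera_length_m": det.camera_length,
        "pixel_size_um": det.pixel_size,
        "panel_shape": list(det.panel_shape),
        "panel_offsets": [list(map(float, o)) for o in det.panel_offsets],
        "panel_rotations_mrad": [float(r) for r in det.panel_rotations],
        "aperture_halfwidth_mm": det.aperture_halfwidth,
        "beamstop_halfwidth_mm": det.beamstop_halfwidth,
        "n_ports": det.n_ports,
        "port_edge_depth": det.port_edge_depth,
    }


def detector_from_dict(d: dict) -> DetectorModel:
    return DetectorModel(
        name=d["name"],
        camera_length=float(d["camera_length_m"]),
        pixel_size=float(d["pixel_size_um"]),
        panel_shape=tuple(d["panel_shape"]),
        panel_offsets=[tuple(o) for o in d["panel_offsets"]],
        panel_rotations=d.get("panel_rotations_mrad"),
        aperture_halfwidth=d.get("aperture_halfwidth_mm"),
        beamstop_halfwidth=d.get("beamstop_halfwidth_mm"),
        n_ports=int(d.get("n_ports", 8)),
        port_edge_depth=int(d.get("port_edge_depth", 50)),
    )


def save_geometry(
    path,
    beam: BeamParameters,
    detectors: dict[str, DetectorModel],
    attenuator: Attenuator | None = None,
) -> None:
    """Write beam/detector/attenuator configuration to one YAML file."""
    doc = {
        "beam": {"photon_energy_keV": beam.photon_energy, "pulse_scale_photons": beam.pulse_scale},
        "detectors": {k: detector_to_dict(v) for k, v in detectors.items()},
    }
    if attenuator is not None:
        doc["attenuator"] = {"material": attenuator.material, "thickness_um": attenuator.thickness}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_geometry(path):
    """Read a YAML geometry config; returns (beam, {name: detector}, attenuator)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    beam = BeamParameters(
        photon_energy=float(doc["beam"]["photon_energy_keV"]),
        pulse_scale=float(doc["beam"].get("pulse_scale_photons", 1.0)),
    )
    dets = {k: detector_from_dict(v) for k, v in doc["detectors"].items()}
    att = None
    if "attenuator" in doc:
        att = Attenuator(doc["attenuator"]["material"], float(doc["attenuator"]["thickness_um"]))
    return beam, dets, att
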