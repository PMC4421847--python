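"""Merging the two detectors' patterns onto one grid.

The wide-angle ("octal") detector has a central aperture through which
the small-angle beam reaches the attenuated "dual" detector at twice the
camera length.  Merging fills the octal aperture with dual intensities:
each octal pixel's four corners are mapped into dual coordinates (scale =
camera-length ratio, rotation = difference of the fitted in-plane pattern
angles, origin = the two beam centers), and the dual intensity inside the
resulting quadrilateral is summed with exact areal weights from convex
polygon clipping — no rasterization, so photon counts are conserved
exactly on fully covered regions.  The attenuator transmission is divided
back out, and a border-continuity diagnostic quantifies how smoothly
radial intensity profiles cross the detector boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    Attenuator,
    BeamCenter,
    BeamParameters,
    DetectorModel,
    attenuator_transmission,
    rotation_matrix,
)
from .preprocess import Frame, STATUS_MISSING, STATUS_VALID

# ---------------------------------------------------------------------------
# Corner mapping
# ---------------------------------------------------------------------------


def map_corners(
    p: tuple[float, float],
    center_octal: BeamCenter,
    center_dual: BeamCenter,
    dtheta: float,
    length_octal: float,
    length_dual: float,
) -> np.ndarray:
    """Corners of octal pixel ``p`` in dual pixel coordinates, (4, 2).

    ``d_dual = R(dtheta) (d_octal - P0_octal) * (L_dual/L_octal) + P0_dual``
    applied to the four pixel corners (pixel centers at integers, so the
    corners sit at +-0.5).  ``dtheta`` (degrees) is the in-plane rotation
    of the dual detector relative to the octal one, i.e. the difference
    of the fitted pattern angles of the same particle on both detectors.
    """
    x, y = p
    corners = np.array(
        [[x - 0.5, y - 0.5], [x + 0.5, y - 0.5], [x + 0.5, y + 0.5], [x - 0.5, y + 0.5]]
    )
    ratio = length_dual / length_octal
    d = (corners - center_octal.xy) @ rotation_matrix(dtheta).T * ratio
    return d + center_dual.xy


# ---------------------------------------------------------------------------
# Exact convex clipping (quadrilateral vs axis-aligned pixel square)
# ---------------------------------------------------------------------------


def _clip_halfplane(poly: list, axis: int, bound: float, keep_below: bool) -> list:
    """Sutherland-Hodgman step against x/y <= or >= bound."""
    out = []
    n = len(poly)
    for i in range(n):
        a, b = poly[i], poly[(i + 1) % n]
        ina = (a[axis] <= bound) if keep_below else (a[axis] >= bound)
        inb = (b[axis] <= bound) if keep_below else (b[axis] >= bound)
        if ina:
            out.append(a)
        if ina != inb:
            t = (bound - a[axis]) / (b[axis] - a[axis])
            out.append((a[0] + t * (b[0] - a[0]), a[1] + t * (b[1] - a[1])))
    return out


def _poly_area(poly: list) -> float:
    if len(poly) < 3:
        return 0.0
    x = np.array([p[0] for p in poly])
    y = np.array([p[1] for p in poly])
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def clip_area(quad: np.ndarray, qx: int, qy: int) -> float:
    """Overlap area of a convex quadrilateral with the unit pixel square
    centered at integer (qx, qy)."""
    poly = [tuple(c) for c in quad]
    poly = _clip_halfplane(poly, 0, qx + 0.5, True)
    poly = _clip_halfplane(poly, 0, qx - 0.5, False)
    poly = _clip_halfplane(poly, 1, qy + 0.5, True)
    poly = _clip_halfplane(poly, 1, qy - 0.5, False)
    return _poly_area(poly)


@dataclass
class PixelFootprint:
    """One octal pixel's footprint on the dual grid: the mapped corner
    quadrilateral and the covered dual pixels with areal weights (dual-
    pixel units; the weights sum to the quadrilateral's area)."""

    source: tuple[float, float]
    quad: np.ndarray
    pixels: np.ndarray  # (m, 2) integer dual (x, y)
    weights: np.ndarray  # (m,)

    @property
    def area(self) -> float:
        return _poly_area([tuple(c) for c in self.quad])


def footprint(
    p: tuple[float, float],
    center_octal: BeamCenter,
    center_dual: BeamCenter,
    dtheta: float,
    length_octal: float,
    length_dual: float,
) -> PixelFootprint:
    """Compute one octal pixel's dual-grid footprint."""
    quad = map_corners(p, center_octal, center_dual, dtheta, length_octal, length_dual)
    x0 = int(np.floor(quad[:, 0].min() + 0.5))
    x1 = int(np.floor(quad[:, 0].max() + 0.5))
    y0 = int(np.floor(quad[:, 1].min() + 0.5))
    y1 = int(np.floor(quad[:, 1].max() + 0.5))
    pix, wts = [], []
    for qy in range(y0, y1 + 1):
        for qx in range(x0, x1 + 1):
            a = clip_area(quad, qx, qy)
            if a > 0.0:
                pix.append((qx, qy))
                wts.append(a)
    return PixelFootprint(
        source=tuple(p), quad=quad,
        pixels=np.array(pix, dtype=int).reshape(-1, 2),
        weights=np.array(wts, dtype=float),
    )


# ---------------------------------------------------------------------------
# Resampling and merging
# ---------------------------------------------------------------------------


def resample(
    dual: Frame,
    targets: np.ndarray,
    center_octal: BeamCenter,
    center_dual: BeamCenter,
    dtheta: float,
    length_octal: float,
    length_dual: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Areal-weighted dual intensity and coverage for octal target pixels.

    ``intensity[i] = sum_q w(i, q) I_dual(q)`` over valid dual pixels in
    target i's footprint; masked (missing/saturated) dual pixels
    contribute nothing and reduce ``coverage[i]`` (valid weight over
    footprint area, in [0, 1]).
    """
    ny, nx = dual.intensity.shape
    valid = dual.valid
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    inten = np.zeros(len(targets))
    cover = np.zeros(len(targets))
    for i, p in enumerate(targets):
        fp = footprint(tuple(p), center_octal, center_dual, dtheta, length_octal, length_dual)
        if fp.weights.size == 0:
            continue
        qx, qy = fp.pixels[:, 0], fp.pixels[:, 1]
        inb = (qx >= 0) & (qx < nx) & (qy >= 0) & (qy < ny)
        ok = np.zeros(len(qx), dtype=bool)
        ok[inb] = valid[qy[inb], qx[inb]]
        inten[i] = float(np.sum(fp.weights[ok] * dual.intensity[qy[ok], qx[ok]]))
        cover[i] = float(np.sum(fp.weights[ok]) / fp.area)
    return inten, cover


@dataclass
class MergedPattern:
    """Single merged intensity array on the octal pixel grid."""

    intensity: np.ndarray
    status: np.ndarray
    center: BeamCenter
    scale_applied: float = 1.0  # 1/transmission applied to dual-sourced pixels

    def as_frame(self) -> Frame:
        return Frame(self.intensity, self.status, detector=self.center.detector)


def merge(
    octal: Frame,
    dual: Frame,
    center_octal: BeamCenter,
    center_dual: BeamCenter,
    det_octal: DetectorModel,
    det_dual: DetectorModel,
    beam: BeamParameters,
    dtheta: float = 0.0,
    attenuator: Attenuator | None = None,
    min_coverage: float = 0.5,
) -> MergedPattern:
    """Fill the octal frame's missing small-angle region from the dual.

    Every missing octal pixel is resampled from the dual frame; pixels
    whose footprint coverage falls below ``min_coverage`` stay missing.
    Dual-sourced intensities are divided by the attenuator transmission
    (absent attenuator means T = 1).  Measured octal pixels are kept.
    """
    scale = 1.0
    if attenuator is not None:
        scale = 1.0 / attenuator_transmission(attenuator, beam)
    my, mx = np.nonzero(octal.status == STATUS_MISSING)
    targets = np.stack([mx, my], axis=1).astype(float)
    out_i = octal.intensity.copy()
    out_s = octal.status.copy()
    if len(targets):
        inten, cover = resample(
            dual, targets, center_octal, center_dual, dtheta,
            det_octal.camera_length, det_dual.camera_length,
        )
        ok = cover >= min_coverage
        out_i[my[ok], mx[ok]] = inten[ok] * scale
        out_s[my[ok], mx[ok]] = STATUS_VALID
    return MergedPattern(out_i, out_s, center_octal, scale_applied=scale)


# ---------------------------------------------------------------------------
# Border-continuity diagnostic
# ---------------------------------------------------------------------------


def continuity_score(
    merged: MergedPattern,
    border_radius: float,
    band: float = 3.0,
    n_azimuth: int = 36,
    min_bins: int = 6,
) -> tuple[float, pd.DataFrame]:
    """Smoothness of intensity profiles across the detector border.

    For each azimuthal sector, the mean valid intensity in the ring just
    inside the border (Chebyshev radius in [border - band, border)) is
    compared with the ring just outside ([border, border + band)); the
    score is the mean absolute log intensity ratio over sectors with
    positive means on both sides.  0 means perfectly continuous; a pure
    scale error s gives |log s|.  Returns (score, per-sector profile).
    """
    inten, status = merged.intensity, merged.status
    ny, nx = inten.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    dx, dy = xx - merged.center.x, yy - merged.center.y
    r = np.maximum(np.abs(dx), np.abs(dy))
    az = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    valid = (status == STATUS_VALID) | (status == 3)
    inner = valid & (r >= border_radius - band) & (r < border_radius)
    outer = valid & (r >= border_radius) & (r < border_radius + band)
    edges = np.linspace(0, 2 * np.pi, n_azimuth + 1)
    rows = []
    for k in range(n_azimuth):
        sel = (az >= edges[k]) & (az < edges[k + 1])
        mi = inten[inner & sel]
        mo = inten[outer & sel]
        if mi.size and mo.size and mi.mean() > 0 and mo.mean() > 0:
            rows.append({
                "azimuth_deg": float(np.degrees(0.5 * (edges[k] + edges[k + 1]))),
                "inner_mean": float(mi.mean()),
                "outer_mean": float(mo.mean()),
                "abs_log_ratio": float(abs(np.log(mi.mean() / mo.mean()))),
            })
    if len(rows) < min_bins:
        raise ValueError(f"only {len(rows)} usable border sectors (< {min_bins})")
    prof = pd.DataFrame(rows)
    return float(prof.abs_log_ratio.mean()), prof


# ---------------------------------------------------------------------------
# Flat-binary output (float32 image + JSON sidecar)
# ---------------------------------------------------------------------------


def save_merged(path_base, merged: MergedPattern) -> None:
    """Write ``<base>.bin`` (row-major float32 intensity), ``<base>.mask.bin``
    (uint8 status) and ``<base>.json`` (shape, center, scale)."""
    import json
    from pathlib import Path

    base = Path(path_base)
    merged.intensity.astype(np.float32).tofile(base.with_suffix(".bin"))
    merged.status.astype(np.uint8).tofile(base.with_suffix(".mask.bin"))
    meta = {
        "shape": list(merged.intensity.shape),
        "dtype": "float32",
        "order": "C",
        "center_x": merged.center.x,
        "center_y": merged.center.y,
        "detector": merged.center.detector,
        "scale_applied": merged.scale_applied,
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_merged(path_base) -> MergedPattern:
    import json
    from pathlib import Path

    base = Path(path_base)
    meta = json.loads(base.with_suffix(".json").read_text())
    shape = tuple(meta["shape"])
    inten = np.fromfile(base.with_suffix(".bin"), dtype=np.float32).reshape(shape)
    status = np.fromfile(base.with_suffix(".mask.bin"), dtype=np.uint8).reshape(shape)
    return MergedPattern(
        inten.astype(float), status,
        BeamCenter(meta["center_x"], meta["center_y"], meta.get("detector", "")),
        scale_applied=float(meta.get("scale_applied", 1.0)),
    )
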