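"""Direct-beam position determination and Friedel-symmetry operations.

Two complementary methods locate the direct-beam pixel, which every later
stage (merging, phasing) needs to sub-pixel precision:

1. *Model fitting*: the diffraction pattern of a face-on cuboid particle
   is the Fraunhofer pattern of a rectangular aperture,
   ``I = K sinc^2(2 pi A Sx') sinc^2(2 pi B Sy')``, fitted by nonlinear
   least squares for (K, A, B, theta, Xc, Yc).  On the small-angle
   detector all six parameters are free; on the wide-angle detector the
   edge lengths A, B are fixed to the values just determined and only
   (K, theta, Xc, Yc) are refined.

2. *Symmetry search*: in the flat-Ewald regime the intensity from a real
   object is centrosymmetric about the direct beam (Friedel symmetry).
   The C_sym score compares ROIs with their point reflections about a
   candidate center; an exhaustive grid search takes the argmax.

The same symmetry fills detector gaps: a missing pixel whose Friedel mate
is measured inherits the mate's intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .geometry import BeamCenter, BeamParameters, DetectorModel, pixel_to_scattering
from .preprocess import Frame, STATUS_FILLED, STATUS_MISSING
from .simulate import sinc

# ---------------------------------------------------------------------------
# Fraunhofer model fit
# ---------------------------------------------------------------------------

_PARAMS = ("K", "A", "B", "theta", "xc", "yc")


@dataclass
class FitResult:
    """Rectangular-aperture fit parameters with 1-sigma uncertainties
    (from the residual-scaled Jacobian covariance) and residual norm."""

    K: float
    A: float
    B: float
    theta: float  # degrees, wrapped to (-90, 90]
    xc: float
    yc: float
    sigmas: dict = field(default_factory=dict)
    residual: float = np.nan  # sum of squared (weighted) residuals
    converged: bool = False
    message: str = ""

    def center(self, detector: str = "") -> BeamCenter:
        return BeamCenter(self.xc, self.yc, detector)

    def as_dict(self) -> dict:
        return {p: getattr(self, p) for p in _PARAMS}


def _wrap_theta(theta: float) -> float:
    t = (theta + 90.0) % 180.0 - 90.0
    return 90.0 if t == -90.0 else t


def fraunhofer_intensity(
    det: DetectorModel,
    beam: BeamParameters,
    params: dict,
    points: np.ndarray,
) -> np.ndarray:
    """Model intensity at pixel coordinates (n, 2) for parameter dict."""
    c = BeamCenter(params["xc"], params["yc"], det.name)
    s = pixel_to_scattering(points, c, det, beam, params["theta"])
    return (
        params["K"]
        * sinc(2 * np.pi * params["A"] * s[:, 0]) ** 2
        * sinc(2 * np.pi * params["B"] * s[:, 1]) ** 2
    )


def fit_fraunhofer(
    frame: Frame,
    det: DetectorModel,
    beam: BeamParameters,
    init: dict | FitResult,
    fixed: dict | None = None,
    min_valid: int = 500,
    weighting: str = "poisson",
) -> FitResult:
    """Least-squares fit of the rectangular-aperture model to a frame.

    ``init`` supplies starting values for all six parameters; ``fixed``
    pins a subset (typically ``{"A": ..., "B": ...}`` on the wide-angle
    detector, reusing the particle size determined on the small-angle
    one).  With the default ``weighting="poisson"`` residuals are scaled
    by ``1/sqrt(max(I_model, 1))`` — photon counting noise grows with
    intensity, and unweighted residuals would both over-trust the bright
    central speckles and grossly understate the parameter uncertainties.
    ``weighting="none"`` gives the plain sum of squared intensity
    residuals.  Non-convergence is reported in the result, never
    silently.
    """
    fixed = dict(fixed or {})
    if isinstance(init, FitResult):
        init = init.as_dict()
    init = {**init, **fixed}
    missing = [p for p in _PARAMS if p not in init]
    if missing:
        raise ValueError(f"init lacks parameters: {missing}")
    v = frame.valid
    if v.sum() < min_valid:
        raise ValueError(f"only {int(v.sum())} valid pixels (< {min_valid})")
    yy, xx = np.nonzero(v)
    pts = np.stack([xx, yy], axis=1).astype(float)
    obs = frame.intensity[yy, xx]

    free = [p for p in _PARAMS if p not in fixed]
    lower = np.array([1e-12 if p in ("K", "A", "B") else -np.inf for p in free])
    upper = np.full(len(free), np.inf)
    x0 = np.array([float(init[p]) for p in free])
    x0 = np.maximum(x0, lower)

    def unpack(x):
        d = dict(fixed)
        d.update(dict(zip(free, x)))
        return d

    if weighting not in ("poisson", "none"):
        raise ValueError(f"unknown weighting {weighting!r}")

    def solve(x_start, weights):
        def residuals(x):
            r = fraunhofer_intensity(det, beam, unpack(x), pts) - obs
            return r if weights is None else r * weights

        scale = np.maximum(np.abs(x_start), [1.0] * len(free))
        return least_squares(residuals, x_start, bounds=(lower, upper),
                             x_scale=scale, method="trf")

    # Unweighted first pass; for Poisson weighting, iterate with weights
    # frozen from the previous model (IRLS -> Poisson maximum likelihood;
    # weights inside the objective would bias the fit).
    res = solve(x0, None)
    if weighting == "poisson":
        for _ in range(2):
            w = 1.0 / np.sqrt(
                np.maximum(fraunhofer_intensity(det, beam, unpack(res.x), pts), 1.0)
            )
            res = solve(res.x, w)
    params = unpack(res.x)
    params["theta"] = _wrap_theta(params["theta"])
    ssq = float(2.0 * res.cost)
    sigmas = dict.fromkeys(free, np.nan)
    dof = obs.size - len(free)
    if dof > 0:
        try:
            cov = np.linalg.inv(res.jac.T @ res.jac)
            if weighting == "none":
                # unknown noise scale: estimate it from the residuals
                cov = cov * (ssq / dof)
            # else: weights encode the known Poisson variance, so the
            # inverse Fisher information needs no empirical scale factor
            sigmas = {p: float(np.sqrt(max(cov[i, i], 0.0))) for i, p in enumerate(free)}
        except np.linalg.LinAlgError:
            pass
    ok = bool(res.success) and params["K"] > 0 and params["A"] > 0 and params["B"] > 0
    return FitResult(
        K=params["K"], A=params["A"], B=params["B"], theta=params["theta"],
        xc=params["xc"], yc=params["yc"], sigmas=sigmas, residual=ssq,
        converged=ok, message=res.message,
    )


def auto_init(frame: Frame, size_guess: float = 100.0) -> dict:
    """Rough starting parameters: center from the intensity centroid of
    the brightest decile, theta from the principal axis of those pixels,
    A = B = ``size_guess`` nm, K from the observed maximum."""
    v = frame.valid
    inten = np.where(v, frame.intensity, 0.0)
    thr = np.quantile(inten[v], 0.9) if v.any() else 0.0
    sel = inten >= max(thr, 1e-12)
    yy, xx = np.nonzero(sel)
    w = inten[yy, xx]
    w = w / w.sum()
    cx, cy = float(np.sum(w * xx)), float(np.sum(w * yy))
    dx, dy = xx - cx, yy - cy
    cxx, cyy, cxy = np.sum(w * dx * dx), np.sum(w * dy * dy), np.sum(w * dx * dy)
    theta = 0.5 * np.degrees(np.arctan2(2 * cxy, cxx - cyy))
    return {
        "K": float(inten.max()),
        "A": size_guess,
        "B": size_guess,
        "theta": _wrap_theta(theta),
        "xc": cx,
        "yc": cy,
    }


# ---------------------------------------------------------------------------
# Friedel-symmetry score
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RoiSpec:
    """Placement of the symmetry-scored ROIs: ``len(angles)`` squares of
    ``size`` px whose centers sit ``radius`` px from the candidate center
    (angles in degrees, all in one half-plane so that no ROI coincides
    with another ROI's Friedel mate)."""

    radius: float = 56.0
    size: int = 48
    angles: tuple = (0.0, 45.0, 90.0, 135.0)

    def offsets(self) -> list[tuple[int, int]]:
        """Integer (dx, dy) of each ROI's lower corner relative to the center."""
        out = []
        h = self.size // 2
        for a in self.angles:
            t = np.deg2rad(a)
            dx = int(round(self.radius * np.cos(t))) - h
            dy = int(round(-self.radius * np.sin(t))) - h
            out.append((dx, dy))
        return out


@dataclass
class CsymMap:
    """Exhaustive C_sym evaluation over a candidate window."""

    xs: np.ndarray  # candidate columns
    ys: np.ndarray  # candidate rows
    scores: np.ndarray  # (len(ys), len(xs)); NaN where not evaluable
    best: BeamCenter
    roi_spec: RoiSpec

    def refine_subpixel(self) -> BeamCenter:
        """Paraboloid refinement of the argmax over its 3x3 neighbourhood
        (off the integer grid; opt-in, the grid search itself is integer)."""
        j = int(np.nanargmax(self.scores))
        iy, ix = np.unravel_index(j, self.scores.shape)
        if not (0 < iy < self.scores.shape[0] - 1 and 0 < ix < self.scores.shape[1] - 1):
            return self.best
        s = self.scores[iy - 1 : iy + 2, ix - 1 : ix + 2]
        if np.isnan(s).any():
            return self.best
        dx = 0.5 * (s[1, 0] - s[1, 2]) / (s[1, 0] - 2 * s[1, 1] + s[1, 2] + 1e-300)
        dy = 0.5 * (s[0, 1] - s[2, 1]) / (s[0, 1] - 2 * s[1, 1] + s[2, 1] + 1e-300)
        dx, dy = np.clip([dx, dy], -0.5, 0.5)
        return BeamCenter(self.xs[ix] + dx, self.ys[iy] + dy, self.best.detector)


def csym(
    frame: Frame,
    candidate: tuple[int, int],
    roi_spec: RoiSpec = RoiSpec(),
    min_pairs: int = 100,
) -> float:
    """Friedel-symmetry score of one candidate center (integer pixel).

    ``C_sym = 1 - sum|I1 - I2| / sum(I1 + I2)`` over pixel pairs (p,
    2c - p) with p in the ROIs and both partners valid.  Bounded in
    [0, 1] for non-negative intensities (values are floored at zero, as
    befits photon counts), equal to 1 exactly on perfect symmetry, and
    decreasing with asymmetry.  The formula is isolated here so an
    alternative similarity measure is a one-line swap.
    """
    cx, cy = int(round(candidate[0])), int(round(candidate[1]))
    ny, nx = frame.intensity.shape
    num = den = 0.0
    n_pairs = 0
    for dx, dy in roi_spec.offsets():
        x0, y0 = cx + dx, cy + dy
        x1, y1 = x0 + roi_spec.size, y0 + roi_spec.size
        mx0, my0 = 2 * cx - (x1 - 1), 2 * cy - (y1 - 1)
        mx1, my1 = mx0 + roi_spec.size, my0 + roi_spec.size
        if x0 < 0 or y0 < 0 or x1 > nx or y1 > ny or mx0 < 0 or my0 < 0 or mx1 > nx or my1 > ny:
            continue
        i1 = np.maximum(frame.intensity[y0:y1, x0:x1], 0.0)
        v1 = frame.valid[y0:y1, x0:x1]
        i2 = np.maximum(frame.intensity[my0:my1, mx0:mx1], 0.0)[::-1, ::-1]
        v2 = frame.valid[my0:my1, mx0:mx1][::-1, ::-1]
        both = v1 & v2
        n_pairs += int(both.sum())
        num += float(np.abs(i1[both] - i2[both]).sum())
        den += float((i1[both] + i2[both]).sum())
    if n_pairs < min_pairs:
        raise ValueError(f"only {n_pairs} valid symmetry pairs (< {min_pairs})")
    if den == 0.0:
        return 1.0
    return 1.0 - num / den


def search_center(
    frame: Frame,
    window: int,
    prior: BeamCenter,
    roi_spec: RoiSpec = RoiSpec(),
    min_pairs: int = 100,
) -> CsymMap:
    """Exhaustive C_sym grid search over an odd ``window`` x ``window``
    pixel area centered on ``prior``.  Ties break toward the prior, then
    lowest row, then lowest column."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    px, py = int(round(prior.x)), int(round(prior.y))
    h = window // 2
    xs = np.arange(px - h, px + h + 1)
    ys = np.arange(py - h, py + h + 1)
    scores = np.full((window, window), np.nan)
    for iy, cy in enumerate(ys):
        for ix, cx in enumerate(xs):
            try:
                scores[iy, ix] = csym(frame, (cx, cy), roi_spec, min_pairs)
            except ValueError:
                continue
    if np.all(np.isnan(scores)):
        raise ValueError("no evaluable candidate in the search window")
    smax = np.nanmax(scores)
    iy, ix = np.nonzero(scores == smax)
    d2 = (xs[ix] - prior.x) ** 2 + (ys[iy] - prior.y) ** 2
    order = np.lexsort((xs[ix], ys[iy], d2))
    k = order[0]
    best = BeamCenter(float(xs[ix[k]]), float(ys[iy[k]]), frame.detector)
    return CsymMap(xs=xs, ys=ys, scores=scores, best=best, roi_spec=roi_spec)


# ---------------------------------------------------------------------------
# Symmetry fill and tandem-center prediction
# ---------------------------------------------------------------------------


def symmetrize_fill(frame: Frame, center: BeamCenter) -> Frame:
    """Fill missing pixels from their Friedel mates about ``center``.

    A missing pixel whose point reflection is measured receives the
    mate's intensity and is flagged valid-by-symmetry; pixels whose mates
    are also missing stay missing and remain excluded downstream.
    """
    out = frame.copy()
    ny, nx = out.intensity.shape
    my, mx = np.nonzero(out.status == STATUS_MISSING)
    if my.size == 0:
        return out
    ry = np.round(2 * center.y - my).astype(int)
    rx = np.round(2 * center.x - mx).astype(int)
    inb = (ry >= 0) & (ry < ny) & (rx >= 0) & (rx < nx)
    sel = np.zeros(my.size, dtype=bool)
    sel[inb] = frame.valid[ry[inb], rx[inb]]
    out.intensity[my[sel], mx[sel]] = frame.intensity[ry[sel], rx[sel]]
    out.status[my[sel], mx[sel]] = STATUS_FILLED
    return out


@dataclass
class DualCenterCalibration:
    """Per-axis affine map from wide-angle to small-angle beam centers:
    slope fixed by the camera-length ratio, offsets fitted per set-up."""

    slope: float  # L_dual / L_octal
    offset_x: float
    offset_y: float


def calibrate_dual_center(
    pairs: list[tuple[BeamCenter, BeamCenter]],
    length_octal: float,
    length_dual: float,
) -> DualCenterCalibration:
    """Fit the per-axis offsets from >= 2 paired (octal, dual) centers;
    the slope is the geometric camera-length ratio."""
    if len(pairs) < 2:
        raise ValueError("need at least two paired center observations")
    s = length_dual / length_octal
    ox = float(np.mean([d.x - s * o.x for o, d in pairs]))
    oy = float(np.mean([d.y - s * o.y for o, d in pairs]))
    return DualCenterCalibration(slope=s, offset_x=ox, offset_y=oy)


def predict_dual_center(center_octal: BeamCenter, calib: DualCenterCalibration) -> BeamCenter:
    """Small-angle-detector beam center predicted from the wide-angle one."""
    return BeamCenter(
        calib.slope * center_octal.x + calib.offset_x,
        calib.slope * center_octal.y + calib.offset_y,
        "dual",
    )
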