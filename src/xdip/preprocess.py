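"""Raw-frame preprocessing: assembly, dark subtraction, saturation-port
offset correction, and hit sorting/extraction.

This is the first pipeline stage.  It turns raw per-panel detector data
into assembled, background-corrected frames and keeps only the shots whose
small-angle intensity says a particle was actually hit.

The subtle physics here is a CCD readout artefact: once any pixel of a
readout port saturates (~2500 photons at 5.5 keV), the whole port's
background level rises by roughly one photon in *every subsequent frame*
until the port is reset.  One photon per pixel is invisible by eye but,
summed over the ~10^5 pixels of a hit-finding ROI, it is large enough to
misclassify empty shots as hits.  The correction estimates the shift from
the histogram mode of an edge region of the port (essentially free of
diffracted photons) and subtracts it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import DetectorModel
from .runfile import RunReader, RunWriter

# Per-pixel status codes
STATUS_VALID = 0
STATUS_MISSING = 1
STATUS_SATURATED = 2
STATUS_FILLED = 3  # valid-by-symmetry (set by the centering stage)


@dataclass
class Frame:
    """Assembled 2-D intensity image in photons with a status mask."""

    intensity: np.ndarray
    status: np.ndarray
    frame_id: str = ""
    detector: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.status = np.asarray(self.status, dtype=np.uint8)
        if self.intensity.shape != self.status.shape:
            raise ValueError("intensity/status shape mismatch")

    @property
    def valid(self) -> np.ndarray:
        """Pixels carrying usable intensity (measured or symmetry-filled)."""
        return (self.status == STATUS_VALID) | (self.status == STATUS_FILLED)

    def copy(self) -> "Frame":
        return Frame(self.intensity.copy(), self.status.copy(), self.frame_id, self.detector)


@dataclass
class PortOffsetRecord:
    """One port's saturation event and the offset(s) subtracted after it."""

    port: tuple[int, int]
    first_saturated_frame: int
    offset: float = 0.0  # representative (per-event) estimate, photons


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def assemble(
    panels: np.ndarray,
    det: DetectorModel,
    rotation_threshold_mrad: float = 2.0,
) -> Frame:
    """Place raw sensor panels onto the assembled grid (nearest pixel).

    Photons are conserved: every input pixel deposits its full intensity
    into exactly one assembled pixel.  Panel rotations below
    ``rotation_threshold_mrad`` are applied as pure translations (the
    calibrated rotations are ~1 mrad, under half a pixel across a panel);
    larger ones rotate pixel coordinates about the panel center before the
    nearest-pixel deposit.  Uncovered pixels (inter-panel gaps) and the
    central aperture/beamstop region are flagged missing.
    """
    panels = np.asarray(panels, dtype=float)
    if panels.shape != (det.n_panels, *det.panel_shape):
        raise ValueError(
            f"panel stack shape {panels.shape} does not match detector "
            f"({det.n_panels}, {det.panel_shape[0]}, {det.panel_shape[1]})"
        )
    ny, nx = det.shape
    out = np.zeros((ny, nx))
    covered = np.zeros((ny, nx), dtype=bool)
    pr, pc = det.panel_shape
    for k in range(det.n_panels):
        r0, c0 = det.panel_offsets[k]
        rot = det.panel_rotations[k]
        if abs(rot) <= rotation_threshold_mrad:
            rr, cc = int(round(r0)), int(round(c0))
            out[rr : rr + pr, cc : cc + pc] += panels[k]
            covered[rr : rr + pr, cc : cc + pc] = True
        else:
            ang = rot * 1e-3
            cy, cx = (pr - 1) / 2.0, (pc - 1) / 2.0
            yy, xx = np.mgrid[0:pr, 0:pc].astype(float)
            yr = cy + np.cos(ang) * (yy - cy) - np.sin(ang) * (xx - cx) + r0
            xr = cx + np.sin(ang) * (yy - cy) + np.cos(ang) * (xx - cx) + c0
            iy = np.clip(np.round(yr).astype(int), 0, ny - 1)
            ix = np.clip(np.round(xr).astype(int), 0, nx - 1)
            np.add.at(out, (iy, ix), panels[k])
            covered[iy, ix] = True
    status = np.where(covered, STATUS_VALID, STATUS_MISSING).astype(np.uint8)
    if det.aperture_halfwidth is not None:
        status[det.aperture_mask()] = STATUS_MISSING
    if det.beamstop_halfwidth is not None:
        h = det.beamstop_halfwidth * 1e3 / det.pixel_size
        c = det.nominal_center
        yy, xx = np.mgrid[0:ny, 0:nx]
        status[np.maximum(np.abs(xx - c.x), np.abs(yy - c.y)) <= h] = STATUS_MISSING
    out[status == STATUS_MISSING] = 0.0
    return Frame(out, status, detector=det.name)


# ---------------------------------------------------------------------------
# Dark correction
# ---------------------------------------------------------------------------


def average_darks(darks: list[Frame]) -> Frame:
    """Per-pixel arithmetic mean of a stack of dark frames."""
    if len(darks) == 0:
        raise ValueError("empty dark stack")
    mean = np.mean([d.intensity for d in darks], axis=0)
    return Frame(mean, darks[0].status.copy(), frame_id="dark_mean", detector=darks[0].detector)


def subtract_dark(frame: Frame, dark: Frame) -> Frame:
    """Subtract the averaged dark on valid pixels; status is preserved."""
    if frame.intensity.shape != dark.intensity.shape:
        raise ValueError("frame/dark shape mismatch")
    out = frame.copy()
    v = out.status != STATUS_MISSING
    out.intensity[v] = out.intensity[v] - dark.intensity[v]
    return out


def flag_saturated(frame: Frame, limit: float) -> Frame:
    """Mark pixels at/above the saturation limit (default 2500 photons at
    5.5 keV; scale per photon energy)."""
    out = frame.copy()
    out.status[(out.status == STATUS_VALID) & (out.intensity >= limit)] = STATUS_SATURATED
    return out


# ---------------------------------------------------------------------------
# Saturation-port offset correction
# ---------------------------------------------------------------------------


def estimate_port_offset(
    frame: Frame,
    port: tuple[int, int],
    det: DetectorModel,
    bin_width: float = 0.1,
    min_pixels: int = 500,
) -> float:
    """Background offset of one readout port, from the histogram mode of
    its high-angle edge ROI.

    The mode (not the mean) is used because occasional diffraction photons
    leaking into the edge region skew the mean but leave the peak of the
    unimodal readout-noise distribution in place.  Bin width 0.1 photon;
    the peak bin is refined to sub-bin precision by a parabola through it
    and its neighbours (otherwise the estimate is quantized to the bin
    grid and its worst-case error is a full bin).
    """
    rsl, csl = det.port_edge_roi(port)
    vals = frame.intensity[rsl, csl][frame.valid[rsl, csl]]
    if vals.size < min_pixels:
        raise ValueError(
            f"port {port}: only {vals.size} usable edge pixels (< {min_pixels})"
        )
    lo = np.floor(vals.min() / bin_width) - 1
    hi = np.ceil(vals.max() / bin_width) + 1
    edges = (np.arange(lo, hi + 1) - 0.5) * bin_width  # centers at k*bin_width
    counts, edges = np.histogram(vals, bins=edges)
    k = int(np.argmax(counts))
    mode = 0.5 * (edges[k] + edges[k + 1])
    if 0 < k < len(counts) - 1:
        denom = counts[k - 1] - 2 * counts[k] + counts[k + 1]
        if denom < 0:
            delta = 0.5 * (counts[k - 1] - counts[k + 1]) / denom
            mode += float(np.clip(delta, -0.5, 0.5)) * bin_width
    return float(mode)


def detect_port_saturation(frames: list[Frame], det: DetectorModel) -> list[PortOffsetRecord]:
    """Find, per readout port, the first frame containing a saturated pixel."""
    records: dict[tuple[int, int], PortOffsetRecord] = {}
    for i, fr in enumerate(frames):
        sat = fr.status == STATUS_SATURATED
        if not sat.any():
            continue
        for port in det.port_ids():
            if port in records:
                continue
            rsl, csl = det.port_region(port)
            if sat[rsl, csl].any():
                records[port] = PortOffsetRecord(port=port, first_saturated_frame=i)
    return list(records.values())


def correct_ports(
    frames: list[Frame],
    det: DetectorModel,
    records: list[PortOffsetRecord],
    per_frame: bool = True,
    bin_width: float = 0.1,
    min_pixels: int = 500,
) -> list[Frame]:
    """Subtract the post-saturation background offset from affected ports.

    For each recorded port the offset is removed from all its pixels in
    every frame *after* the saturation event.  With ``per_frame`` the
    offset is re-estimated from the edge ROI of each frame (robust to
    drifting levels); otherwise the estimate from the first post-event
    frame is reused for the whole tail.  Returns corrected copies; input
    frames are untouched.
    """
    out = [fr.copy() for fr in frames]
    for rec in records:
        rsl, csl = det.port_region(rec.port)
        first = rec.first_saturated_frame
        event_offset = None
        estimates = []
        for i in range(first + 1, len(out)):
            if per_frame or event_offset is None:
                try:
                    off = estimate_port_offset(out[i], rec.port, det, bin_width, min_pixels)
                except ValueError:
                    off = event_offset if event_offset is not None else 0.0
                if event_offset is None:
                    event_offset = off
            if not per_frame:
                off = event_offset
            out[i].intensity[rsl, csl] -= off
            estimates.append(off)
        rec.offset = float(np.mean(estimates)) if estimates else 0.0
    return out


# ---------------------------------------------------------------------------
# Hit sorting and extraction
# ---------------------------------------------------------------------------


def roi_sum(frame: Frame, center_xy: tuple[float, float], size: int = 512) -> float:
    """Summed intensity in a ``size`` x ``size`` pixel ROI centered on the
    assumed direct-beam position; missing/saturated pixels are excluded."""
    ny, nx = frame.intensity.shape
    cx, cy = center_xy
    h = size // 2
    x0, x1 = int(round(cx)) - h, int(round(cx)) + (size - h)
    y0, y1 = int(round(cy)) - h, int(round(cy)) + (size - h)
    x0, x1 = max(0, x0), min(nx, x1)
    y0, y1 = max(0, y0), min(ny, y1)
    sub_i = frame.intensity[y0:y1, x0:x1]
    sub_v = frame.valid[y0:y1, x0:x1]
    if not sub_v.any():
        raise ValueError("ROI fully masked")
    return float(sub_i[sub_v].sum())


def extract_hits(
    roi_sums: dict[str, float],
    threshold: float,
    no_signal_threshold: float = 100.0,
) -> pd.DataFrame:
    """Partition frames by ROI sum into no-signal / below / above threshold.

    ``is_hit`` (extraction set) means strictly above ``threshold``.  The
    no-signal class (ROI sum below a much lower second threshold, default
    100 photons) separates genuinely empty shots from weak hits in the
    summary histogram.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    rows = []
    for fid in sorted(roi_sums):
        s = roi_sums[fid]
        if s > threshold:
            klass = "hit"
        elif s < no_signal_threshold:
            klass = "no_signal"
        else:
            klass = "below"
        rows.append({"frame_id": fid, "roi_sum": s, "class": klass,
                     "is_hit": klass == "hit", "threshold": threshold})
    return pd.DataFrame(rows, columns=["frame_id", "roi_sum", "class", "is_hit", "threshold"])


def roi_sum_quantiles(roi_sums: dict[str, float], q=(0.5, 0.75, 0.9, 0.95, 0.99)) -> pd.Series:
    """ROI-sum quantiles, a starting point for manual threshold choice
    (automatic threshold selection is intentionally not provided)."""
    return pd.Series(roi_sums).quantile(list(q))


# ---------------------------------------------------------------------------
# File-level driver
# ---------------------------------------------------------------------------


def tamon_run(
    run_path,
    dark_path,
    out_path,
    threshold: float,
    roi_size: int = 512,
    saturation_limit: float = 2500.0,
    no_signal_threshold: float = 100.0,
    per_frame_offsets: bool = True,
    keep_all: bool = False,
) -> dict:
    """Full preprocessing pass over a raw run file.

    Assembles every frame of every detector, subtracts the averaged dark
    stack, flags saturation, corrects post-saturation port offsets, sorts
    frames by small-angle ROI sum and writes the extracted (above
    threshold) frames to an assembled run file.  Returns a summary dict
    with the hit table and per-detector port records.
    """
    summary: dict = {"ports": {}, "n_frames": 0}
    with RunReader(run_path) as run, RunReader(dark_path) as darkrun:
        dets = run.detectors
        dark_mean = {
            name: average_darks([assemble(darkrun.raw_panels(f, name), det)
                                 for f in darkrun.frame_ids])
            for name, det in dets.items()
        }
        frames: dict[str, list[Frame]] = {}
        fids = run.frame_ids
        summary["n_frames"] = len(fids)
        for name, det in dets.items():
            fl = []
            for fid in fids:
                fr = assemble(run.raw_panels(fid, name), det)
                fr.frame_id = fid
                fr = subtract_dark(fr, dark_mean[name])
                fr = flag_saturated(fr, saturation_limit)
                fl.append(fr)
            records = detect_port_saturation(fl, det)
            fl = correct_ports(fl, det, records, per_frame=per_frame_offsets)
            frames[name] = fl
            summary["ports"][name] = records
        # hit finding on the wide-angle (first-listed octal-like) detector
        hit_det = "octal" if "octal" in dets else sorted(dets)[0]
        det = dets[hit_det]
        sums = {
            fr.frame_id: roi_sum(fr, (det.nominal_center.x, det.nominal_center.y), roi_size)
            for fr in frames[hit_det]
        }
        table = extract_hits(sums, threshold, no_signal_threshold)
        keep = list(table.frame_id[table.is_hit]) if not keep_all else fids
        with RunWriter(out_path, dets, run.beam, run.attenuator, kind="assembled") as w:
            for fid in fids:
                if fid not in keep:
                    continue
                w.add_assembled_frame(
                    {name: frames[name][fids.index(fid)] for name in dets},
                    pulse_id=run.pulse_id(fid),
                )
    summary["hit_table"] = table
    summary["n_hits"] = int(table.is_hit.sum())
    summary["class_counts"] = table["class"].value_counts().to_dict()
    return summary


def load_assembled(path) -> tuple[RunReader, dict[str, list[Frame]]]:
    """Read an assembled run into memory as {detector: [Frame, ...]}."""
    run = RunReader(path)
    out: dict[str, list[Frame]] = {name: [] for name in run.detectors}
    for fid in run.frame_ids:
        for name in run.detectors:
            inten, status = run.assembled(fid, name)
            out[name].append(Frame(inten, status, frame_id=fid, detector=name))
    return run, out
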