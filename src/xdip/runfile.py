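"""HDF5 run-file schema shared by the simulator and the preprocessing stage.

A *run* is one raster scan's worth of detector frames in a single HDF5
file.  Two layouts exist under the same container:

``kind="raw"``
    What the data-acquisition side produces: per frame, one
    ``(n_panels, rows, cols)`` float32 stack *per detector* in raw panel
    coordinates.  Assembly into a single image is the preprocessing
    stage's job.

``kind="assembled"``
    What preprocessing writes back out: per frame and detector, an
    assembled ``intensity`` image plus a ``status`` byte mask.

Layout::

    /                 attrs: schema, schema_version, kind, seed (optional)
    /geometry         attrs: beam_photon_energy_keV, ...; one YAML string
                      dataset per detector
    /frames/00000     attrs: pulse_id
        /<detector>/panels            (raw)
        /<detector>/intensity,status  (assembled)

All objects are created with HDF5 time-tracking disabled so that a run
written twice from the same seed is byte-identical.
"""

from __future__ import annotations

import h5py
import numpy as np
import yaml

from .geometry import Attenuator, BeamParameters, DetectorModel, detector_from_dict, detector_to_dict

SCHEMA = "xdip-run"
SCHEMA_VERSION = 1


def _notime_group(parent: h5py.Group, name: str) -> h5py.Group:
    """Create a subgroup with object-header time tracking off."""
    gcpl = h5py.h5p.create(h5py.h5p.GROUP_CREATE)
    gcpl.set_obj_track_times(False)
    gid = h5py.h5g.create(parent.id, name.encode(), gcpl=gcpl)
    return h5py.Group(gid)


def _write_ds(group: h5py.Group, name: str, data: np.ndarray) -> None:
    group.create_dataset(name, data=data, track_times=False)


class RunWriter:
    """Sequential writer for a run file."""

    def __init__(
        self,
        path,
        detectors: dict[str, DetectorModel],
        beam: BeamParameters,
        attenuator: Attenuator | None = None,
        kind: str = "raw",
        seed: int | None = None,
    ):
        if kind not in ("raw", "assembled"):
            raise ValueError(kind)
        self._fh = h5py.File(path, "w", libver="earliest")
        root = self._fh["/"]
        root.attrs["schema"] = SCHEMA
        root.attrs["schema_version"] = SCHEMA_VERSION
        root.attrs["kind"] = kind
        if seed is not None:
            root.attrs["seed"] = int(seed)
        geo = _notime_group(root, "geometry")
        geo.attrs["beam_photon_energy_keV"] = beam.photon_energy
        geo.attrs["beam_pulse_scale_photons"] = beam.pulse_scale
        if attenuator is not None:
            geo.attrs["attenuator_material"] = attenuator.material
            geo.attrs["attenuator_thickness_um"] = attenuator.thickness
        for name, det in detectors.items():
            _write_ds(geo, name, np.bytes_(yaml.safe_dump(detector_to_dict(det), sort_keys=True)))
        self._frames = _notime_group(root, "frames")
        self._kind = kind
        self._n = 0

    def add_raw_frame(self, panels: dict[str, np.ndarray], pulse_id: int | None = None) -> str:
        """Append one frame of raw panel stacks, one stack per detector."""
        assert self._kind == "raw"
        fid = f"{self._n:05d}"
        g = _notime_group(self._frames, fid)
        g.attrs["pulse_id"] = int(pulse_id if pulse_id is not None else self._n)
        for det_name, stack in panels.items():
            dg = _notime_group(g, det_name)
            _write_ds(dg, "panels", np.asarray(stack, dtype=np.float32))
        self._n += 1
        return fid

    def add_assembled_frame(self, frames: dict[str, "object"], pulse_id: int | None = None) -> str:
        """Append one frame of assembled images (`preprocess.Frame` per detector)."""
        assert self._kind == "assembled"
        fid = f"{self._n:05d}"
        g = _notime_group(self._frames, fid)
        g.attrs["pulse_id"] = int(pulse_id if pulse_id is not None else self._n)
        for det_name, fr in frames.items():
            dg = _notime_group(g, det_name)
            _write_ds(dg, "intensity", np.asarray(fr.intensity, dtype=np.float32))
            _write_ds(dg, "status", np.asarray(fr.status, dtype=np.uint8))
        self._n += 1
        return fid

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


class RunReader:
    """Read-only view of a run file."""

    def __init__(self, path):
        self._fh = h5py.File(path, "r")
        root = self._fh["/"]
        if root.attrs.get("schema") != SCHEMA:
            raise ValueError(f"{path} is not an {SCHEMA} file")
        self.kind = root.attrs["kind"]
        geo = self._fh["geometry"]
        self.beam = BeamParameters(
            photon_energy=float(geo.attrs["beam_photon_energy_keV"]),
            pulse_scale=float(geo.attrs.get("beam_pulse_scale_photons", 1.0)),
        )
        self.attenuator = None
        if "attenuator_material" in geo.attrs:
            self.attenuator = Attenuator(
                str(geo.attrs["attenuator_material"]),
                float(geo.attrs["attenuator_thickness_um"]),
            )
        self.detectors: dict[str, DetectorModel] = {}
        for name in geo:
            self.detectors[name] = detector_from_dict(yaml.safe_load(geo[name][()].decode()))

    @property
    def frame_ids(self) -> list[str]:
        return sorted(self._fh["frames"].keys())

    def __len__(self) -> int:
        return len(self._fh["frames"])

    def pulse_id(self, frame_id: str) -> int:
        return int(self._fh["frames"][frame_id].attrs["pulse_id"])

    def raw_panels(self, frame_id: str, detector: str) -> np.ndarray:
        return self._fh["frames"][frame_id][detector]["panels"][()]

    def assembled(self, frame_id: str, detector: str) -> tuple[np.ndarray, np.ndarray]:
        g = self._fh["frames"][frame_id][detector]
        return g["intensity"][()], g["status"][()]

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
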