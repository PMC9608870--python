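"""HDF5 containers for the pipeline's intermediate artifacts."""

from __future__ import annotations

import numpy as np
import h5py

from cortexlrp.preprocess import WindowedTrialSet
from cortexlrp.projection import ProjectionMap
from cortexlrp.sourcespace import CorticalSourceSpace, RegionCap
from cortexlrp.synthdata import TrialSet

__all__ = [
    "save_trials",
    "load_trials",
    "save_windowed",
    "load_windowed",
    "save_images",
    "load_images",
]

_STR = h5py.string_dtype()


def _write_space(g: h5py.Group, space: CorticalSourceSpace) -> None:
    g.create_dataset("coordinates", data=np.column_stack([space.lat, space.lon]))
    g.create_dataset("hemisphere", data=space.hemisphere.astype(object), dtype=_STR)
    g.create_dataset("regions", data=space.region.astype(object), dtype=_STR)
    caps = g.create_group("region_spec")
    for i, cap in enumerate(space.region_spec):
        c = caps.create_group(str(i))
        c.attrs.update(
            name=cap.name, hemisphere=cap.hemisphere, center_lat=cap.center_lat,
            center_lon=cap.center_lon, radius=cap.radius,
        )


def _read_space(g: h5py.Group) -> CorticalSourceSpace:
    coords = g["coordinates"][...]
    caps = [
        RegionCap(
            name=c.attrs["name"], hemisphere=c.attrs["hemisphere"],
            center_lat=float(c.attrs["center_lat"]), center_lon=float(c.attrs["center_lon"]),
            radius=float(c.attrs["radius"]),
        )
        for _, c in sorted(g["region_spec"].items(), key=lambda kv: int(kv[0]))
    ]
    return CorticalSourceSpace(
        lat=coords[:, 0], lon=coords[:, 1],
        hemisphere=g["hemisphere"].asstr()[...],
        region=g["regions"].asstr()[...],
        region_spec=caps,
    )


def save_trials(path, trials: TrialSet, space: CorticalSourceSpace) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=trials.data)
        f.create_dataset("eog", data=trials.eog)
        f.create_dataset("labels/subject_id", data=trials.subject_id.astype(np.int64))
        f.create_dataset("labels/group", data=trials.group.astype(object), dtype=_STR)
        f.create_dataset("labels/retained", data=trials.retained)
        f.create_dataset("time_ms", data=trials.time_ms)
        _write_space(f.create_group("space"), space)


def load_trials(path) -> tuple[TrialSet, CorticalSourceSpace]:
    with h5py.File(path, "r") as f:
        trials = TrialSet(
            data=f["data"][...],
            eog=f["eog"][...],
            subject_id=f["labels/subject_id"][...],
            group=f["labels/group"].asstr()[...],
            retained=f["labels/retained"][...].astype(bool),
            time_ms=f["time_ms"][...],
        )
        space = _read_space(f["space"])
    return trials, space


def save_windowed(path, windowed: WindowedTrialSet, space: CorticalSourceSpace) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=windowed.data)
        f.create_dataset("labels/subject_id", data=windowed.subject_id.astype(np.int64))
        f.create_dataset("labels/group", data=windowed.group.astype(object), dtype=_STR)
        f.create_dataset("rejected_trials", data=windowed.rejected_trials.astype(np.int64))
        f.attrs["window_ms"] = windowed.window_ms
        _write_space(f.create_group("space"), space)


def load_windowed(path) -> tuple[WindowedTrialSet, CorticalSourceSpace]:
    with h5py.File(path, "r") as f:
        windowed = WindowedTrialSet(
            data=f["data"][...],
            subject_id=f["labels/subject_id"][...],
            group=f["labels/group"].asstr()[...],
            rejected_trials=f["rejected_trials"][...],
            window_ms=tuple(f.attrs["window_ms"]),
        )
        space = _read_space(f["space"])
    return windowed, space


def _write_pmap(g: h5py.Group, pmap: ProjectionMap) -> None:
    g.attrs["grid_size"] = pmap.grid_size
    g.create_dataset("vertex_index", data=pmap.vertex_index.astype(np.int64))
    g.create_dataset("rows", data=pmap.rows.astype(np.int64))
    g.create_dataset("cols", data=pmap.cols.astype(np.int64))


def _read_pmap(g: h5py.Group) -> ProjectionMap:
    return ProjectionMap(
        grid_size=int(g.attrs["grid_size"]),
        vertex_index=g["vertex_index"][...],
        rows=g["rows"][...],
        cols=g["cols"][...],
    )


def save_images(
    path,
    images: np.ndarray,
    subject_id: np.ndarray,
    group: np.ndarray,
    left_map: ProjectionMap,
    right_map: ProjectionMap,
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=images)
        f.create_dataset("labels/subject_id", data=np.asarray(subject_id, dtype=np.int64))
        f.create_dataset("labels/group", data=np.asarray(group, dtype=object), dtype=_STR)
        _write_pmap(f.create_group("projection/left"), left_map)
        _write_pmap(f.create_group("projection/right"), right_map)


def load_images(path):
    with h5py.File(path, "r") as f:
        images = f["images"][...]
        subject_id = f["labels/subject_id"][...]
        group = f["labels/group"].asstr()[...]
        left_map = _read_pmap(f["projection/left"])
        right_map = _read_pmap(f["projection/right"])
    return images, subject_id, group, left_map, right_map
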