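"""File interfaces: SNIRF scans, PLY surfaces, CSV tables, HDF5 results.

SNIRF (Shared Near InfraRed File format) is an HDF5 layout; the subset
written here covers continuous-wave intensity data: dataTimeSeries +
time, a measurement list (source / detector / wavelength triples), the
probe block (wavelengths, optode positions and labels), per-condition
stimulus tables and the per-trial looking-time fractions as an aux
series.  Reading the subset back reproduces the scan exactly.

Surface meshes travel as ASCII PLY (via trimesh) with a sidecar CSV of
node parcel labels; the volume mesh as an HDF5 group of node/element
tables; landmarks and placements as small CSVs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import h5py
import trimesh

from .head_model import HeadMesh
from .preprocessing import RawScan, StimulusEvent

__all__ = [
    "write_snirf",
    "read_snirf",
    "write_surface_ply",
    "read_surface_ply",
    "write_head_mesh_h5",
    "read_head_mesh_h5",
    "write_landmarks_csv",
    "read_landmarks_csv",
    "write_placements_csv",
    "read_placements_csv",
    "write_sensitivity_h5",
    "read_sensitivity_h5",
]

_CONDITIONS = ("VS", "V", "NV", "baseline")


def _str(ds) -> str:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else str(v)


def write_snirf(path, scan: RawScan, optode_positions: dict | None = None) -> None:
    """Write a continuous-wave scan to a SNIRF-layout HDF5 file."""
    n_ch, n_wl, n_t = scan.intensity.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs1")
        data = nirs.create_group("data1")
        # columns ordered channel-major, wavelength-minor
        series = scan.intensity.reshape(n_ch * n_wl, n_t).T
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset("time", data=np.arange(n_t) / scan.fs)
        for ci in range(n_ch):
            for wi in range(n_wl):
                ml = data.create_group(f"measurementList{ci * n_wl + wi + 1}")
                ml.create_dataset("sourceIndex", data=ci + 1)
                ml.create_dataset("detectorIndex", data=ci + 1)
                ml.create_dataset("wavelengthIndex", data=wi + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(scan.wavelengths))
        if optode_positions:
            labels = sorted(optode_positions)
            probe.create_dataset(
                "sourcePos3D",
                data=np.array([optode_positions[k] for k in labels]),
            )
            probe.create_dataset(
                "sourceLabels",
                data=np.array(labels, dtype=h5py.string_dtype()),
            )
        for k, cond in enumerate(_CONDITIONS):
            onsets = [e.onset_s for e in scan.events if e.condition == cond]
            if not onsets:
                continue
            stim = nirs.create_group(f"stim{k + 1}")
            stim.create_dataset("name", data=cond)
            stim.create_dataset(
                "data",
                data=np.column_stack([onsets, np.full(len(onsets), 12.0),
                                      np.ones(len(onsets))]),
            )
        aux = nirs.create_group("aux1")
        aux.create_dataset("name", data="looking_fraction")
        aux.create_dataset("dataTimeSeries",
                           data=np.asarray(scan.looking_fraction, float))
        aux.create_dataset("time",
                           data=np.array([e.onset_s for e in scan.events]))
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("SubjectID",
                            data=str(scan.subject.get("subject_id", ""))
                            if isinstance(scan.subject, dict) else "")


def read_snirf(path) -> RawScan:
    """Read back the SNIRF subset written by :func:`write_snirf`."""
    with h5py.File(path, "r") as f:
        nirs = f["nirs1"]
        data = nirs["data1"]
        series = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        fs = 1.0 / float(np.median(np.diff(time)))
        wavelengths = tuple(np.asarray(nirs["probe"]["wavelengths"]).tolist())
        n_wl = len(wavelengths)
        n_ch = series.shape[1] // n_wl
        intensity = series.T.reshape(n_ch, n_wl, -1)
        stamped = []
        for key in sorted(k for k in nirs if k.startswith("stim")):
            cond = _str(nirs[key]["name"])
            for onset, *_ in np.atleast_2d(np.asarray(nirs[key]["data"])):
                stamped.append(StimulusEvent(onset_s=float(onset), condition=cond))
        stamped.sort(key=lambda e: e.onset_s)
        looking = np.asarray(nirs["aux1"]["dataTimeSeries"]) if "aux1" in nirs \
            else np.ones(len(stamped))
        subject_id = ""
        if "metaDataTags" in nirs and "SubjectID" in nirs["metaDataTags"]:
            subject_id = _str(nirs["metaDataTags"]["SubjectID"])
    return RawScan(
        intensity=intensity,
        events=stamped,
        looking_fraction=looking,
        wavelengths=wavelengths,
        fs=fs,
        subject={"subject_id": subject_id},
    )


# ---------------------------------------------------------------------------
# meshes

def write_surface_ply(path, vertices, faces, parcel_labels=None) -> None:
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    mesh.export(path, file_type="ply", encoding="ascii")
    if parcel_labels is not None:
        pd.DataFrame({"node": np.arange(len(parcel_labels)),
                      "parcel": np.asarray(parcel_labels)}).to_csv(
            str(path) + ".parcels.csv", index=False)


def read_surface_ply(path):
    mesh = trimesh.load(path, file_type="ply", process=False)
    import os
    sidecar = str(path) + ".parcels.csv"
    parcels = None
    if os.path.exists(sidecar):
        parcels = pd.read_csv(sidecar)["parcel"].to_numpy()
    return np.asarray(mesh.vertices), np.asarray(mesh.faces), parcels


def write_head_mesh_h5(path, mesh: HeadMesh) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("volume/nodes", data=mesh.volume_nodes)
        f.create_dataset("volume/tetrahedra", data=mesh.tetrahedra)
        f.create_dataset("volume/tissue",
                         data=np.array(mesh.tissue_labels, dtype="S4"))
        if mesh.node_tissue is not None:
            f.create_dataset("volume/node_tissue",
                             data=np.array(mesh.node_tissue, dtype="S4"))
        f.create_dataset("gm/nodes", data=mesh.gm_surface_nodes)
        f.create_dataset("gm/faces", data=mesh.gm_surface_faces)
        f.create_dataset("gm/parcels", data=np.asarray(mesh.parcel_labels, int))
        f.create_dataset("scalp/nodes", data=mesh.scalp_surface_nodes)
        f.create_dataset("scalp/faces", data=mesh.scalp_surface_faces)
        lm = f.create_group("landmarks")
        for k, v in mesh.landmarks.items():
            lm.create_dataset(k, data=v)


def read_head_mesh_h5(path) -> HeadMesh:
    with h5py.File(path, "r") as f:
        node_tissue = None
        if "volume/node_tissue" in f:
            node_tissue = np.array(
                [s.decode() for s in f["volume/node_tissue"]], dtype=object)
        return HeadMesh(
            volume_nodes=np.asarray(f["volume/nodes"]),
            tetrahedra=np.asarray(f["volume/tetrahedra"]),
            tissue_labels=np.array(
                [s.decode() for s in f["volume/tissue"]], dtype=object),
            gm_surface_nodes=np.asarray(f["gm/nodes"]),
            gm_surface_faces=np.asarray(f["gm/faces"]),
            scalp_surface_nodes=np.asarray(f["scalp/nodes"]),
            scalp_surface_faces=np.asarray(f["scalp/faces"]),
            parcel_labels=np.asarray(f["gm/parcels"]),
            landmarks={k: np.asarray(v) for k, v in f["landmarks"].items()},
            node_tissue=node_tissue,
        )


# ---------------------------------------------------------------------------
# small CSV tables

def write_landmarks_csv(path, landmarks: dict) -> None:
    pd.DataFrame(
        [{"name": k, "x_mm": v[0], "y_mm": v[1], "z_mm": v[2]}
         for k, v in landmarks.items()]
    ).to_csv(path, index=False)


def read_landmarks_csv(path) -> dict:
    df = pd.read_csv(path)
    return {r["name"]: np.array([r.x_mm, r.y_mm, r.z_mm])
            for _, r in df.iterrows()}


def write_placements_csv(path, rows: list[dict]) -> None:
    """rows: dicts with subject, hemisphere, x_disp_cm, y_disp_cm."""
    pd.DataFrame(rows).to_csv(path, index=False)


def read_placements_csv(path):
    from .array_registration import PlacementMeasurement

    df = pd.read_csv(path)
    out: dict[str, dict[str, PlacementMeasurement]] = {}
    for _, r in df.iterrows():
        out.setdefault(str(r.subject), {})[r.hemisphere] = PlacementMeasurement(
            hemisphere=r.hemisphere, x_disp=float(r.x_disp_cm),
            y_disp=float(r.y_disp_cm))
    return out


# ---------------------------------------------------------------------------
# sensitivity / image HDF5

def write_sensitivity_h5(path, J) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["model_tag"] = J.model_tag
        f.create_dataset("node_indices", data=J.node_indices)
        f.create_dataset(
            "channel_ids",
            data=np.array([f"{s}|{d}" for s, d in J.channel_ids],
                          dtype=h5py.string_dtype()),
        )
        for wl, v in J.values.items():
            f.create_dataset(f"J/{wl:g}", data=v)


def read_sensitivity_h5(path):
    from .photon_model import SensitivityMatrix, load_optical_properties

    with h5py.File(path, "r") as f:
        values = {float(k): np.asarray(v) for k, v in f["J"].items()}
        chans = [tuple(s.decode().split("|")) for s in f["channel_ids"]]
        return SensitivityMatrix(
            values=values,
            channel_ids=chans,
            node_indices=np.asarray(f["node_indices"]),
            optode_positions={},
            optical_properties=load_optical_properties(),
            model_tag=f.attrs.get("model_tag", "loaded"),
        )
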