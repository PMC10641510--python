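"""Readers/writers for the on-disk formats.

Raw recordings are stored either as SNIRF (the community HDF5 layout for
continuous-wave NIRS; written/read directly with h5py) or as a delimited
text fallback (rows = time, columns = channel x wavelength) with the
montage in a TSV sidecar. FC matrices are square delimited text with a
channel-name header and a JSON sidecar carrying stage/condition/subject
metadata; annotations are 3-column TSV.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import AnnotationSet, FCMatrix, HemoSeries, Montage, RawRecording

__all__ = [
    "write_snirf",
    "read_snirf",
    "write_recording_text",
    "read_recording_text",
    "write_fc_matrix",
    "read_fc_matrix",
    "write_hemo",
    "read_hemo",
]

_FMT = "%.17g"  # round-trips float64 exactly


def write_snirf(recording: RawRecording, path: str | Path) -> None:
    """Write a RawRecording to a SNIRF-layout HDF5 file.

    dataTimeSeries is time x measurement with one measurementList entry per
    channel/wavelength; montage metadata beyond source/detector indices is
    carried in metaDataTags (JSON) so a read round-trips exactly.
    """
    path = Path(path)
    n_ch = recording.n_channels
    n_t = recording.n_times
    data = np.empty((n_t, n_ch * 2))
    for w in range(2):
        data[:, w * n_ch : (w + 1) * n_ch] = recording.intensity[:, w, :].T
    sources = {s: i + 1 for i, s in enumerate(dict.fromkeys(recording.montage.table["source"]))}
    detectors = {d: i + 1 for i, d in enumerate(dict.fromkeys(recording.montage.table["detector"]))}
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=str(recording.subject.get("id", "")))
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        meta.create_dataset("montage_json", data=recording.montage.table.to_json())
        meta.create_dataset("subject_json", data=json.dumps(recording.subject))
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(recording.wavelengths, float))
        probe.create_dataset("sourceLabels", data=np.array(list(sources), dtype="S"))
        probe.create_dataset("detectorLabels", data=np.array(list(detectors), dtype="S"))
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=np.arange(n_t) / recording.fs)
        rows = recording.montage.table
        for w in range(2):
            for c in range(n_ch):
                ml = d1.create_group(f"measurementList{w * n_ch + c + 1}")
                ml.create_dataset("sourceIndex", data=sources[rows.iloc[c]["source"]])
                ml.create_dataset("detectorIndex", data=detectors[rows.iloc[c]["detector"]])
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)


def read_snirf(path: str | Path) -> RawRecording:
    """Read a SNIRF file written by :func:`write_snirf`."""
    with h5py.File(path, "r") as f:
        d1 = f["nirs/data1"]
        data = np.asarray(d1["dataTimeSeries"])
        time = np.asarray(d1["time"])
        if time.size < 2:
            raise ValueError("SNIRF time axis too short to infer sampling rate")
        fs = 1.0 / float(np.median(np.diff(time)))
        wavelengths = tuple(np.asarray(f["nirs/probe/wavelengths"], float))
        meta = f["nirs/metaDataTags"]
        montage = Montage(pd.read_json(meta["montage_json"][()].decode()))
        subject = json.loads(meta["subject_json"][()].decode())
    n_ch = montage.n_channels
    if data.shape[1] != 2 * n_ch:
        raise ValueError(
            f"SNIRF has {data.shape[1]} measurements but montage describes {n_ch} channels"
        )
    intensity = np.empty((n_ch, 2, data.shape[0]))
    for w in range(2):
        intensity[:, w, :] = data[:, w * n_ch : (w + 1) * n_ch].T
    return RawRecording(
        intensity=intensity, fs=fs, wavelengths=wavelengths, montage=montage, subject=subject
    )


def write_recording_text(recording: RawRecording, path: str | Path, montage_path=None) -> None:
    """Delimited-text fallback: rows = time, columns = CHxx_<wavelength>."""
    path = Path(path)
    cols = [
        f"{ch}_{int(lam)}"
        for lam in recording.wavelengths
        for ch in recording.montage.channels
    ]
    n_ch = recording.n_channels
    data = np.concatenate([recording.intensity[:, w, :].T for w in range(2)], axis=1)
    header = "\t".join(["time_s"] + cols)
    t = np.arange(recording.n_times) / recording.fs
    np.savetxt(
        path, np.column_stack([t, data]), delimiter="\t", header=header, comments="", fmt=_FMT
    )
    montage_path = Path(montage_path) if montage_path else path.with_suffix(".montage.tsv")
    recording.montage.to_tsv(montage_path)
    path.with_suffix(".subject.json").write_text(
        json.dumps({"subject": recording.subject, "fs": recording.fs, "wavelengths": list(recording.wavelengths)})
    )


def read_recording_text(path: str | Path, montage_path=None) -> RawRecording:
    """Read the delimited-text recording + montage TSV pair."""
    path = Path(path)
    montage_path = Path(montage_path) if montage_path else path.with_suffix(".montage.tsv")
    montage = Montage.from_tsv(montage_path)
    sidecar = json.loads(path.with_suffix(".subject.json").read_text())
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    n_ch = montage.n_channels
    wavelengths = tuple(float(w) for w in sidecar["wavelengths"])
    expected = [
        f"{ch}_{int(lam)}" for lam in wavelengths for ch in montage.channels
    ]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"recording text missing channel columns: {missing[:3]} ...")
    intensity = np.empty((n_ch, 2, len(df)))
    for w, lam in enumerate(wavelengths):
        for c, ch in enumerate(montage.channels):
            intensity[c, w, :] = df[f"{ch}_{int(lam)}"].to_numpy()
    return RawRecording(
        intensity=intensity,
        fs=float(sidecar["fs"]),
        wavelengths=wavelengths,
        montage=montage,
        subject=sidecar["subject"],
    )


def write_fc_matrix(fc: FCMatrix, path: str | Path) -> None:
    """Square delimited text with channel header + JSON sidecar."""
    path = Path(path)
    names = fc.channels or [f"CH{i + 1:02d}" for i in range(fc.n_channels)]
    pd.DataFrame(fc.values, index=names, columns=names).to_csv(path, sep="\t", float_format="%.17g")
    path.with_suffix(".json").write_text(
        json.dumps(
            {
                "stage": fc.stage,
                "condition": fc.condition,
                "subject": fc.subject,
                "n_samples_used": fc.n_samples_used,
            }
        )
    )


def read_fc_matrix(path: str | Path) -> FCMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    meta = json.loads(path.with_suffix(".json").read_text())
    return FCMatrix(
        values=df.to_numpy(dtype=float),
        stage=meta["stage"],
        condition=meta["condition"],
        subject=meta["subject"],
        n_samples_used=meta["n_samples_used"],
        channels=list(df.columns),
    )


def write_hemo(hemo: HemoSeries, path: str | Path) -> None:
    """HbO/HbR + mask as HDF5 (montage/subject embedded as JSON strings)."""
    with h5py.File(Path(path), "w") as f:
        f.create_dataset("hbo", data=hemo.hbo)
        f.create_dataset("hbr", data=hemo.hbr)
        f.create_dataset("valid_mask", data=hemo.valid_mask)
        f.create_dataset("retained_channels", data=hemo.retained_channels)
        f.attrs["fs"] = hemo.fs
        if hemo.dpf is not None:
            f.attrs["dpf"] = list(hemo.dpf)
        if hemo.montage is not None:
            f.attrs["montage_json"] = hemo.montage.table.to_json()
        f.attrs["subject_json"] = json.dumps(hemo.subject)


def read_hemo(path: str | Path) -> HemoSeries:
    with h5py.File(Path(path), "r") as f:
        montage = (
            Montage(pd.read_json(f.attrs["montage_json"])) if "montage_json" in f.attrs else None
        )
        return HemoSeries(
            hbo=np.asarray(f["hbo"]),
            hbr=np.asarray(f["hbr"]),
            fs=float(f.attrs["fs"]),
            valid_mask=np.asarray(f["valid_mask"], bool),
            retained_channels=np.asarray(f["retained_channels"], bool),
            dpf=tuple(f.attrs["dpf"]) if "dpf" in f.attrs else None,
            montage=montage,
            subject=json.loads(f.attrs["subject_json"]),
        )
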