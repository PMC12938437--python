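"""File IO: the internal HDF5 session container, the per-subject tensor
store, and optional adapters for real-data formats (MNE Raw / EDF, SNIRF).

Session container: ``<name>.h5`` with datasets ``/eeg``, ``/hbo``, ``/hbr``
and sampling-rate attributes, plus a ``<name>.json`` sidecar holding events
and both montages.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .preprocess import SampleSet
from .synthgen import Montage, RecordingPair

__all__ = ["write_session", "read_session", "write_samples", "read_samples",
           "from_mne_raw", "write_snirf", "read_snirf"]


def _montage_to_json(m: Montage) -> dict:
    return {"names": list(m.names), "xy": m.xy.tolist(), "modality": m.modality}


def _montage_from_json(d: dict) -> Montage:
    return Montage(tuple(d["names"]), np.asarray(d["xy"]), d["modality"])


def write_session(pair: RecordingPair, path) -> Path:
    """Write one session to ``path``.h5 + ``path``.json sidecar."""
    path = Path(path)
    h5path = path.with_suffix(".h5")
    with h5py.File(h5path, "w") as f:
        f.create_dataset("eeg", data=pair.eeg)
        f.create_dataset("hbo", data=pair.fnirs_hbo)
        f.create_dataset("hbr", data=pair.fnirs_hbr)
        f.attrs["fs_eeg"] = pair.fs_eeg
        f.attrs["fs_fnirs"] = pair.fs_fnirs
    sidecar = {"events": [[float(t), int(l)] for t, l in pair.events],
               "montage_eeg": _montage_to_json(pair.montage_eeg),
               "montage_fnirs": _montage_to_json(pair.montage_fnirs)}
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    return h5path


def read_session(path) -> RecordingPair:
    path = Path(path)
    with h5py.File(path.with_suffix(".h5"), "r") as f:
        eeg = f["eeg"][()]
        hbo = f["hbo"][()]
        hbr = f["hbr"][()]
        fs_eeg = float(f.attrs["fs_eeg"])
        fs_fnirs = float(f.attrs["fs_fnirs"])
    side = json.loads(path.with_suffix(".json").read_text())
    events = [(float(t), int(l)) for t, l in side["events"]]
    pair = RecordingPair(eeg, fs_eeg, hbo, hbr, fs_fnirs, events,
                         _montage_from_json(side["montage_eeg"]),
                         _montage_from_json(side["montage_fnirs"]))
    pair.validate()
    return pair


def write_samples(samples: SampleSet, path) -> Path:
    path = Path(path).with_suffix(".h5")
    with h5py.File(path, "w") as f:
        f.create_dataset("eeg_samples", data=samples.eeg)
        f.create_dataset("fnirs_samples", data=samples.fnirs)
        f.create_dataset("labels", data=samples.labels.astype(np.int64))
        f.create_dataset("trial_ids", data=samples.trial_ids.astype(np.int64))
        f.create_dataset("anchor_offsets", data=samples.anchor_offsets)
        f.attrs["subject_id"] = samples.subject_id
    return path


def read_samples(path) -> SampleSet:
    with h5py.File(Path(path).with_suffix(".h5"), "r") as f:
        return SampleSet(f["eeg_samples"][()], f["fnirs_samples"][()],
                         f["labels"][()], f["trial_ids"][()],
                         f["anchor_offsets"][()], str(f.attrs["subject_id"]))


# ---------------------------------------------------------------------------
# real-data adapters (optional)
# ---------------------------------------------------------------------------

def from_mne_raw(raw_eeg, raw_hbo: np.ndarray, raw_hbr: np.ndarray,
                 fs_fnirs: float, events: list, montage_eeg: Montage,
                 montage_fnirs: Montage) -> RecordingPair:
    """Map an MNE ``Raw`` EEG object (e.g. from ``mne.io.read_raw_edf``) plus
    fNIRS concentration arrays to a :class:`RecordingPair`.

    EEG data is converted from MNE's volts to microvolts.
    """
    eeg = raw_eeg.get_data() * 1e6
    pair = RecordingPair(eeg, float(raw_eeg.info["sfreq"]), raw_hbo, raw_hbr,
                         fs_fnirs, events, montage_eeg, montage_fnirs)
    pair.validate()
    return pair


def write_snirf(path, hbo: np.ndarray, hbr: np.ndarray, fs: float,
                montage: Montage) -> Path:
    """Minimal SNIRF (HDF5 layout) writer for processed concentration data:
    one data block, dataType 99999 (processed), dataTypeLabel HbO/HbR."""
    path = Path(path)
    n_ch, n_t = hbo.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=np.bytes_("1.0"))
        nirs = f.create_group("nirs")
        d1 = nirs.create_group("data1")
        block = np.vstack([hbo, hbr]).T  # time x measurement
        d1.create_dataset("dataTimeSeries", data=block)
        d1.create_dataset("time", data=np.arange(n_t) / fs)
        for i in range(2 * n_ch):
            ml = d1.create_group(f"measurementList{i + 1}")
            ml.create_dataset("sourceIndex", data=i % n_ch + 1)
            ml.create_dataset("detectorIndex", data=i % n_ch + 1)
            ml.create_dataset("dataType", data=99999)
            ml.create_dataset("dataTypeLabel",
                              data=np.bytes_("HbO" if i < n_ch else "HbR"))
        probe = nirs.create_group("probe")
        pos = np.column_stack([montage.xy, np.zeros(n_ch)])
        probe.create_dataset("sourcePos3D", data=pos)
        probe.create_dataset("detectorPos3D", data=pos)
    return path


def read_snirf(path) -> tuple:
    """Read the minimal SNIRF layout written by :func:`write_snirf`.

    Returns (hbo, hbr, fs, positions).
    """
    with h5py.File(path, "r") as f:
        d1 = f["nirs/data1"]
        block = d1["dataTimeSeries"][()]
        t = d1["time"][()]
        fs = 1.0 / float(np.median(np.diff(t)))
        labels = []
        i = 1
        while f"measurementList{i}" in d1:
            labels.append(d1[f"measurementList{i}/dataTypeLabel"][()].decode())
            i += 1
        labels = np.array(labels)
        hbo = block[:, labels == "HbO"].T
        hbr = block[:, labels == "HbR"].T
        pos = f["nirs/probe/sourcePos3D"][()][:, :2]
    return hbo, hbr, fs, pos
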