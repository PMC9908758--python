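"""Reading and writing datasets.

The canonical on-disk format is a plain directory: ``dataset.json``
(montage, sampling metadata, design, provenance) plus one ``.npy`` array
per subject x condition cell, and a ``manifest.json`` listing every file
with its SHA-256 checksum.  It round-trips bit-exactly.

External EEG formats (EDF, BrainVision, EEGLAB .set) are import-only
conveniences delegated to :mod:`mne`.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .containers import CONDITIONS, EpochedEEG, EvokedDataset, condition_factors
from .montage import ElectrodeMontage

__all__ = ["read_dataset", "write_dataset", "read_behavioral", "write_behavioral"]

_FORMATS = ("canonical", "edf", "brainvision", "eeglab_set")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _cell_filename(subject: str, condition: str) -> str:
    return f"sub-{subject}_cond-{condition}.npy"


def write_dataset(
    data: Sequence[EpochedEEG] | EvokedDataset,
    path: str | Path,
    provenance: Mapping | None = None,
) -> dict:
    """Write an epoched collection or an evoked dataset to a directory.

    Returns the manifest: a mapping file name -> SHA-256 checksum.  The
    checksum of an array file changes iff its contents change.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    if isinstance(data, EvokedDataset):
        montage = data.montage
        meta_cells = []
        arrays = {}
        for (subj, cond), arr in sorted(data.evoked.items()):
            fname = _cell_filename(subj, cond)
            arrays[fname] = arr
            meta_cells.append(
                {
                    "subject": subj,
                    "condition": cond,
                    "file": fname,
                    "n_epochs_used": int(data.n_epochs_used.get((subj, cond), 0)),
                }
            )
        meta = {
            "format_version": 1,
            "kind": "evoked",
            "sfreq": data.sfreq,
            "t0_offset": data.t0_offset,
            "design": {"conditions": list(CONDITIONS)},
            "cells": meta_cells,
        }
    else:
        cells = list(data)
        if not cells:
            raise ValueError("empty epoched collection")
        montage = cells[0].montage
        meta_cells = []
        arrays = {}
        for ep in cells:
            if ep.montage != montage:
                raise ValueError("all cells must share one montage")
            fname = _cell_filename(ep.subject_id, ep.condition_id)
            arrays[fname] = ep.data
            meta_cells.append(
                {
                    "subject": ep.subject_id,
                    "condition": ep.condition_id,
                    "file": fname,
                    "sfreq": ep.sfreq,
                    "t0_offset": ep.t0_offset,
                }
            )
        meta = {
            "format_version": 1,
            "kind": "epoched",
            "sfreq": cells[0].sfreq,
            "t0_offset": cells[0].t0_offset,
            "design": {"conditions": list(CONDITIONS)},
            "cells": meta_cells,
        }

    meta["montage"] = {
        "labels": list(montage.labels),
        "positions": montage.positions.tolist(),
    }
    meta["provenance"] = dict(provenance or {})

    for fname, arr in arrays.items():
        np.save(path / fname, np.ascontiguousarray(arr, dtype="<f8"))
    (path / "dataset.json").write_text(json.dumps(meta, indent=1, sort_keys=True))

    manifest = {"dataset.json": _sha256(path / "dataset.json")}
    for fname in sorted(arrays):
        manifest[fname] = _sha256(path / fname)
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _read_canonical(path: Path) -> list[EpochedEEG] | EvokedDataset:
    meta = json.loads((path / "dataset.json").read_text())
    montage = ElectrodeMontage(
        tuple(meta["montage"]["labels"]), np.array(meta["montage"]["positions"])
    )
    if meta["kind"] == "evoked":
        evoked = {}
        n_used = {}
        for cell in meta["cells"]:
            key = (cell["subject"], cell["condition"])
            evoked[key] = np.load(path / cell["file"])
            n_used[key] = cell.get("n_epochs_used", 0)
        return EvokedDataset(
            evoked=evoked,
            sfreq=meta["sfreq"],
            t0_offset=meta["t0_offset"],
            montage=montage,
            n_epochs_used=n_used,
        )
    out = []
    for cell in meta["cells"]:
        out.append(
            EpochedEEG(
                data=np.load(path / cell["file"]),
                sfreq=cell.get("sfreq", meta["sfreq"]),
                t0_offset=cell.get("t0_offset", meta["t0_offset"]),
                subject_id=cell["subject"],
                condition_id=cell["condition"],
                montage=montage,
            )
        )
    return out


def _import_mne(
    path: Path,
    fmt: str,
    montage: ElectrodeMontage,
    subject_id: str,
    condition_map: Mapping[int, str],
    epoch_window: tuple[float, float],
) -> list[EpochedEEG]:
    """Import a continuous recording via mne and epoch it on its events.

    ``condition_map`` maps integer event codes to condition ids.  Values
    are converted to microvolt; time to seconds.
    """
    import mne

    readers = {
        "edf": mne.io.read_raw_edf,
        "brainvision": mne.io.read_raw_brainvision,
        "eeglab_set": mne.io.read_raw_eeglab,
    }
    raw = readers[fmt](str(path), preload=True, verbose="error")
    missing = [ch for ch in raw.ch_names if ch not in montage.labels]
    if missing:
        raise ValueError(f"channels absent from montage: {missing}")
    raw.reorder_channels([ch for ch in montage.labels if ch in raw.ch_names])
    if raw.info["nchan"] != montage.n_channels:
        absent = sorted(set(montage.labels) - set(raw.ch_names))
        raise ValueError(f"montage channels missing from recording: {absent}")
    events, _ = mne.events_from_annotations(raw, verbose="error")
    tmin, tmax = epoch_window
    out = []
    for code, cond in condition_map.items():
        condition_factors(cond)
        sel = events[events[:, 2] == code]
        if not len(sel):
            continue
        epochs = mne.Epochs(
            raw, sel, tmin=tmin, tmax=tmax, baseline=None, preload=True, verbose="error"
        )
        data = epochs.get_data(copy=True)[..., :-1] * 1e6  # V -> uV, half-open window
        out.append(
            EpochedEEG(
                data=data,
                sfreq=float(raw.info["sfreq"]),
                t0_offset=tmin,
                subject_id=subject_id,
                condition_id=cond,
                montage=montage,
            )
        )
    return out


def read_dataset(
    path: str | Path,
    format: str = "canonical",
    *,
    montage: ElectrodeMontage | None = None,
    subject_id: str = "S01",
    condition_map: Mapping[int, str] | None = None,
    epoch_window: tuple[float, float] = (-0.050, 0.300),
) -> list[EpochedEEG] | EvokedDataset:
    """Read a dataset from disk.

    ``format='canonical'`` reads a directory written by
    :func:`write_dataset` and round-trips bit-exactly.  The other formats
    import a single continuous recording file via mne and require
    ``montage`` and ``condition_map`` (event code -> condition id).
    """
    if format not in _FORMATS:
        raise ValueError(f"unsupported format {format!r}; choose from {_FORMATS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "canonical":
        return _read_canonical(path)
    if montage is None or condition_map is None:
        raise ValueError(f"importing {format!r} requires montage and condition_map")
    return _import_mne(path, format, montage, subject_id, condition_map, epoch_window)


def write_behavioral(table, path: str | Path) -> None:
    from .containers import BehavioralTable

    if isinstance(table, BehavioralTable):
        table = table.table
    table.to_csv(path, index=False)


def read_behavioral(path: str | Path):
    import pandas as pd

    from .containers import BehavioralTable

    return BehavioralTable(pd.read_csv(path))
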