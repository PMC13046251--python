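"""Serialization: episodes as numeric matrix + JSON sidecar + label
table; PLV stacks; optional EDF export for clinical viewers.

The primary on-disk layout for an episode ``<prefix>`` is

* ``<prefix>.signal.npz`` (or ``.csv``) — channels x samples matrix;
* ``<prefix>.meta.json`` — sampling rate, channel names, segment
  boundaries, onset time, compression, seed;
* ``<prefix>.labels.csv`` — one row per window: start, end, ychimera,
  ystate, ytime, cluster order parameters, contrast.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MultiChannelSignal, WindowLabels
from .episodes import LabeledEpisode

__all__ = ["save_episode", "load_episode", "labels_to_frame",
           "save_plv_stack", "load_plv_stack", "export_edf"]


def labels_to_frame(labels: list[WindowLabels]) -> pd.DataFrame:
    """Window-label table with documented column order."""
    rows = []
    for w in labels:
        row = {
            "start_s": w.window[0],
            "end_s": w.window[1],
            "ychimera": w.ychimera,
            "ystate": w.ystate,
            "ytime_min": w.ytime,
            "contrast": w.contrast,
        }
        for i, r in enumerate(np.atleast_1d(w.cluster_R)):
            row[f"R_cluster{i}"] = r
        rows.append(row)
    return pd.DataFrame(rows)


def save_episode(episode: LabeledEpisode, prefix: str | Path,
                 signal_format: str = "npz") -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    sig = episode.signal
    if signal_format == "npz":
        np.savez_compressed(f"{prefix}.signal.npz", data=sig.data)
    elif signal_format == "csv":
        np.savetxt(f"{prefix}.signal.csv", sig.data, delimiter=",")
    else:
        raise ValueError("signal_format must be 'npz' or 'csv'")
    meta = {
        "sampling_rate": sig.sampling_rate,
        "channel_names": sig.channel_names,
        "start_time": sig.start_time,
        "onset_time": episode.onset_time,
        "segment_boundaries": {k: list(v) for k, v in episode.segment_boundaries.items()},
        "time_compression": episode.spec.time_compression if episode.spec else None,
        "seed": episode.spec.seed if episode.spec else None,
        "signal_format": signal_format,
    }
    with open(f"{prefix}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    labels_to_frame(episode.window_labels).to_csv(f"{prefix}.labels.csv", index=False)


def load_episode(prefix: str | Path) -> LabeledEpisode:
    prefix = Path(prefix)
    with open(f"{prefix}.meta.json") as fh:
        meta = json.load(fh)
    if meta.get("signal_format", "npz") == "npz":
        data = np.load(f"{prefix}.signal.npz")["data"]
    else:
        data = np.loadtxt(f"{prefix}.signal.csv", delimiter=",")
    sig = MultiChannelSignal(
        data=data, sampling_rate=meta["sampling_rate"],
        channel_names=meta["channel_names"], start_time=meta["start_time"],
    )
    frame = pd.read_csv(f"{prefix}.labels.csv")
    r_cols = sorted(c for c in frame.columns if c.startswith("R_cluster"))
    labels = [
        WindowLabels(
            window=(row["start_s"], row["end_s"]),
            cluster_R=np.array([row[c] for c in r_cols]),
            contrast=row["contrast"],
            ychimera=int(row["ychimera"]),
            ystate=int(row["ystate"]),
            ytime=float(row["ytime_min"]),
        )
        for _, row in frame.iterrows()
    ]
    return LabeledEpisode(
        signal=sig,
        window_labels=labels,
        onset_time=meta["onset_time"],
        segment_boundaries={k: tuple(v) for k, v in meta["segment_boundaries"].items()},
    )


def save_plv_stack(plvs, path: str | Path) -> None:
    """3-axis array (window, C, C) plus window-boundary table."""
    values = np.stack([m.values for m in plvs])
    windows = np.array([m.window for m in plvs])
    np.savez_compressed(path, values=values, windows=windows)


def load_plv_stack(path: str | Path):
    from .phase import PLVMatrix

    archive = np.load(path)
    return [
        PLVMatrix(values=v, window=(float(w[0]), float(w[1])))
        for v, w in zip(archive["values"], archive["windows"])
    ]


def export_edf(signal: MultiChannelSignal, path: str | Path) -> None:
    """EDF export through MNE, when available."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError("EDF export requires the optional mne dependency") from exc
    info = mne.create_info(signal.channel_names, signal.sampling_rate, ch_types="eeg")
    raw = mne.io.RawArray(signal.data * 1e-6, info, verbose="error")
    mne.export.export_raw(str(path), raw, fmt="edf", overwrite=True)
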