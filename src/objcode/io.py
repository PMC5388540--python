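"""HDF5 / CSV / JSON persistence for stimuli, sessions and results."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .recording import NeuronRecording
from .rf import RFMap
from .stimuli import DisplayGeometry, StimulusSet, render_condition

__all__ = [
    "save_geometry",
    "load_geometry",
    "save_stimulus_set",
    "save_session",
    "load_session",
]


def save_geometry(geometry: DisplayGeometry, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(geometry), indent=2))


def load_geometry(path: str | Path) -> DisplayGeometry:
    return DisplayGeometry(**json.loads(Path(path).read_text()))


def save_stimulus_set(
    stimset: StimulusSet, h5_path: str | Path, manifest_path: str | Path,
    render: bool = False,
) -> None:
    """CSV manifest (one row per condition) plus optional HDF5 images."""
    stimset.manifest().to_csv(manifest_path, index=False)
    with h5py.File(h5_path, "w") as f:
        f.attrs["n_conditions"] = len(stimset)
        f.attrs["distance_cm"] = stimset.geometry.distance_cm
        if render:
            for cond in stimset.conditions:
                image, az, el = render_condition(
                    cond, stimset.library, stimset.geometry
                )
                g = f.create_group(f"condition_{cond.condition_id:04d}")
                g.create_dataset("image", data=image, compression="gzip")
                g.create_dataset("azimuth_deg", data=az)
                g.create_dataset("elevation_deg", data=el)


def save_session(
    recordings: list[NeuronRecording], h5_path: str | Path, csv_path: str | Path
) -> None:
    """Counts to HDF5 (neuron x condition x trial), metadata to CSV."""
    rows = []
    with h5py.File(h5_path, "w") as f:
        for rec in recordings:
            g = f.create_group(rec.neuron_id)
            g.create_dataset("spike_counts", data=rec.spike_counts)
            g.create_dataset("background_counts", data=rec.background_counts)
            if rec.rf_map is not None:
                g.create_dataset("rf_grid", data=rec.rf_map.grid)
            if rec.rf_luminance is not None:
                g.create_dataset("rf_luminance", data=rec.rf_luminance)
            rows.append(
                {
                    "neuron_id": rec.neuron_id,
                    "area": rec.area,
                    "layer": rec.layer,
                    "window_ms": rec.window_ms,
                    "latency_ms": rec.latency_ms,
                    "snr": rec.snr,
                    "rv": rec.rv,
                }
            )
    pd.DataFrame(rows).to_csv(csv_path, index=False)


def load_session(h5_path: str | Path, csv_path: str | Path) -> list[NeuronRecording]:
    meta = pd.read_csv(csv_path).set_index("neuron_id")
    out = []
    with h5py.File(h5_path, "r") as f:
        for neuron_id in f:
            g = f[neuron_id]
            m = meta.loc[neuron_id]
            out.append(
                NeuronRecording(
                    neuron_id=neuron_id,
                    area=str(m["area"]),
                    layer=str(m["layer"]),
                    spike_counts=np.asarray(g["spike_counts"]),
                    background_counts=np.asarray(g["background_counts"]),
                    window_ms=float(m["window_ms"]),
                    latency_ms=float(m["latency_ms"]),
                    snr=float(m["snr"]),
                    rv=float(m["rv"]),
                    rf_map=RFMap(grid=np.asarray(g["rf_grid"]))
                    if "rf_grid" in g
                    else None,
                    rf_luminance=np.asarray(g["rf_luminance"])
                    if "rf_luminance" in g
                    else None,
                )
            )
    return out
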