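"""HDF5 container and TSV artifacts.

One experiment lives in a single HDF5 file:

``/recording``  channels x samples float32 (+ srate, ch_names attrs)
``/events``     (sample, label) table
``/responses``  per-trial behavioral label
``/latents``    simulator ground-truth trial table (synthetic data only)
``/config``     the generator configuration as YAML text
``/epochs``     optional epoched data with time-axis attributes
``/cca``        optional fitted decomposition (filters, patterns, rho, selection)

Trial tables are exchanged as plain TSV.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .preprocess import Recording, Epochs
from .cca import CCAResult
from .synthetic_data import GeneratorConfig, SyntheticDataset


def _write_strings(group, name, values):
    group.create_dataset(name, data=np.array([str(v) for v in values], dtype=object),
                         dtype=h5py.string_dtype())


def _read_strings(dset):
    return [v.decode() if isinstance(v, bytes) else str(v) for v in dset[()]]


def save_dataset(dataset: SyntheticDataset, path):
    with h5py.File(path, "w") as f:
        rec = dataset.recording
        g = f.create_group("recording")
        g.create_dataset("data", data=rec.data.astype(np.float32),
                         compression="gzip", compression_opts=1)
        g.attrs["srate"] = rec.srate
        _write_strings(g, "ch_names", rec.ch_names)
        ev = f.create_group("events")
        ev.create_dataset("sample", data=np.array([s for s, _ in dataset.events], dtype=np.int64))
        _write_strings(ev, "label", [l for _, l in dataset.events])
        _write_strings(f, "responses", dataset.responses)
        lat = f.create_group("latents")
        for col in dataset.latents.columns:
            vals = dataset.latents[col]
            if vals.dtype == object:
                _write_strings(lat, col, vals)
            else:
                lat.create_dataset(col, data=vals.to_numpy())
        f.create_dataset("config", data=dataset.truth.to_yaml(),
                         dtype=h5py.string_dtype())


def load_dataset(path) -> SyntheticDataset:
    with h5py.File(path, "r") as f:
        g = f["recording"]
        rec = Recording(data=g["data"][()].astype(float), srate=float(g.attrs["srate"]),
                        ch_names=_read_strings(g["ch_names"]),
                        events=list(zip(f["events/sample"][()].tolist(),
                                        _read_strings(f["events/label"]))))
        responses = np.array(_read_strings(f["responses"]), dtype=object)
        lat = {}
        for col in f["latents"]:
            d = f["latents"][col]
            if d.dtype.kind in ("O", "S"):
                lat[col] = np.array(_read_strings(d), dtype=object)
            else:
                lat[col] = d[()]
        config_yaml = f["config"][()]
        if isinstance(config_yaml, bytes):
            config_yaml = config_yaml.decode()
    truth = GeneratorConfig.from_yaml(config_yaml)
    return SyntheticDataset(recording=rec, events=rec.events, responses=responses,
                            latents=pd.DataFrame(lat), truth=truth)


def save_epochs(epochs: Epochs, path, group: str = "epochs"):
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("data", data=epochs.data.astype(np.float32),
                         compression="gzip", compression_opts=1)
        g.create_dataset("times", data=epochs.times)
        g.attrs["srate"] = epochs.srate
        _write_strings(g, "ch_names", epochs.ch_names)
        g.create_dataset("metadata", data=epochs.metadata.to_json(orient="table"),
                         dtype=h5py.string_dtype())


def load_epochs(path, group: str = "epochs") -> Epochs:
    with h5py.File(path, "r") as f:
        g = f[group]
        meta_json = g["metadata"][()]
        if isinstance(meta_json, bytes):
            meta_json = meta_json.decode()
        import io as _io
        meta = pd.read_json(_io.StringIO(meta_json), orient="table")
        return Epochs(data=g["data"][()].astype(float), times=g["times"][()],
                      srate=float(g.attrs["srate"]),
                      ch_names=_read_strings(g["ch_names"]),
                      metadata=meta.reset_index(drop=True))


def save_cca(result: CCAResult, path, group: str = "cca"):
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        for name in ("w_x", "w_y", "rho", "patterns", "mean_waveforms",
                     "window_times", "cov_x"):
            g.create_dataset(name, data=getattr(result, name))
        g.attrs["window"] = result.window
        g.attrs["selected"] = -1 if result.selected is None else result.selected
        g.attrs["sign"] = result.sign
        _write_strings(g, "ch_names", result.ch_names)


def load_cca(path, group: str = "cca") -> CCAResult:
    with h5py.File(path, "r") as f:
        g = f[group]
        selected = int(g.attrs["selected"])
        return CCAResult(
            w_x=g["w_x"][()], w_y=g["w_y"][()], rho=g["rho"][()],
            patterns=g["patterns"][()], mean_waveforms=g["mean_waveforms"][()],
            window=tuple(g.attrs["window"]), window_times=g["window_times"][()],
            ch_names=_read_strings(g["ch_names"]), cov_x=g["cov_x"][()],
            selected=None if selected < 0 else selected, sign=int(g.attrs["sign"]),
        )


def save_trial_table(table: pd.DataFrame, path):
    """TSV with a stable column order and full-precision floats."""
    table.to_csv(path, sep="\t", index=False)


def load_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
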