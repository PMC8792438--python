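"""Readers and writers: feature containers, raw recordings, manifests.

Two feature-container dialects are supported:

* ``native`` — a single HDF5 file per recording with datasets
  ``values`` (windows x width), ``labels``, ``trial_index`` and attrs
  ``layout``, ``window_s``, ``normalized``, ``subject_id``,
  ``session_id``, ``n_channels``, ``n_bands``.
* ``mat_extracted_features`` — a MATLAB container holding one array per
  trial (``<prefix><trial>`` such as ``de_LDS1``), each shaped
  channels x bands x windows, plus a ``label`` vector; trials are
  flattened to the merged windows x (channels * bands) layout,
  channel-major band-minor.  Validated against synthetic fixtures
  shaped per that convention.

Raw recordings travel as ``.npz`` archives (``signal``, ``fs``,
``trial_bounds``, ``labels`` plus id strings).  Run manifests are plain
JSON and capture everything needed to re-execute a run bit-comparably.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DialectError, LayoutError, ParseError
from .preprocess import EEGRecording, FeatureTensor

__all__ = [
    "read_feature_container",
    "write_feature_container",
    "read_raw_npz",
    "write_raw_npz",
    "load_feature_dir",
    "write_results",
    "write_manifest",
    "read_manifest",
    "save_network",
    "load_network",
]

RESULT_COLUMNS = ["split_id", "scenario", "n_domains", "accuracy", "seed", "status"]


def write_feature_container(tensor: FeatureTensor, path: str | Path) -> Path:
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=tensor.values)
        f.create_dataset("labels", data=tensor.labels)
        f.create_dataset("trial_index", data=tensor.trial_index)
        f.attrs.update(
            layout=tensor.layout,
            window_s=tensor.window_s,
            normalized=tensor.normalized,
            subject_id=tensor.subject_id,
            session_id=tensor.session_id,
            n_channels=tensor.n_channels,
            n_bands=tensor.n_bands,
        )
    return path


def _read_native(path: Path) -> FeatureTensor:
    import h5py

    try:
        with h5py.File(path, "r") as f:
            a = f.attrs
            return FeatureTensor(
                values=f["values"][...],
                labels=f["labels"][...],
                trial_index=f["trial_index"][...] if "trial_index" in f else None,
                layout=str(a.get("layout", "channel-major-band-minor")),
                window_s=float(a.get("window_s", 1.0)),
                normalized=bool(a.get("normalized", False)),
                subject_id=str(a.get("subject_id", "")),
                session_id=str(a.get("session_id", "")),
                n_channels=int(a.get("n_channels", 62)),
                n_bands=int(a.get("n_bands", 5)),
            )
    except (OSError, KeyError) as exc:
        size = path.stat().st_size if path.exists() else -1
        raise ParseError(f"cannot read {path} ({size} bytes on disk): {exc}") from exc


def _read_mat(path: Path, prefix: str = "de_LDS") -> FeatureTensor:
    from scipy.io import loadmat
    from scipy.io.matlab import MatReadError

    try:
        mat = loadmat(path)
    except (OSError, ValueError, NotImplementedError, MatReadError) as exc:
        size = path.stat().st_size if path.exists() else -1
        raise ParseError(f"cannot read {path} ({size} bytes on disk): {exc}") from exc

    trial_keys = sorted(
        (k for k in mat if re.fullmatch(re.escape(prefix) + r"\d+", k)),
        key=lambda k: int(k[len(prefix) :]),
    )
    if not trial_keys:
        raise ParseError(f"{path}: no '{prefix}<n>' trial arrays found")
    labels = None
    if "label" in mat:
        labels = np.asarray(mat["label"]).ravel().astype(int)

    rows, row_labels, row_trials = [], [], []
    for t, key in enumerate(trial_keys):
        arr = np.asarray(mat[key], dtype=float)  # channels x bands x windows
        if arr.ndim != 3:
            raise LayoutError(f"{path}:{key}: expected 3-d array, got shape {arr.shape}")
        n_ch, n_bands, n_win = arr.shape
        flat = arr.transpose(2, 0, 1).reshape(n_win, n_ch * n_bands)
        if flat.shape[1] != n_ch * n_bands:
            raise LayoutError(
                f"{path}:{key}: width {flat.shape[1]} != channels*bands {n_ch * n_bands}"
            )
        rows.append(flat)
        lab = int(labels[t]) if labels is not None and t < len(labels) else 0
        row_labels.extend([lab] * n_win)
        row_trials.extend([t] * n_win)
    values = np.vstack(rows)
    return FeatureTensor(
        values=values,
        labels=np.asarray(row_labels),
        trial_index=np.asarray(row_trials),
        n_channels=rows[0].shape[1] // n_bands,
        n_bands=n_bands,
    )


def read_feature_container(path: str | Path, dialect: str = "native") -> FeatureTensor:
    """Load one recording's feature tensor.

    ``dialect`` is ``"native"`` (HDF5) or ``"mat_extracted_features"``.
    """
    path = Path(path)
    if dialect == "native":
        return _read_native(path)
    if dialect == "mat_extracted_features":
        return _read_mat(path)
    raise DialectError(f"unknown dialect {dialect!r}")


def write_raw_npz(recording: EEGRecording, path: str | Path) -> Path:
    path = Path(path)
    np.savez(
        path,
        signal=recording.signal,
        fs=recording.fs,
        trial_bounds=np.asarray(recording.trial_boundaries, dtype=int),
        labels=recording.labels,
        subject_id=recording.subject_id,
        session_id=recording.session_id,
    )
    return path


def read_raw_npz(path: str | Path) -> EEGRecording:
    path = Path(path)
    try:
        with np.load(path, allow_pickle=False) as z:
            return EEGRecording(
                signal=z["signal"],
                fs=float(z["fs"]),
                trial_boundaries=[tuple(b) for b in z["trial_bounds"]],
                labels=z["labels"],
                subject_id=str(z["subject_id"]),
                session_id=str(z["session_id"]),
            )
    except (OSError, ValueError, KeyError) as exc:
        size = path.stat().st_size if path.exists() else -1
        raise ParseError(f"cannot read {path} ({size} bytes on disk): {exc}") from exc


def load_feature_dir(directory: str | Path) -> dict[tuple[str, str], FeatureTensor]:
    """Load every ``*.h5`` native container under ``directory`` into a grid."""
    directory = Path(directory)
    grid: dict[tuple[str, str], FeatureTensor] = {}
    for p in sorted(directory.glob("*.h5")):
        t = _read_native(p)
        grid[t.key] = t
    if not grid:
        raise ParseError(f"no .h5 feature containers under {directory}")
    return grid


def write_results(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, columns=[c for c in RESULT_COLUMNS if c in table])
    return path


def write_manifest(
    path: str | Path,
    *,
    config,
    scenario: str,
    partitions: list[dict],
    results: pd.DataFrame | None = None,
    extra: dict | None = None,
) -> Path:
    """Write a run manifest: config snapshot, partitions, results, stamps."""
    from . import __version__

    cfg = asdict(config)
    cfg["kernel"] = asdict(config.kernel)
    doc = {
        "package_version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "scenario": scenario,
        "train_config": cfg,
        "partitions": partitions,
        "results": results.to_dict(orient="records") if results is not None else None,
    }
    if extra:
        doc.update(extra)
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2, default=str))
    return path


def read_manifest(path: str | Path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ParseError(f"cannot read manifest {path}: {exc}") from exc


def manifest_train_config(doc: dict):
    """Rebuild a TrainConfig (and its KernelConfig) from a manifest."""
    from .mmd import KernelConfig
    from .train import TrainConfig

    cfg = dict(doc["train_config"])
    cfg["kernel"] = KernelConfig(**cfg["kernel"])
    cfg["alpha"] = cfg.get("alpha", None)
    return TrainConfig(**cfg)


def save_network(network, path: str | Path) -> Path:
    """Persist a trained network as an ``.npz`` of parameters + config JSON."""
    from dataclasses import asdict as dc

    path = Path(path)
    arrays = {f"p{i}": p for i, p in enumerate(network.parameters())}
    arrays["_config"] = np.frombuffer(
        json.dumps(dc(network.config)).encode(), dtype=np.uint8
    )
    arrays["_trained"] = np.asarray([int(network.trained)])
    np.savez(path, **arrays)
    return path


def load_network(path: str | Path):
    from .model import ModelConfig, MSMRANetwork

    path = Path(path)
    try:
        with np.load(path, allow_pickle=False) as z:
            cfg_doc = json.loads(bytes(z["_config"]).decode())
            for k in ("common_dims", "branch_dims"):
                cfg_doc[k] = tuple(cfg_doc[k])
            net = MSMRANetwork(ModelConfig(**cfg_doc), seed=0)
            for i, p in enumerate(net.parameters()):
                p[...] = z[f"p{i}"]
            net.trained = bool(z["_trained"][0])
            return net
    except (OSError, ValueError, KeyError) as exc:
        raise ParseError(f"cannot load network from {path}: {exc}") from exc
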