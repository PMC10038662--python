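"""Plain-text and HDF5 readers/writers for the pipeline's data objects.

Formats:

* Triplet trials — tab-separated with header ``objA objB objC choice``,
  0-based integer indices, one trial per row.
* Embeddings — whitespace-delimited matrix, one object per row, with an
  optional ``.meta`` sidecar of ``key: value`` lines (object ids, dimension
  labels, training configuration, seed).
* Square similarity/dissimilarity matrices — TSV with object ids as header
  row and first column.
* Dimensionality curves — TSV with a ``size`` column followed by one column
  per replicate.
* RepeatedMeasures / FusionDataset — HDF5 containers with named datasets
  (``responses``, ``sensor_data``, ``roi/<name>``, ``sessions``,
  ``time_ms``) and generator parameters stored as attributes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .extrapolation import DimCurve
from .synthetic import FusionDataset, RepeatedMeasures, TripletDataset

_TRIPLET_COLUMNS = ["objA", "objB", "objC", "choice"]


def write_triplets(path, data: TripletDataset) -> None:
    df = pd.DataFrame(data.trials, columns=_TRIPLET_COLUMNS)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_triplets(path, n_objects: int | None = None) -> TripletDataset:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _TRIPLET_COLUMNS:
        raise ValueError(f"expected columns {_TRIPLET_COLUMNS}, got {list(df.columns)}")
    trials = df.to_numpy(dtype=np.int64)
    if n_objects is None:
        n_objects = int(trials[:, :3].max()) + 1 if trials.size else 0
    return TripletDataset(trials, n_objects)


def write_embedding(path, weights: np.ndarray, metadata: dict | None = None) -> None:
    path = Path(path)
    np.savetxt(path, np.asarray(weights, dtype=float), fmt="%.10g")
    if metadata is not None:
        with open(path.with_suffix(path.suffix + ".meta"), "w") as fh:
            for key, value in metadata.items():
                if dataclasses.is_dataclass(value):
                    value = dataclasses.asdict(value)
                fh.write(f"{key}: {json.dumps(value, default=str)}\n")


def read_embedding(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    weights = np.atleast_2d(np.loadtxt(path))
    meta_path = path.with_suffix(path.suffix + ".meta")
    metadata: dict = {}
    if meta_path.exists():
        for line in meta_path.read_text().splitlines():
            if ":" in line:
                key, value = line.split(":", 1)
                metadata[key.strip()] = json.loads(value.strip())
    return weights, metadata


def write_matrix(path, values: np.ndarray, object_ids) -> None:
    df = pd.DataFrame(np.asarray(values, dtype=float),
                      index=list(object_ids), columns=list(object_ids))
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("matrix header row and column must match")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_dim_curve(path, curve: DimCurve) -> None:
    n_rep = curve.dims_per_replicate.shape[1]
    df = pd.DataFrame(curve.dims_per_replicate,
                      columns=[f"rep{i}" for i in range(n_rep)])
    df.insert(0, "size", curve.sizes)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_dim_curve(path) -> DimCurve:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "size":
        raise ValueError("first column must be 'size'")
    return DimCurve(df["size"].to_numpy(dtype=float),
                    df.iloc[:, 1:].to_numpy(dtype=float))


def write_repeated_measures(path, data: RepeatedMeasures, **attrs) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("responses", data=data.responses)
        ds.attrs.update(attrs)
        fh.create_dataset("channel_ids", data=np.array(data.channel_ids, dtype="S"))
        fh.create_dataset("image_ids", data=np.array(data.image_ids, dtype="S"))


def read_repeated_measures(path) -> RepeatedMeasures:
    with h5py.File(path, "r") as fh:
        return RepeatedMeasures(
            fh["responses"][()],
            [s.decode() for s in fh["channel_ids"][()]],
            [s.decode() for s in fh["image_ids"][()]],
        )


def write_fusion_dataset(path, data: FusionDataset, **attrs) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("sensor_data", data=data.sensor_data)
        ds.attrs.update(attrs)
        fh.create_dataset("sessions", data=data.session_labels)
        fh.create_dataset("time_ms", data=data.time_axis)
        fh.attrs["baseline_window"] = list(data.baseline_window)
        grp = fh.create_group("roi")
        for name, resp in data.roi_responses.items():
            grp.create_dataset(name, data=resp)


def read_fusion_dataset(path) -> FusionDataset:
    with h5py.File(path, "r") as fh:
        return FusionDataset(
            fh["sensor_data"][()],
            {name: fh["roi"][name][()] for name in fh["roi"]},
            fh["sessions"][()],
            fh["time_ms"][()],
            tuple(fh.attrs["baseline_window"]),
        )


def convert_neuro_recording(path):  # pragma: no cover - documented stub
    """Stub defining the expected container layout for real recordings.

    Real multimodal recordings must be converted into the
    :class:`~sposekit.synthetic.FusionDataset` HDF5 layout written by
    :func:`write_fusion_dataset` (``sensor_data`` trials x sensors x
    timepoints, per-region scalar responses under ``roi/<name>``, integer
    ``sessions``, millisecond ``time_ms``). Two open conversion choices are
    left to the user because acquisition designs differ: (1) whether region
    responses are averaged across subjects before or after matching trials
    to stimuli, and (2) how sensor trials are matched to the stimuli of the
    other modality when the two experiments used different trial orders.
    This package takes no position on either; the synthetic pathway
    (`simulate_fusion_data`) generates already-matched trials.
    """
    raise NotImplementedError(
        "real-recording conversion is out of scope; see the docstring for the "
        "container layout to produce"
    )
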