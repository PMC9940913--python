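"""Data containers and file formats.

Conventions shared by the whole package:

* activity matrices are neuron-major, shape ``(N, T)``, entries in {0, 1};
* frames are 0-based and segment boundaries are half-open ``[start, end)``;
* HDF5 is used for activity (``/v`` dataset + ``frame_rate`` attr),
  generated samples and model parameters, TSV for annotations and
  morphology, CSV for connectivity matrices, JSON for reports and
  manifests.  Every on-disk artifact carries a ``format_version``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "BinarySpikeMatrix",
    "RegionAnnotation",
    "MorphologySet",
    "read_spike_matrix",
    "write_spike_matrix",
    "read_region_annotation",
    "write_region_annotation",
    "read_morphology",
    "write_morphology",
    "write_connectivity_csv",
    "read_connectivity_csv",
]

DATA_FORMAT_VERSION = 1


@dataclass
class BinarySpikeMatrix:
    """Binary activity of N neurons over T frames.

    ``values`` is ``(N, T)`` with entries in {0, 1}; ``frame_rate`` is in
    Hz; ``region_labels`` optionally names the anatomical region of each
    neuron (length N).
    """

    values: np.ndarray
    frame_rate: float = 1.0
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("spike matrix must be 2-D (neurons x frames)")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            i, t = np.argwhere(bad)[0]
            raise ValueError(
                f"spike matrix must be binary; first offending entry at "
                f"neuron {i}, frame {t} (value {self.values[i, t]!r})"
            )
        self.values = self.values.astype(np.uint8)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.region_labels is not None:
            self.region_labels = [str(r) for r in self.region_labels]
            if len(self.region_labels) != self.values.shape[0]:
                raise ValueError("region_labels length must equal the neuron count")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def frames(self) -> np.ndarray:
        """Frame-major float view, shape (T, N), for model code."""
        return self.values.T.astype(float)


@dataclass
class RegionAnnotation:
    """Binary membership of neurons in named regions.

    ``membership`` is ``(n_regions, n_neurons)`` with entries in {0, 1};
    a neuron may belong to zero or several regions.
    """

    membership: np.ndarray
    region_names: list[str]

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership)
        if not np.isin(self.membership, (0, 1)).all():
            raise ValueError("region membership entries must be 0 or 1")
        self.membership = self.membership.astype(np.uint8)
        self.region_names = [str(r) for r in self.region_names]
        if self.membership.shape[0] != len(self.region_names):
            raise ValueError("one name per membership row is required")

    @property
    def n_regions(self) -> int:
        return self.membership.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.membership.shape[1]

    def counts(self) -> np.ndarray:
        return self.membership.sum(axis=1)

    @classmethod
    def from_labels(cls, labels: Sequence[str]) -> "RegionAnnotation":
        """One-region-per-neuron annotation from a label list."""
        names = sorted(set(str(l) for l in labels))
        idx = {r: k for k, r in enumerate(names)}
        mem = np.zeros((len(names), len(labels)), dtype=np.uint8)
        for i, lab in enumerate(labels):
            mem[idx[str(lab)], i] = 1
        return cls(membership=mem, region_names=names)


@dataclass
class MorphologySet:
    """Single-neuron morphology aggregated per region.

    ``soma_region[n]`` indexes the region hosting neuron n's soma,
    ``neurite_length[n, r]`` is the cumulative neurite length of neuron n
    inside region r (same length units throughout) and ``volumes[r]`` is
    the region volume.
    """

    soma_region: np.ndarray
    neurite_length: np.ndarray
    volumes: np.ndarray
    region_names: list[str]

    def __post_init__(self) -> None:
        self.soma_region = np.asarray(self.soma_region, dtype=int)
        self.neurite_length = np.asarray(self.neurite_length, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.region_names = [str(r) for r in self.region_names]
        n_regions = len(self.region_names)
        if self.neurite_length.ndim != 2 or self.neurite_length.shape[1] != n_regions:
            raise ValueError("neurite_length must be (n_neurons, n_regions)")
        if self.neurite_length.shape[0] != self.soma_region.shape[0]:
            raise ValueError("soma_region and neurite_length disagree on neuron count")
        if self.volumes.shape != (n_regions,):
            raise ValueError("one volume per region is required")
        if np.any(self.neurite_length < 0):
            raise ValueError("neurite lengths must be >= 0")
        if np.any(self.volumes <= 0):
            raise ValueError("region volumes must be > 0")
        if self.soma_region.min(initial=0) < 0 or self.soma_region.max(initial=0) >= n_regions:
            raise ValueError("soma_region indices out of range")

    @property
    def n_neurons(self) -> int:
        return self.soma_region.shape[0]

    @property
    def n_regions(self) -> int:
        return len(self.region_names)


# ---------------------------------------------------------------------------
# spike matrices


def write_spike_matrix(path, data: BinarySpikeMatrix) -> None:
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(
            path,
            v=data.values,
            frame_rate=data.frame_rate,
            format_version=DATA_FORMAT_VERSION,
        )
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("v", data=data.values, compression="gzip")
        f.attrs["frame_rate"] = data.frame_rate
        f.attrs["format_version"] = DATA_FORMAT_VERSION
        if data.region_labels is not None:
            f.create_dataset(
                "region_labels",
                data=np.array(data.region_labels, dtype=h5py.string_dtype()),
            )


def read_spike_matrix(path, annotation_tsv=None) -> BinarySpikeMatrix:
    """Read activity from HDF5 (``/v`` + ``frame_rate``) or NPZ.

    Non-binary files are rejected with the offending coordinate named; a
    missing frame rate falls back to 1 Hz with a warning.
    """
    import warnings

    path = Path(path)
    region_labels = None
    if path.suffix == ".npz":
        with np.load(path) as f:
            v = f["v"]
            frame_rate = float(f["frame_rate"]) if "frame_rate" in f else None
    else:
        with h5py.File(path, "r") as f:
            if "v" not in f:
                raise ValueError(f"{path} has no '/v' dataset")
            v = f["v"][...]
            frame_rate = float(f.attrs["frame_rate"]) if "frame_rate" in f.attrs else None
            if "region_labels" in f:
                region_labels = [s.decode() if isinstance(s, bytes) else str(s)
                                 for s in f["region_labels"][...]]
    if frame_rate is None:
        warnings.warn(f"{path} has no frame_rate attribute; assuming 1 Hz")
        frame_rate = 1.0
    data = BinarySpikeMatrix(values=v, frame_rate=frame_rate, region_labels=region_labels)
    if annotation_tsv is not None:
        ann = read_region_annotation(annotation_tsv)
        if ann.n_neurons != data.n_neurons:
            raise ValueError("annotation neuron count does not match the recording")
        labels = []
        for i in range(ann.n_neurons):
            rows = np.flatnonzero(ann.membership[:, i])
            labels.append(ann.region_names[rows[0]] if rows.size else "unassigned")
        data.region_labels = labels
    return data


# ---------------------------------------------------------------------------
# region annotations (TSV: neuron_id, region)


def write_region_annotation(path, ann: RegionAnnotation) -> None:
    rows = []
    for r, name in enumerate(ann.region_names):
        for i in np.flatnonzero(ann.membership[r]):
            rows.append((int(i), name))
    df = pd.DataFrame(rows, columns=["neuron_id", "region"]).sort_values(
        ["neuron_id", "region"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_region_annotation(path, n_neurons: int | None = None) -> RegionAnnotation:
    df = pd.read_csv(path, sep="\t")
    if not {"neuron_id", "region"} <= set(df.columns):
        raise ValueError("annotation TSV needs 'neuron_id' and 'region' columns")
    names = sorted(df["region"].astype(str).unique())
    idx = {r: k for k, r in enumerate(names)}
    n = int(df["neuron_id"].max()) + 1 if n_neurons is None else n_neurons
    mem = np.zeros((len(names), n), dtype=np.uint8)
    for _, row in df.iterrows():
        mem[idx[str(row["region"])], int(row["neuron_id"])] = 1
    return RegionAnnotation(membership=mem, region_names=names)


# ---------------------------------------------------------------------------
# morphology (TSV: neuron_id, soma_region, region, length  +  region, volume)


def write_morphology(neurite_path, volume_path, morph: MorphologySet) -> None:
    rows = []
    for n in range(morph.n_neurons):
        soma = morph.region_names[morph.soma_region[n]]
        for r, name in enumerate(morph.region_names):
            length = morph.neurite_length[n, r]
            if length > 0 or r == morph.soma_region[n]:
                rows.append((n, soma, name, length))
    pd.DataFrame(rows, columns=["neuron_id", "soma_region", "region", "length"]).to_csv(
        neurite_path, sep="\t", index=False
    )
    pd.DataFrame(
        {"region": morph.region_names, "volume": morph.volumes}
    ).to_csv(volume_path, sep="\t", index=False)


def read_morphology(neurite_path, volume_path) -> MorphologySet:
    neurites = pd.read_csv(neurite_path, sep="\t")
    volumes = pd.read_csv(volume_path, sep="\t")
    names = [str(r) for r in volumes["region"]]
    idx = {r: k for k, r in enumerate(names)}
    n_neurons = int(neurites["neuron_id"].max()) + 1
    soma = np.zeros(n_neurons, dtype=int)
    length = np.zeros((n_neurons, len(names)))
    for _, row in neurites.iterrows():
        n = int(row["neuron_id"])
        soma[n] = idx[str(row["soma_region"])]
        length[n, idx[str(row["region"])]] = float(row["length"])
    return MorphologySet(
        soma_region=soma,
        neurite_length=length,
        volumes=volumes["volume"].to_numpy(float),
        region_names=names,
    )


# ---------------------------------------------------------------------------
# connectivity matrices (CSV with labelled rows/columns + JSON sidecar)


def write_connectivity_csv(path, values, labels, sidecar: dict | None = None) -> None:
    path = Path(path)
    pd.DataFrame(values, index=labels, columns=labels).to_csv(path)
    meta = {"format_version": DATA_FORMAT_VERSION}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))


def read_connectivity_csv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(float), [str(c) for c in df.columns]
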