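"""Dataset container: distance-matrix collections, scaling, HDF5 persistence.

Distances enter the networks linearly mapped to [0, 1] by a dataset-wide
maximum (with clamping above it); the maximum is stored with the dataset so
generated outputs can be mapped back to Å exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np


@dataclass(frozen=True)
class ScalerState:
    """Linear [0, 1] scaling of distances by a dataset-wide maximum (Å)."""

    max_distance: float

    def __post_init__(self):
        if not (self.max_distance > 0 and np.isfinite(self.max_distance)):
            raise ValueError("max_distance must be a positive finite number")


@dataclass
class MatrixDataset:
    """A stack of equally-sized distance matrices with provenance and scaling."""

    matrices: np.ndarray              # (count, N, N) float, Å
    source_ids: list[str]
    scaler: ScalerState | None = None

    def __post_init__(self):
        self.matrices = np.asarray(self.matrices, dtype=np.float64)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must have shape (count, N, N)")
        if len(self.source_ids) != len(self.matrices):
            raise ValueError("source_ids length mismatch")

    def __len__(self) -> int:
        return len(self.matrices)

    @property
    def n_residues(self) -> int:
        return self.matrices.shape[1]


def fit_scaler(matrices) -> ScalerState:
    """Fit the [0, 1] scaler: ``max_distance`` is the dataset-wide maximum."""
    arr = np.asarray(matrices, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot fit a scaler on an empty dataset")
    mx = float(arr.max())
    if mx <= 0:
        raise ValueError("all-zero dataset: max_distance would be 0")
    return ScalerState(mx)


def apply_scale(d: np.ndarray, scaler: ScalerState) -> np.ndarray:
    """Map distances (Å) into [0, 1]; values above ``max_distance`` clamp to 1."""
    return np.clip(np.asarray(d, dtype=np.float64) / scaler.max_distance, 0.0, 1.0)


def invert_scale(m: np.ndarray, scaler: ScalerState) -> np.ndarray:
    """Map [0, 1] model outputs back to Å."""
    return np.asarray(m, dtype=np.float64) * scaler.max_distance


def save_dataset(path, dataset: MatrixDataset) -> None:
    """Write matrices, source ids and scaler to a single HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("matrices", data=dataset.matrices.astype(np.float32))
        f.create_dataset(
            "source_ids",
            data=np.array(dataset.source_ids, dtype=h5py.string_dtype()),
        )
        if dataset.scaler is not None:
            f.attrs["max_distance"] = dataset.scaler.max_distance


def load_dataset(path) -> MatrixDataset:
    """Load a container written by :func:`save_dataset`.

    Raises OSError on a missing or corrupt file; never returns a partial
    dataset.
    """
    try:
        with h5py.File(path, "r") as f:
            matrices = np.asarray(f["matrices"], dtype=np.float64)
            ids = [s.decode() if isinstance(s, bytes) else str(s)
                   for s in f["source_ids"][()]]
            scaler = None
            if "max_distance" in f.attrs:
                scaler = ScalerState(float(f.attrs["max_distance"]))
    except (OSError, KeyError) as exc:
        raise OSError(f"cannot read dataset container {path!r}: {exc}") from exc
    return MatrixDataset(matrices, ids, scaler)
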