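"""Synthetic protein-like Cα chains and distance-matrix datasets.

The generator is a jittered-angle self-avoiding walk: consecutive Cα atoms are
placed exactly ``bond_length`` (3.8 Å) apart, the pseudo-bond angle between
successive bonds is drawn around a mean with jitter, the dihedral is uniform,
and any placement closer than ``min_separation`` to a non-consecutive residue
is rejected and retried. This reproduces the statistical regimes the
structure metrics probe (backbone spacing near 3.8 Å, tunable compactness)
without simulating real protein energetics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import MatrixDataset, fit_scaler
from .traces import CaTrace, trace_to_distance_matrix


class ChainGenerationError(RuntimeError):
    """Self-avoidance could not be satisfied within the retry budget."""


@dataclass(frozen=True)
class ChainParams:
    """Parameters of the self-avoiding Cα walk.

    bond_angle_deg is the mean pseudo-bond angle between successive Cα–Cα
    bonds (real chains sit around 90–130°); bond_angle_jitter_deg its
    standard deviation. min_separation is the self-avoidance radius for
    non-consecutive residues.
    """

    n_residues: int = 128
    bond_length: float = 3.8
    bond_angle_deg: float = 105.0
    bond_angle_jitter_deg: float = 20.0
    min_separation: float = 3.4
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 2:
            raise ValueError("n_residues must be >= 2")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if not self.min_separation < 2 * self.bond_length:
            raise ValueError("min_separation must be < 2 * bond_length")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def sample_chain(params: ChainParams, rng: np.random.Generator | None = None,
                 max_tries: int = 60, max_restarts: int = 50) -> CaTrace:
    """Generate one self-avoiding Cα trace.

    Deterministic for a given ``params.seed`` (when no explicit ``rng`` is
    passed). Raises ChainGenerationError if self-avoidance cannot be
    satisfied within the retry budget.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    b = params.bond_length
    n = params.n_residues
    for _ in range(max_restarts):
        coords = np.zeros((n, 3))
        coords[1] = b * _random_unit(rng)
        ok = True
        i = 2
        while i < n:
            placed = False
            for _try in range(max_tries):
                theta = np.deg2rad(rng.normal(params.bond_angle_deg,
                                              params.bond_angle_jitter_deg))
                theta = float(np.clip(theta, np.deg2rad(45.0), np.deg2rad(175.0)))
                phi = rng.uniform(0.0, 2.0 * np.pi)
                prev = _unit(coords[i - 1] - coords[i - 2])
                # orthonormal frame around the previous bond
                ref = np.array([1.0, 0.0, 0.0])
                if abs(prev @ ref) > 0.9:
                    ref = np.array([0.0, 1.0, 0.0])
                u = _unit(np.cross(prev, ref))
                w = np.cross(prev, u)
                # new bond makes angle (pi - theta) with the previous bond
                direction = (np.cos(np.pi - theta) * prev
                             + np.sin(np.pi - theta)
                             * (np.cos(phi) * u + np.sin(phi) * w))
                cand = coords[i - 1] + b * _unit(direction)
                dists = np.linalg.norm(coords[: i - 1] - cand, axis=1)
                if np.all(dists >= params.min_separation):
                    coords[i] = cand
                    placed = True
                    break
            if not placed:
                ok = False
                break
            i += 1
        if ok:
            return CaTrace(coords, f"synthetic_seed{params.seed}")
    raise ChainGenerationError(
        f"self-avoidance unsatisfiable for n={n} after {max_restarts} restarts"
    )


def make_dataset(count: int, params: ChainParams) -> MatrixDataset:
    """Generate ``count`` chains and return their distance matrices.

    Each chain uses an independent stream derived from ``params.seed``; the
    returned dataset carries a fitted scaler.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(params.seed)
    matrices = np.empty((count, params.n_residues, params.n_residues))
    ids = []
    for k in range(count):
        try:
            trace = sample_chain(params, rng=rng)
        except ChainGenerationError as exc:
            raise ChainGenerationError(f"chain {k}: {exc}") from exc
        matrices[k] = trace_to_distance_matrix(trace)
        ids.append(f"synthetic_seed{params.seed}_{k}")
    return MatrixDataset(matrices, ids, fit_scaler(matrices))


def inject_asymmetry(d: np.ndarray, i: int, j: int, eps: float) -> np.ndarray:
    """Return a copy of symmetric ``d`` with ``eps`` added to entry (i, j) only.

    The resulting asymmetry score (Frobenius norm of D - D^T) equals
    ``|eps| * sqrt(2)`` when d was symmetric.
    """
    if i == j:
        raise IndexError("i and j must differ (diagonal perturbation has no effect)")
    out = np.array(d, dtype=np.float64)
    out[i, j] += eps
    return out
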