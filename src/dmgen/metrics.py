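"""Per-matrix structural features of Cα distance matrices.

Residue pairs (i, i+t) are classified by sequence separation t = |i - j|:
t = 1 is the backbone, 1 < t <= 4 the short range, t > 4 the long range.
Features are read from the upper triangle (i < j), a single consistent
convention for possibly-asymmetric generated matrices; asymmetry itself is
reported separately as the Frobenius norm of D - D^T.

Cutoffs are closed ("within" means <=): 4 Å for the backbone score, 10 Å for
short/long-range contacts. Mean distances average over ALL qualifying pairs
of the class, not only the pairs in contact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FEATURE_COLUMNS = [
    "avg_peptide_bond",
    "backbone_score",
    "short_range_contacts",
    "short_range_distance",
    "long_range_contacts",
    "long_range_distance",
    "asymmetry",
]


@dataclass(frozen=True)
class MetricThresholds:
    backbone_contact_cutoff: float = 4.0
    contact_cutoff: float = 10.0

    def __post_init__(self):
        if self.backbone_contact_cutoff <= 0 or self.contact_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


DEFAULT_THRESHOLDS = MetricThresholds()


def _check_square(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("expected a square matrix")
    return d


def _diagonals(d: np.ndarray, offsets) -> np.ndarray:
    return np.concatenate([np.diagonal(d, offset=t) for t in offsets])


def avg_peptide_bond(d: np.ndarray) -> float:
    """Mean consecutive-residue (t = 1) distance, Å."""
    d = _check_square(d)
    if d.shape[0] < 2:
        raise ValueError("need N >= 2")
    return float(np.diagonal(d, offset=1).mean())


def backbone_score(d: np.ndarray, thresholds: MetricThresholds = DEFAULT_THRESHOLDS) -> int:
    """Number of consecutive pairs within the 4 Å backbone cutoff."""
    d = _check_square(d)
    if d.shape[0] < 2:
        raise ValueError("need N >= 2")
    return int((np.diagonal(d, offset=1) <= thresholds.backbone_contact_cutoff).sum())


def short_range_stats(d: np.ndarray,
                      thresholds: MetricThresholds = DEFAULT_THRESHOLDS) -> tuple[int, float]:
    """(contact count, mean distance) over pairs with 1 < t <= 4."""
    d = _check_square(d)
    if d.shape[0] < 3:
        raise ValueError("need N >= 3 for short-range pairs")
    vals = _diagonals(d, range(2, min(5, d.shape[0])))
    return int((vals <= thresholds.contact_cutoff).sum()), float(vals.mean())


def long_range_stats(d: np.ndarray,
                     thresholds: MetricThresholds = DEFAULT_THRESHOLDS) -> tuple[int, float]:
    """(contact count, mean distance) over pairs with t > 4."""
    d = _check_square(d)
    n = d.shape[0]
    if n < 6:
        raise ValueError("need N >= 6 for long-range pairs")
    vals = _diagonals(d, range(5, n))
    return int((vals <= thresholds.contact_cutoff).sum()), float(vals.mean())


def asymmetry_score(d: np.ndarray) -> float:
    """Frobenius norm of D - D^T; 0 iff the matrix is symmetric."""
    d = _check_square(d)
    return float(np.linalg.norm(d - d.T, ord="fro"))


def featurize(d: np.ndarray, thresholds: MetricThresholds = DEFAULT_THRESHOLDS) -> dict:
    """All seven per-matrix features as a dict keyed by FEATURE_COLUMNS."""
    sc, sd = short_range_stats(d, thresholds)
    lc, ld = long_range_stats(d, thresholds)
    return {
        "avg_peptide_bond": avg_peptide_bond(d),
        "backbone_score": backbone_score(d, thresholds),
        "short_range_contacts": sc,
        "short_range_distance": sd,
        "long_range_contacts": lc,
        "long_range_distance": ld,
        "asymmetry": asymmetry_score(d),
    }


def featurize_set(matrices,
                  thresholds: MetricThresholds = DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """One FeatureRow per matrix; all matrices must share one size."""
    arr = np.asarray(matrices, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("expected (count, N, N) matrices of uniform size")
    if arr.shape[0] == 0:
        raise ValueError("empty set")
    return pd.DataFrame([featurize(m, thresholds) for m in arr],
                        columns=FEATURE_COLUMNS)


def summarize_features(table: pd.DataFrame) -> pd.DataFrame:
    """Column means and sample (n-1) standard deviations."""
    return pd.DataFrame({"mean": table.mean(), "std": table.std(ddof=1)})
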