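"""Pairwise similarity between distance matrices and set-vs-set protocols.

Three scores: contact score (Jaccard index of 8 Å contact maps), dRMSD
(root-mean-square deviation of corresponding upper-triangle distances), and a
TM-style score applying the classical TM kernel 1/(1 + (dev/d0)^2) with
d0(N) = 1.24 (N - 15)^(1/3) - 1.8 to per-pair distance deviations.

The set comparison mirrors a memorization check: each query matrix is scored
against every reference and the best value per query is aggregated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

CONTACT_CUTOFF = 8.0


def _check_square(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("expected a square matrix")
    return d


def _check_pair(da, db) -> tuple[np.ndarray, np.ndarray]:
    da, db = _check_square(da), _check_square(db)
    if da.shape != db.shape:
        raise ValueError("matrices must have equal sizes")
    return da, db


def contact_map(d: np.ndarray, cutoff: float = CONTACT_CUTOFF,
                include_backbone: bool = False) -> np.ndarray:
    """Boolean upper-triangle contact map at ``cutoff`` Å.

    Backbone-adjacent pairs (t = 1), which are trivially always in contact,
    are excluded unless ``include_backbone`` is set.
    """
    d = _check_square(d)
    t_min = 1 if include_backbone else 2
    mask = np.triu(np.ones(d.shape, dtype=bool), k=t_min)
    return (d <= cutoff) & mask


def contact_score(da: np.ndarray, db: np.ndarray, cutoff: float = CONTACT_CUTOFF,
                  include_backbone: bool = False) -> float:
    """Jaccard index of the two contact maps; both-empty pairs score 1."""
    da, db = _check_pair(da, db)
    a = contact_map(da, cutoff, include_backbone)
    b = contact_map(db, cutoff, include_backbone)
    union = (a | b).sum()
    if union == 0:
        return 1.0
    return float((a & b).sum() / union)


def drmsd(da: np.ndarray, db: np.ndarray) -> float:
    """RMS deviation of corresponding upper-triangle (i < j) distances, Å."""
    da, db = _check_pair(da, db)
    iu = np.triu_indices(da.shape[0], k=1)
    diff = da[iu] - db[iu]
    return float(np.sqrt(np.mean(diff * diff)))


def tm_d0(n: int) -> float:
    """Classical TM-score length normalization; defined for N > 15."""
    if n <= 15:
        raise ValueError("d0 undefined for N <= 15")
    return 1.24 * (n - 15) ** (1.0 / 3.0) - 1.8


def tm_score_dm(da: np.ndarray, db: np.ndarray) -> float:
    """TM-style similarity of two distance matrices, in (0, 1]."""
    da, db = _check_pair(da, db)
    n = da.shape[0]
    d0 = tm_d0(n)
    iu = np.triu_indices(n, k=1)
    dev = np.abs(da[iu] - db[iu])
    return float(np.mean(1.0 / (1.0 + (dev / d0) ** 2)))


@dataclass
class SimilarityReport:
    """Mean/std per metric over the query set, with the pairing policy used."""

    metrics: dict = field(default_factory=dict)   # metric -> {mean, std}
    per_query: dict = field(default_factory=dict)  # metric -> list of best scores
    pairing: str = "nearest"
    n_query: int = 0
    n_reference: int = 0

    def to_json(self) -> str:
        return json.dumps({
            "metrics": self.metrics,
            "pairing": self.pairing,
            "n_query": self.n_query,
            "n_reference": self.n_reference,
        }, indent=2)


_METRICS = {
    "contact": (contact_score, max),
    "rmsd": (drmsd, min),
    "tm": (tm_score_dm, max),
}


def set_comparison(query_set, reference_set, metrics=("contact", "rmsd", "tm"),
                   pairing: str = "nearest") -> SimilarityReport:
    """Compare every query matrix against a reference set.

    pairing="nearest" keeps, per query, the best score over the references
    (max for contact/tm, min for rmsd); pairing="allpairs" averages over all
    references instead. Means and sample stds are taken over queries.
    """
    q = np.asarray(query_set, dtype=np.float64)
    r = np.asarray(reference_set, dtype=np.float64)
    if q.ndim != 3 or r.ndim != 3 or len(q) == 0 or len(r) == 0:
        raise ValueError("query and reference must be non-empty (count, N, N) stacks")
    if q.shape[1:] != r.shape[1:]:
        raise ValueError("query and reference matrix sizes differ")
    if pairing not in ("nearest", "allpairs"):
        raise ValueError(f"unknown pairing policy {pairing!r}")
    for m in metrics:
        if m not in _METRICS:
            raise ValueError(f"unknown metric {m!r}")

    report = SimilarityReport(pairing=pairing, n_query=len(q), n_reference=len(r))
    for name in metrics:
        fn, best = _METRICS[name]
        per_query = []
        for qi in q:
            scores = [fn(qi, ri) for ri in r]
            per_query.append(best(scores) if pairing == "nearest"
                             else float(np.mean(scores)))
        arr = np.array(per_query)
        report.per_query[name] = per_query
        report.metrics[name] = {
            "mean": float(arr.mean()),
            "std": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        }
    return report
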