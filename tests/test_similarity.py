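"""Contact score, dRMSD, TM-style score and the set-comparison protocol."""

import numpy as np
import pytest

from dmgen.similarity import (
    contact_map,
    contact_score,
    drmsd,
    set_comparison,
    tm_d0,
    tm_score_dm,
)
from dmgen.traces import CaTrace, trace_to_distance_matrix

from conftest import random_symmetric_matrix


def colinear(n, spacing=3.8):
    return trace_to_distance_matrix(
        CaTrace(np.column_stack([spacing * np.arange(n), np.zeros(n), np.zeros(n)])))


def test_contact_map_all_far_is_empty():
    d = np.full((6, 6), 100.0)
    np.fill_diagonal(d, 0.0)
    assert contact_map(d).sum() == 0


def test_contact_map_colinear_marks_exactly_t2():
    d = colinear(8)
    m = contact_map(d)                       # backbone (t=1) excluded
    # 7.6 <= 8 < 11.4: exactly the t = 2 pairs
    expected = {(i, i + 2) for i in range(6)}
    assert {tuple(p) for p in np.argwhere(m)} == expected
    m_bb = contact_map(d, include_backbone=True)
    assert m_bb.sum() == m.sum() + 7          # t = 1 pairs re-included


def test_contact_score_identity_disjoint_and_fraction(rng):
    d = random_symmetric_matrix(rng, 10)
    assert contact_score(d, d) == 1.0
    # constructed 6x6 toy with |A & B| = 2, |A | B| = 5
    a = np.full((6, 6), 100.0)
    b = np.full((6, 6), 100.0)
    for (i, j) in [(0, 2), (1, 3), (2, 4)]:
        a[i, j] = a[j, i] = 5.0
    for (i, j) in [(0, 2), (1, 3), (0, 4), (1, 5)]:
        b[i, j] = b[j, i] = 5.0
    np.fill_diagonal(a, 0.0), np.fill_diagonal(b, 0.0)
    assert np.isclose(contact_score(a, b), 2 / 5)
    # disjoint contact sets
    c = np.full((6, 6), 100.0)
    c[0, 3] = c[3, 0] = 5.0
    np.fill_diagonal(c, 0.0)
    assert contact_score(a, c) == 0.0


def test_contact_score_both_empty_is_one():
    d = np.full((5, 5), 100.0)
    np.fill_diagonal(d, 0.0)
    assert contact_score(d, d.copy()) == 1.0


def test_drmsd_closed_forms_and_oracle(rng):
    d = random_symmetric_matrix(rng, 10)
    assert drmsd(d, d) == 0.0
    shifted = d + 2.0
    np.fill_diagonal(shifted, 0.0)
    assert np.isclose(drmsd(d, shifted), 2.0)
    # brute-force oracle on random pairs
    for _ in range(20):
        a = rng.random((10, 10)) * 20
        b = rng.random((10, 10)) * 20
        vals = [(a[i, j] - b[i, j]) ** 2 for i in range(10) for j in range(i + 1, 10)]
        assert np.isclose(drmsd(a, b), np.sqrt(np.mean(vals)))


def test_tm_score_closed_forms(rng):
    d = random_symmetric_matrix(rng, 20)
    assert tm_score_dm(d, d) == 1.0
    dev = tm_d0(20)
    other = d + dev
    np.fill_diagonal(other, 0.0)
    assert np.isclose(tm_score_dm(d, other), 0.5)
    with pytest.raises(ValueError):
        tm_score_dm(np.zeros((15, 15)), np.zeros((15, 15)))


def test_tm_score_monotone_in_uniform_deviation(rng):
    d = random_symmetric_matrix(rng, 20)
    scores = []
    for dev in (0.0, 0.5, 1.0, 2.0, 5.0):
        other = d + dev
        np.fill_diagonal(other, 0.0)
        scores.append(tm_score_dm(d, other))
    assert all(s1 > s2 for s1, s2 in zip(scores, scores[1:]))


def test_scores_symmetric_under_argument_exchange(rng):
    a = rng.random((18, 18)) * 15
    b = rng.random((18, 18)) * 15
    assert np.isclose(contact_score(a, b), contact_score(b, a))
    assert np.isclose(drmsd(a, b), drmsd(b, a))
    assert np.isclose(tm_score_dm(a, b), tm_score_dm(b, a))


def test_drmsd_triangle_inequality(rng):
    for _ in range(20):
        a, b, c = (rng.random((8, 8)) * 10 for _ in range(3))
        assert drmsd(a, c) <= drmsd(a, b) + drmsd(b, c) + 1e-9


def test_self_match_protocol(small_dataset):
    x = small_dataset.matrices[:6]
    report = set_comparison(x, x, pairing="nearest")
    assert report.metrics["contact"] == {"mean": 1.0, "std": 0.0}
    assert report.metrics["rmsd"] == {"mean": 0.0, "std": 0.0}
    assert report.metrics["tm"] == {"mean": 1.0, "std": 0.0}


def test_singleton_reference_equals_allpairs(small_dataset):
    q = small_dataset.matrices[:4]
    r = small_dataset.matrices[5:6]
    near = set_comparison(q, r, pairing="nearest")
    allp = set_comparison(q, r, pairing="allpairs")
    assert near.metrics == allp.metrics


def test_report_consistent_with_per_query_scores(small_dataset):
    q = small_dataset.matrices[:5]
    r = small_dataset.matrices[5:10]
    report = set_comparison(q, r)
    for name, stats in report.metrics.items():
        arr = np.array(report.per_query[name])
        assert np.isclose(stats["mean"], arr.mean())
        assert np.isclose(stats["std"], arr.std(ddof=1))


def test_invalid_metric_or_pairing_rejected(small_dataset):
    x = small_dataset.matrices[:2]
    with pytest.raises(ValueError):
        set_comparison(x, x, metrics=("nope",))
    with pytest.raises(ValueError):
        set_comparison(x, x, pairing="weird")
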