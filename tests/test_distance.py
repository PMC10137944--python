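"""Relative distance, calibration-pair collection, threshold selection and
resolution conversion — each checked against an independent brute-force
oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepaploidy import (CellAssignment, NucleusRecord, ResolutionSpec,
                        ThresholdCalibrator, collect_calibration_pairs,
                        convert_threshold, relative_distance, select_threshold)
from hepaploidy.records import NucleusPair


@pytest.mark.parametrize("d, r1, r2, expected", [
    (20.0, 5.0, 5.0, 10.0),
    (10.0, 6.0, 4.0, 0.0),   # tangent circles
    (8.0, 5.0, 5.0, -2.0),   # overlapping footprints
])
def test_relative_distance_arithmetic(d, r1, r2, expected):
    assert relative_distance(d, r1, r2) == pytest.approx(expected)
    assert relative_distance(d, r2, r1) == pytest.approx(expected)  # symmetry


def test_relative_distance_rejects_bad_inputs():
    with pytest.raises(ValueError):
        relative_distance(-1.0, 5.0, 5.0)
    with pytest.raises(ValueError):
        relative_distance(10.0, 0.0, 5.0)


def _nucleus(nid, row, col, radius):
    return NucleusRecord(nucleus_id=nid, centroid_row=row, centroid_col=col,
                         area=math.pi * radius ** 2, equivalent_radius=radius)


def _assignment(cid, nuclei):
    return CellAssignment(
        cell_id=cid, nucleus_ids=tuple(n.nucleus_id for n in nuclei),
        cell_centroid_row=float(np.mean([n.centroid_row for n in nuclei])),
        cell_centroid_col=float(np.mean([n.centroid_col for n in nuclei])))


def test_pair_collection_counts():
    a, b = _nucleus(1, 10, 10, 3), _nucleus(2, 40, 40, 3)
    pairs = collect_calibration_pairs([a, b], [_assignment(1, [a]), _assignment(2, [b])])
    assert sum(1 for p in pairs if not p.same_cell) == 2
    assert sum(1 for p in pairs if p.same_cell) == 0

    # 1 binuclear + 1 mononuclear cell: 3 RDNDC samples, 2 RDNSC samples
    c = _nucleus(3, 14, 10, 3)
    pairs = collect_calibration_pairs(
        [a, b, c], [_assignment(1, [a, c]), _assignment(2, [b])])
    assert sum(1 for p in pairs if not p.same_cell) == 3
    assert sum(1 for p in pairs if p.same_cell) == 2


def test_pair_collection_requires_assignment():
    a = _nucleus(1, 10, 10, 3)
    with pytest.raises(ValueError, match="without a cell assignment"):
        collect_calibration_pairs([a], [])


def test_pair_collection_matches_bruteforce_oracle(rng):
    """Per-nucleus nearest-neighbour sampling agrees with an exhaustive
    O(n^2) pure-python enumeration on 200 random nuclei."""
    n = 200
    coords = rng.uniform(0, 1000, (n, 2))
    radii = rng.uniform(2, 8, n)
    cells = rng.integers(0, 60, n)
    nuclei = [_nucleus(i + 1, *coords[i], radii[i]) for i in range(n)]
    members = {}
    for i in range(n):
        members.setdefault(int(cells[i]), []).append(nuclei[i])
    assignments = [_assignment(cid + 1, ms) for cid, ms in members.items()]

    pairs = collect_calibration_pairs(nuclei, assignments)

    def oracle():
        out = []
        for i in range(n):
            best = {True: (None, np.inf), False: (None, np.inf)}
            for j in range(n):
                if i == j:
                    continue
                d = math.hypot(*(coords[i] - coords[j]))
                rel = d - radii[i] - radii[j]
                same = cells[i] == cells[j]
                if rel < best[same][1]:
                    best[same] = (j, rel)
            for same in (False, True):
                j, rel = best[same]
                if j is not None:
                    out.append((i + 1, j + 1, same))
        return sorted(out)

    got = sorted((p.nucleus_id_a, p.nucleus_id_b, p.same_cell) for p in pairs)
    assert got == oracle()


def _pair(rel, same):
    # encode a relative distance as a pair with unit radii
    return NucleusPair(0, 1, rel + 2.0, 1.0, 1.0, same_cell=same)


def test_select_threshold_separable():
    pairs = [_pair(r, True) for r in (1.0, 2.0, 3.0)] + \
            [_pair(r, False) for r in (8.0, 9.0, 12.0)]
    result = select_threshold(pairs)
    assert result.f1_at_threshold == 1.0
    assert result.auc == 1.0
    assert 3.0 < result.threshold_if < 8.0
    assert result.n_rdnsc == 3 and result.n_rdndc == 3


def test_select_threshold_single_class_errors():
    with pytest.raises(ValueError, match="RDNDC"):
        select_threshold([_pair(1.0, True)])
    with pytest.raises(ValueError, match="RDNSC"):
        select_threshold([_pair(1.0, False)])


def test_select_threshold_matches_grid_oracle(rng):
    """F1 at the selected threshold equals an exhaustive 0.01-px grid scan
    on 2000 noisy pairs."""
    rel_same = rng.normal(3.0, 2.0, 1000)
    rel_diff = rng.normal(12.0, 4.0, 1000)
    pairs = [_pair(r, True) for r in rel_same] + [_pair(r, False) for r in rel_diff]
    result = select_threshold(pairs)

    distances = np.array([p.relative_distance for p in pairs])
    labels = np.array([p.same_cell for p in pairs])
    def naive_f1(t):
        pred = distances < t
        tp = np.sum(pred & labels)
        fp = np.sum(pred & ~labels)
        fn = np.sum(~pred & labels)
        return 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0

    # exact: the reported F1 is the naive recount at the selected threshold,
    # and no other midpoint candidate beats it
    assert result.f1_at_threshold == pytest.approx(
        naive_f1(result.threshold_if), abs=1e-12)
    unique = np.unique(distances)
    candidates = np.concatenate(([unique[0] - 1], (unique[:-1] + unique[1:]) / 2,
                                 [unique[-1] + 1]))
    assert result.f1_at_threshold == pytest.approx(
        max(naive_f1(t) for t in candidates), abs=1e-12)
    # and it is at least as good as an exhaustive 0.01-px grid scan
    grid = np.arange(distances.min() - 1, distances.max() + 1, 0.01)
    assert result.f1_at_threshold >= max(naive_f1(t) for t in grid) - 1e-12


def test_auc_equals_mann_whitney(rng):
    rel_same = rng.normal(3.0, 2.5, 300)
    rel_diff = rng.normal(8.0, 3.0, 400)
    pairs = [_pair(r, True) for r in rel_same] + [_pair(r, False) for r in rel_diff]
    result = select_threshold(pairs)
    less = (rel_same[:, None] < rel_diff[None, :]).mean()
    ties = (rel_same[:, None] == rel_diff[None, :]).mean()
    assert result.auc == pytest.approx(less + 0.5 * ties, abs=1e-9)


def test_shuffled_labels_give_chance_auc(rng):
    distances = rng.normal(5.0, 2.0, 2000)
    labels = rng.random(2000) < 0.5
    pairs = [_pair(r, bool(s)) for r, s in zip(distances, labels)]
    result = select_threshold(pairs)
    assert result.auc == pytest.approx(0.5, abs=0.05)


def test_calibrator_estimator_interface(rng):
    X = np.concatenate([rng.normal(2, 1, 200), rng.normal(10, 1, 200)])
    y = np.concatenate([np.ones(200, bool), np.zeros(200, bool)])
    clf = ThresholdCalibrator().fit(X.reshape(-1, 1), y)
    assert clf.f1_ > 0.99
    pred = clf.predict(np.array([0.0, 20.0]))
    assert pred.tolist() == [True, False]
    # sklearn param plumbing
    assert ThresholdCalibrator().get_params() == {}


@given(st.floats(0.1, 50.0))
@settings(max_examples=30, deadline=None)
def test_select_threshold_shift_invariance(shift):
    """Adding a constant to all distances shifts the threshold by it."""
    base_same = [1.0, 2.0, 2.5]
    base_diff = [6.0, 7.5, 9.0]
    res0 = select_threshold([_pair(r, True) for r in base_same]
                            + [_pair(r, False) for r in base_diff])
    res1 = select_threshold([_pair(r + shift, True) for r in base_same]
                            + [_pair(r + shift, False) for r in base_diff])
    assert res1.threshold_if == pytest.approx(res0.threshold_if + shift, abs=1e-9)
    assert res1.f1_at_threshold == res0.f1_at_threshold


def test_convert_threshold():
    assert round(convert_threshold(5.5, ResolutionSpec(0.65, 0.23)), 2) == 15.54
    assert convert_threshold(3.0, ResolutionSpec(0.5, 0.5)) == pytest.approx(3.0)
    assert convert_threshold(1.0, ResolutionSpec(0.5, 0.25)) == pytest.approx(2.0)
    # linear in the threshold
    assert convert_threshold(11.0, ResolutionSpec(0.65, 0.23)) == pytest.approx(
        2 * convert_threshold(5.5, ResolutionSpec(0.65, 0.23)))
    with pytest.raises(ValueError):
        convert_threshold(5.5, ResolutionSpec(0.65, -1.0))
    with pytest.raises(ValueError):
        convert_threshold(-5.5, ResolutionSpec(0.65, 0.23))
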