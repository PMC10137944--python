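"""Two-stage mixture fitting and nuclear ploidy calling.

The in-package EM is cross-checked against scikit-learn's GaussianMixture
started from the identical initialisation, and the hard calls against a
brute-force per-component density evaluation.
"""

import math

import numpy as np
import pytest
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from hepaploidy import (AreaSimConfig, EMConvergenceError, NuclearPloidyGMM,
                        classify_nuclei, fit_gmm, simulate_areas,
                        summarize_total_ploidy, total_ploidy_distribution)
from hepaploidy.records import CellRecord, NuclearPloidyCall, NucleusRecord


def _mixture(rng, means=(200.0, 500.0, 900.0), sds=(20.0, 20.0, 20.0),
             sizes=(1500, 1000, 500)):
    return np.concatenate([rng.normal(m, s, n) for m, s, n in zip(means, sds, sizes)])


def test_initial_means_follow_the_ratio():
    rng = np.random.default_rng(0)
    model = fit_gmm(_mixture(rng))
    k = model.peak_k_
    np.testing.assert_allclose(
        k * 1.4 ** np.arange(3), (k, 1.4 * k, 1.96 * k), atol=1e-9)
    # concrete anchor: k = 170 seeds components at (170, 238, 333.2)
    np.testing.assert_allclose(170 * 1.4 ** np.arange(3), (170.0, 238.0, 333.2))


def test_parameter_recovery_well_separated(rng):
    areas = _mixture(rng)
    model = fit_gmm(areas)
    np.testing.assert_allclose(model.means_, (200, 500, 900), rtol=0.02)
    np.testing.assert_allclose(model.weights_, (0.5, 1 / 3, 1 / 6), atol=0.05)


def test_loglikelihood_trace_monotone(rng):
    model = fit_gmm(_mixture(rng))
    trace = np.array(model.log_likelihood_trace_)
    assert (np.diff(trace) >= -1e-9).all()
    assert model.n_iter_ <= 500


def test_validation_errors(rng):
    with pytest.raises(ValueError, match="at least 30"):
        fit_gmm(np.linspace(100, 200, 10))
    with pytest.raises(ValueError, match="positive"):
        fit_gmm(np.concatenate([np.linspace(100, 200, 40), [-5.0]]))
    with pytest.raises(EMConvergenceError) as err:
        fit_gmm(_mixture(rng), max_iter=2)
    assert len(err.value.trace) == 2


def test_agrees_with_sklearn_mixture(rng):
    """Independent oracle: sklearn EM from the identical initialisation
    converges to the same component parameters."""
    areas = _mixture(rng)
    model = fit_gmm(areas)
    k, v0 = areas.mean(), areas.var()
    sk = GaussianMixture(
        n_components=3, covariance_type="spherical", tol=1e-4, max_iter=500,
        weights_init=np.full(3, 1 / 3),
        means_init=(k * 1.4 ** np.arange(3)).reshape(-1, 1),
        precisions_init=np.full(3, 1 / v0),
    ).fit(areas.reshape(-1, 1))
    order = np.argsort(sk.means_[:, 0])
    np.testing.assert_allclose(model.means_, sk.means_[order, 0], rtol=1e-3)
    np.testing.assert_allclose(model.weights_, sk.weights_[order], atol=1e-3)
    np.testing.assert_allclose(model.variances_, sk.covariances_[order], rtol=5e-3)


def test_hard_calls_match_bruteforce_density(rng):
    model = fit_gmm(_mixture(rng))
    queries = rng.uniform(100, 1100, 100)
    predicted = model.predict(queries)
    for area, label in zip(queries, predicted):
        dens = [w * norm.pdf(area, m, math.sqrt(v))
                for w, m, v in zip(model.weights_, model.means_, model.variances_)]
        assert model.classes_[int(np.argmax(dens))] == label


def test_posteriors_normalised_and_dominant(rng):
    model = fit_gmm(_mixture(rng))
    post = model.predict_proba(rng.uniform(100, 1100, 200))
    np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)
    # an area at a well-separated component mean is called with certainty
    at_means = model.predict_proba(model.means_)
    assert (np.diag(at_means) > 0.99).all()


def test_scale_invariance_of_calls(rng):
    areas = _mixture(rng)
    model = fit_gmm(areas)
    scaled = fit_gmm(areas * 3.0)
    np.testing.assert_allclose(scaled.means_, model.means_ * 3.0, rtol=1e-6)
    np.testing.assert_allclose(scaled.variances_, model.variances_ * 9.0, rtol=1e-6)
    assert (scaled.predict(areas * 3.0) == model.predict(areas)).all()


def test_refit_recovery_from_fitted_family(rng):
    """Draws from the fitted-model family refit to within 5% means and 0.05
    weights at n = 5000."""
    model = fit_gmm(_mixture(rng))
    n = 5000
    comps = rng.choice(3, size=n, p=model.weights_)
    draws = rng.normal(model.means_[comps], np.sqrt(model.variances_[comps]))
    refit = fit_gmm(draws[draws > 0])
    np.testing.assert_allclose(refit.means_, model.means_, rtol=0.05)
    np.testing.assert_allclose(refit.weights_, model.weights_, atol=0.05)


def test_fit_on_simulated_areas():
    """Fitted on the censored sphere-slicing dataset, the mixture respects
    the EM fixed point (mixture mean equals the data mean), keeps three
    ordered non-degenerate components spanning the class structure, and its
    top component tracks the octoploid class mean.  The sliced-sphere class
    densities are not Gaussian, so the lower component means are pulled
    toward the censoring floor and need not coincide with the per-class
    empirical means."""
    samples = simulate_areas(AreaSimConfig(seed=1))
    kept = samples[~samples["censored"]]
    areas = kept["area"].to_numpy()
    model = fit_gmm(areas)
    assert model.weights_ @ model.means_ == pytest.approx(areas.mean(), rel=1e-6)
    assert (np.diff(model.means_) > 0).all()
    assert (model.weights_ > 0.05).all()
    empirical = kept.groupby("ploidy")["area"].mean()
    assert empirical["2n"] * 0.8 < model.means_[0] < empirical["4n"]
    assert model.means_[2] == pytest.approx(empirical["8n"], rel=0.05)


def test_equal_variance_boundaries_monotone(rng):
    model = fit_gmm(_mixture(rng))
    var = float(model.variances_.mean())
    model.variances_ = np.full(3, var)
    sorted_areas = np.sort(rng.uniform(100, 1100, 500))
    calls = model.predict(sorted_areas)
    ranks = [list(model.classes_).index(c) for c in calls]
    assert (np.diff(ranks) >= 0).all()


def test_json_roundtrip(tmp_path, rng):
    model = fit_gmm(_mixture(rng), training_resolution=0.23)
    path = tmp_path / "model.json"
    model.to_json(str(path))
    loaded = NuclearPloidyGMM.from_json(str(path))
    np.testing.assert_allclose(loaded.means_, model.means_)
    np.testing.assert_allclose(loaded.weights_, model.weights_)
    assert loaded.training_resolution == 0.23
    queries = rng.uniform(100, 1100, 50)
    assert (loaded.predict(queries) == model.predict(queries)).all()


def test_resolution_rescaling(rng):
    model = fit_gmm(_mixture(rng), training_resolution=0.23)
    area_at_046 = model.means_[1] / 4.0  # same physical size, half the resolution
    assert model.predict(np.array([area_at_046]), resolution=0.46)[0] == "4n"


def _cell(cid, nids):
    return CellRecord(cell_id=cid, nucleus_ids=tuple(nids),
                      cell_centroid_row=0.0, cell_centroid_col=0.0)


def _call(nid, ploidy):
    post = {"2n": (1.0, 0.0, 0.0), "4n": (0.0, 1.0, 0.0), "8n": (0.0, 0.0, 1.0)}
    return NuclearPloidyCall(nucleus_id=nid, area=100.0, ploidy=ploidy,
                             posterior=post[ploidy])


def test_total_ploidy_summation_and_categories():
    cells = [_cell(1, [1, 2]), _cell(2, [3]), _cell(3, [4, 5])]
    calls = [_call(1, "2n"), _call(2, "2n"), _call(3, "8n"),
             _call(4, "2n"), _call(5, "4n")]
    table = summarize_total_ploidy(cells, calls)
    assert table.loc[0, "total_ploidy"] == 4
    assert table.loc[0, "category"] == "binuclear-2x2n"
    assert table.loc[1, "total_ploidy"] == 8
    assert table.loc[1, "category"] == "mononuclear-8n"
    assert table.loc[2, "total_ploidy"] == 6
    assert table.loc[2, "category"] == "binuclear-2n+4n"
    dist = total_ploidy_distribution(table)
    assert dist["binuclear-2x2n"] == 1 and dist.sum() == 3


def test_total_ploidy_missing_call_errors():
    with pytest.raises(ValueError, match="missing ploidy call"):
        summarize_total_ploidy([_cell(1, [1, 2])], [_call(1, "2n")])


def test_classify_nuclei_records(rng):
    model = fit_gmm(_mixture(rng))
    nuclei = [NucleusRecord(nucleus_id=i + 1, centroid_row=0, centroid_col=0,
                            area=float(a))
              for i, a in enumerate(model.means_)]
    calls = classify_nuclei(model, nuclei)
    assert [c.ploidy for c in calls] == ["2n", "4n", "8n"]
    assert classify_nuclei(model, []) == []
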