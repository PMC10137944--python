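"""Two-stage Gaussian mixture model for nuclear ploidy.

Nuclear cross-section area carries the ploidy signal, but in normal liver
the pooled area histogram shows a single obvious peak, so a blind mixture
fit is fragile.  The two-stage procedure anchors the fit instead: a
one-component Gaussian locates the dominant peak ``k``, and a three-
component mixture is then initialised at means ``(k, 1.4 k, 1.4^2 k)`` with
uniform weights and the stage-one variance, so expectation-maximisation
starts from ploidy-plausible positions and the fit is fully deterministic.
Components sorted by ascending mean map to diploid (2n), tetraploid (4n)
and octoploid (8n).

The EM itself is one-dimensional with per-component variances, converges
when the mean log-likelihood improves by less than ``tol`` and keeps the
full iteration trace, which downstream checks use to assert monotonicity.
"""

from __future__ import annotations

import json
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .records import PLOIDY_LABELS, CellRecord, NuclearPloidyCall, NucleusRecord

PLOIDY_COPY_NUMBER = {"2n": 2, "4n": 4, "8n": 8}


class EMConvergenceError(RuntimeError):
    """EM failed to converge within the iteration cap; carries the trace."""

    def __init__(self, message: str, trace: Sequence[float]):
        super().__init__(message)
        self.trace = list(trace)


class NuclearPloidyGMM(ClassifierMixin, BaseEstimator):
    """Three-component 1-D Gaussian mixture classifier for nuclear areas.

    Parameters
    ----------
    mean_ratio : float, default 1.4
        Ratio between consecutive initial component means.
    tol : float, default 1e-4
        Convergence threshold on the improvement of the mean log-likelihood.
    max_iter : int, default 500
        EM iteration cap; exceeding it raises :class:`EMConvergenceError`.
    min_samples : int, default 30
        Minimum number of areas required to fit (three components need
        roughly ten observations each).
    training_resolution : float or None
        Micrometres per pixel of the training areas.  When set, areas
        supplied at a different resolution are rescaled by the squared
        resolution ratio before classification, so a frozen model is not
        bound to one scanner.

    Attributes (after ``fit``)
    --------------------------
    weights_, means_, variances_ : ndarray of shape (3,)
        Mixture parameters, components sorted by ascending mean.
    peak_k_ : float
        Stage-one peak location (mean of the single-component fit).
    log_likelihood_trace_ : list of float
        Mean log-likelihood per EM iteration (non-decreasing).
    n_iter_ : int
    classes_ : ndarray
        ``["2n", "4n", "8n"]`` by ascending component mean.
    """

    def __init__(self, mean_ratio: float = 1.4, tol: float = 1e-4,
                 max_iter: int = 500, min_samples: int = 30,
                 training_resolution: Optional[float] = None):
        self.mean_ratio = mean_ratio
        self.tol = tol
        self.max_iter = max_iter
        self.min_samples = min_samples
        self.training_resolution = training_resolution

    # ------------------------------------------------------------------
    def _validate_areas(self, X) -> np.ndarray:
        areas = np.asarray(X, dtype=np.float64)
        if areas.ndim == 2 and areas.shape[1] == 1:
            areas = areas[:, 0]
        if areas.ndim != 1:
            raise ValueError("areas must be a 1-D array or a column vector")
        if (areas <= 0).any():
            raise ValueError("all areas must be positive")
        return areas

    def fit(self, X, y=None):
        areas = self._validate_areas(X)
        if areas.size < self.min_samples:
            raise ValueError(
                f"need at least {self.min_samples} areas to fit, got {areas.size}")

        # stage 1: single Gaussian locates the dominant peak
        k = float(areas.mean())
        var0 = float(areas.var())
        if var0 <= 0:
            raise ValueError("areas are constant; cannot fit a mixture")

        means = k * self.mean_ratio ** np.arange(3, dtype=np.float64)
        weights = np.full(3, 1.0 / 3.0)
        variances = np.full(3, var0)
        var_floor = 1e-8 * var0

        trace: List[float] = []
        converged = False
        for _ in range(self.max_iter):
            log_joint = (np.log(weights)
                         + norm.logpdf(areas[:, None], means, np.sqrt(variances)))
            log_norm = logsumexp(log_joint, axis=1)
            trace.append(float(log_norm.mean()))
            if len(trace) > 1 and trace[-1] - trace[-2] < self.tol:
                converged = True
                break
            resp = np.exp(log_joint - log_norm[:, None])
            counts = resp.sum(axis=0)
            weights = counts / areas.size
            means = (resp * areas[:, None]).sum(axis=0) / counts
            variances = np.maximum(
                (resp * (areas[:, None] - means) ** 2).sum(axis=0) / counts,
                var_floor)
        if not converged:
            raise EMConvergenceError(
                f"EM did not converge within {self.max_iter} iterations", trace)

        order = np.argsort(means)
        self.weights_ = weights[order]
        self.means_ = means[order]
        self.variances_ = variances[order]
        self.peak_k_ = k
        self.log_likelihood_trace_ = trace
        self.n_iter_ = len(trace)
        self.classes_ = np.array(PLOIDY_LABELS)
        return self

    # ------------------------------------------------------------------
    def _to_training_scale(self, areas: np.ndarray,
                           resolution: Optional[float]) -> np.ndarray:
        if resolution is None or self.training_resolution is None:
            return areas
        # a physical area covers (res_new / res_train)^2 more training pixels
        return areas * (resolution / self.training_resolution) ** 2

    def predict_proba(self, X, resolution: Optional[float] = None) -> np.ndarray:
        check_is_fitted(self, "means_")
        areas = self._to_training_scale(self._validate_areas(X), resolution)
        log_joint = (np.log(self.weights_)
                     + norm.logpdf(areas[:, None], self.means_, np.sqrt(self.variances_)))
        return np.exp(log_joint - logsumexp(log_joint, axis=1)[:, None])

    def predict(self, X, resolution: Optional[float] = None) -> np.ndarray:
        posterior = self.predict_proba(X, resolution=resolution)
        return self.classes_[np.argmax(posterior, axis=1)]

    # ------------------------------------------------------------------
    def to_json(self, path: Optional[str] = None) -> str:
        check_is_fitted(self, "means_")
        payload = json.dumps({
            "weights": self.weights_.tolist(),
            "means": self.means_.tolist(),
            "variances": self.variances_.tolist(),
            "peak_k": self.peak_k_,
            "mean_ratio": self.mean_ratio,
            "training_resolution": self.training_resolution,
        }, indent=2)
        if path is not None:
            with open(path, "w") as handle:
                handle.write(payload)
        return payload

    @classmethod
    def from_json(cls, source: str) -> "NuclearPloidyGMM":
        """Load a frozen model from a JSON string or file path."""
        try:
            data = json.loads(source)
        except (json.JSONDecodeError, ValueError):
            with open(source) as handle:
                data = json.load(handle)
        model = cls(mean_ratio=data.get("mean_ratio", 1.4),
                    training_resolution=data.get("training_resolution"))
        model.weights_ = np.asarray(data["weights"], dtype=np.float64)
        model.means_ = np.asarray(data["means"], dtype=np.float64)
        model.variances_ = np.asarray(data["variances"], dtype=np.float64)
        model.peak_k_ = float(data["peak_k"])
        model.log_likelihood_trace_ = []
        model.n_iter_ = 0
        model.classes_ = np.array(PLOIDY_LABELS)
        return model


def fit_gmm(areas: Sequence[float], **kwargs) -> NuclearPloidyGMM:
    """Fit the two-stage mixture to nuclear areas (thin estimator wrapper)."""
    return NuclearPloidyGMM(**kwargs).fit(np.asarray(areas, dtype=np.float64))


def classify_nuclei(model: NuclearPloidyGMM, nuclei: Sequence[NucleusRecord],
                    resolution: Optional[float] = None) -> List[NuclearPloidyCall]:
    """Call nuclear ploidy for each nucleus by maximum posterior."""
    if not nuclei:
        return []
    areas = np.array([n.area for n in nuclei], dtype=np.float64)
    posterior = model.predict_proba(areas, resolution=resolution)
    labels = model.classes_[np.argmax(posterior, axis=1)]
    return [
        NuclearPloidyCall(
            nucleus_id=n.nucleus_id,
            area=float(n.area),
            ploidy=str(label),
            posterior=tuple(float(p) for p in probs),
        )
        for n, label, probs in zip(nuclei, labels, posterior)
    ]


def _category(ploidies: Sequence[str]) -> str:
    size = len(ploidies)
    prefix = {1: "mononuclear", 2: "binuclear"}.get(size, f"{size}-nuclear")
    counts: Dict[str, int] = {}
    for p in ploidies:
        counts[p] = counts.get(p, 0) + 1
    parts = []
    for label in PLOIDY_LABELS:
        if label in counts:
            c = counts[label]
            parts.append(f"{c}x{label}" if c > 1 else label)
    return f"{prefix}-{'+'.join(parts)}"


def summarize_total_ploidy(cells: Sequence[CellRecord],
                           calls: Sequence[NuclearPloidyCall]) -> pd.DataFrame:
    """Per-cell total ploidy: the sum of member nuclear ploidies.

    A binuclear cell of two diploid nuclei totals 4n (category
    ``binuclear-2x2n``); a mononuclear octoploid totals 8n.  Returns one row
    per cell with columns ``cell_id``, ``cellular_ploidy``,
    ``total_ploidy`` (copy number, e.g. 4) and ``category``.
    """
    call_of = {c.nucleus_id: c for c in calls}
    rows = []
    for cell in cells:
        missing = [nid for nid in cell.nucleus_ids if nid not in call_of]
        if missing:
            raise ValueError(f"cell {cell.cell_id}: missing ploidy call for "
                             f"nuclei {missing}")
        ploidies = [call_of[nid].ploidy for nid in cell.nucleus_ids]
        rows.append({
            "cell_id": cell.cell_id,
            "cellular_ploidy": cell.cellular_ploidy,
            "total_ploidy": sum(PLOIDY_COPY_NUMBER[p] for p in ploidies),
            "category": _category(ploidies),
        })
    return pd.DataFrame(rows, columns=["cell_id", "cellular_ploidy",
                                       "total_ploidy", "category"])


def total_ploidy_distribution(table: pd.DataFrame) -> pd.Series:
    """Cell counts per total-ploidy category, sorted by category name."""
    return table["category"].value_counts().sort_index()
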