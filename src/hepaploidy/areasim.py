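"""Stereological simulation of nuclear cross-section areas.

A histology section cuts each (approximately spherical) nucleus at a random
offset from its centre, so the observed 2-D area understates the true 3-D
size.  The simulation models each ploidy class as spheres whose radii are
normal — with the spread tied to the mean by the three-sigma rule
``3 * sigma = a * mu`` — sliced by planes at offsets uniform on ``[0, R]``:
a cut at offset ``h`` exposes a disc of area ``pi * (R^2 - h^2)``.  Slices
below a minimum detectable area are censored, mimicking nuclei too small to
segment.

Volume doubling per ploidy step implies a radius multiplier of ``2^(1/3)``
(about 1.26); because the pooled area histogram of normal human liver shows
a single obvious peak, the working multiplier is searched for as the largest
value at which the pooled simulated histogram becomes unimodal, which lands
near the reported 1.18.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .records import PLOIDY_LABELS

#: radius multiplier implied by exact volume doubling per ploidy step
THEORETICAL_MULTIPLIER = 2.0 ** (1.0 / 3.0)


@dataclass(frozen=True)
class AreaSimConfig:
    """Parameters of the sphere-slicing simulation.

    Defaults reproduce the normal-human-liver regime: diploid mean radius 9
    (units are pixels at the H&E scale; the model itself is unit-agnostic),
    shape factor 0.3 (so sigma = 0.3 * mu / 3), fitted multiplier 1.18,
    600/350/250 sphere radii per class with as many cuts per sphere, and a
    detection floor of 200 area units.
    """

    mu_diploid: float = 9.0
    shape_factor: float = 0.3
    multiplier: float = 1.18
    n_radii: Tuple[int, int, int] = (600, 350, 250)
    n_cuts_per_radius: Optional[Tuple[int, int, int]] = None
    min_area: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_diploid <= 0 or self.shape_factor <= 0:
            raise ValueError("mu_diploid and shape_factor must be positive")
        if not 1.0 < self.multiplier <= 1.3:
            raise ValueError("multiplier must lie in (1, 1.3]")
        if any(n <= 0 for n in self.n_radii):
            raise ValueError("n_radii must be positive")
        if self.min_area < 0:
            raise ValueError("min_area must be >= 0")
        if self.n_cuts_per_radius is not None and any(n <= 0 for n in self.n_cuts_per_radius):
            raise ValueError("n_cuts_per_radius must be positive")

    @property
    def cuts(self) -> Tuple[int, int, int]:
        return self.n_cuts_per_radius if self.n_cuts_per_radius is not None else self.n_radii


def class_means(config: AreaSimConfig) -> Tuple[float, float, float]:
    """Mean sphere radii (diploid, tetraploid, octoploid).

    Each ploidy step scales the mean radius by the multiplier:
    ``mu_tetra = m * mu_di`` and ``mu_octo = m * mu_tetra``.
    """
    mu = config.mu_diploid
    return (mu, config.multiplier * mu, config.multiplier ** 2 * mu)


def class_sigmas(config: AreaSimConfig) -> Tuple[float, float, float]:
    """Per-class radius standard deviations from the rule 3*sigma = a*mu."""
    return tuple(config.shape_factor * mu / 3.0 for mu in class_means(config))


def _simulate_class(rng: np.random.Generator, mu: float, sigma: float,
                    n_radii: int, n_cuts: int) -> Tuple[np.ndarray, np.ndarray]:
    """Radii (repeated per cut) and offsets for one ploidy class."""
    radii = rng.normal(mu, sigma, n_radii)
    # truncation to positive radii; at sigma/mu = 0.1 this is a ~1e-23 event
    while (bad := radii <= 0).any():
        radii[bad] = rng.normal(mu, sigma, int(bad.sum()))
    offsets = rng.uniform(0.0, 1.0, (n_radii, n_cuts)) * radii[:, None]
    return np.repeat(radii, n_cuts), offsets.ravel()


def simulate_areas(config: AreaSimConfig) -> pd.DataFrame:
    """Simulate cross-section areas for the three ploidy classes.

    Returns one row per cross-section with columns ``ploidy`` (2n/4n/8n),
    ``R`` (sphere radius), ``h`` (cut offset, uniform on [0, R]), ``area``
    (``pi * (R^2 - h^2)``) and ``censored`` (area below the detection
    floor).  With the default counts the classes contribute 360,000,
    122,500 and 62,500 cross-sections before censoring.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    for label, mu, sigma, n_r, n_c in zip(
            PLOIDY_LABELS, class_means(config), class_sigmas(config),
            config.n_radii, config.cuts):
        radii, offsets = _simulate_class(rng, mu, sigma, n_r, n_c)
        areas = np.pi * (radii ** 2 - offsets ** 2)
        frames.append(pd.DataFrame({
            "ploidy": label,
            "R": radii,
            "h": offsets,
            "area": areas,
            "censored": areas < config.min_area,
        }))
    return pd.concat(frames, ignore_index=True)


def censor(samples: pd.DataFrame, min_area: float,
           strategy: str = "drop-below",
           seed: Optional[int] = None) -> pd.DataFrame:
    """Apply the minimum-area detection floor.

    ``drop-below`` (default) deterministically removes every cross-section
    with area below ``min_area`` — the same rule applied proportionately in
    every class.  ``random-proportional`` instead removes, per class, the
    same *number* of samples chosen uniformly at random, for sensitivity
    checks of the censoring reading.
    """
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    if strategy == "drop-below":
        return samples.loc[samples["area"] >= min_area].reset_index(drop=True)
    if strategy == "random-proportional":
        rng = np.random.default_rng(seed)
        kept = []
        for label, group in samples.groupby("ploidy", sort=False):
            n_drop = int((group["area"] < min_area).sum())
            drop_idx = rng.choice(group.index.to_numpy(), size=n_drop, replace=False)
            kept.append(group.drop(index=drop_idx))
        return pd.concat(kept).sort_index().reset_index(drop=True)
    raise ValueError(f"unknown censoring strategy {strategy!r}")


def _pooled_areas(config: AreaSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Censored pooled areas without the DataFrame overhead (search helper)."""
    chunks = []
    for mu, sigma, n_r, n_c in zip(class_means(config), class_sigmas(config),
                                   config.n_radii, config.cuts):
        radii, offsets = _simulate_class(rng, mu, sigma, n_r, n_c)
        areas = np.pi * (radii ** 2 - offsets ** 2)
        chunks.append(areas[areas >= config.min_area])
    return np.concatenate(chunks)


def count_histogram_modes(areas: np.ndarray, bins: int = 256,
                          prominence_frac: float = 0.01) -> int:
    """Count modes of a smoothed area histogram.

    The histogram is smoothed with a Gaussian kernel whose bandwidth follows
    Silverman's rule, and local maxima with prominence above
    ``prominence_frac`` of the highest density count as modes.
    """
    areas = np.asarray(areas, dtype=np.float64)
    if areas.size == 0:
        return 0
    counts, edges = np.histogram(areas, bins=bins)
    width = edges[1] - edges[0]
    sd = areas.std()
    iqr = np.subtract(*np.percentile(areas, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    bandwidth = 0.9 * spread * areas.size ** (-1 / 5)
    density = gaussian_filter1d(counts.astype(np.float64),
                                max(bandwidth / width, 1e-9), mode="nearest")
    # padding lets boundary maxima (e.g. at the censoring floor) count as
    # peaks with their proper prominence
    padded = np.concatenate(([-1.0], density, [-1.0]))
    peaks, _ = find_peaks(padded, prominence=prominence_frac * density.max())
    return int(len(peaks))


def search_merge_multiplier(
    config: AreaSimConfig,
    candidates: Optional[Sequence[float]] = None,
    bins: int = 256,
    prominence_frac: float = 0.01,
) -> Tuple[Optional[float], pd.DataFrame]:
    """Search downward from the theoretical multiplier for histogram merging.

    For each candidate multiplier (default grid: 1.26 down to 1.10 in steps
    of 0.01) the three class histograms are simulated, pooled, censored and
    mode-counted; the result is the largest candidate whose pooled histogram
    is unimodal, with a per-candidate diagnostic table.  Returns
    ``(None, table)`` when no candidate merges.
    """
    if candidates is None:
        candidates = np.round(np.arange(1.26, 1.0999, -0.01), 2)
    candidates = sorted(candidates, reverse=True)
    # the printed-precision endpoint 1.26 is admitted alongside 2^(1/3)
    if any(not 1.0 < c <= round(THEORETICAL_MULTIPLIER, 2) for c in candidates):
        raise ValueError("candidates must lie in (1, 2^(1/3)]")
    rows = []
    best = None
    for candidate in candidates:
        rng = np.random.default_rng(config.seed)
        areas = _pooled_areas(replace(config, multiplier=float(candidate)), rng)
        modes = count_histogram_modes(areas, bins=bins, prominence_frac=prominence_frac)
        rows.append({"multiplier": float(candidate), "n_modes": modes})
        if modes == 1 and (best is None or candidate > best):
            best = float(candidate)
    return best, pd.DataFrame(rows)
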