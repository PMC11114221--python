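"""Sensor-characterization statistics.

Covers the quantitative side of receptor-array characterization:

* tryptophan fluorescence quenching normalization, ΔF/F₀ (%) =
  100 · (F₀ − F)/F₀, the binding readout of receptor-nanodisc assays;
* principal-component analysis of G_max response matrices (samples ×
  channels), used to visualize odorant discrimination;
* the 3σ/S limit of detection from a calibration curve (blank noise σ,
  sensitivity slope S);
* equimolar mixture combinatorics over the odorant panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .synth import CalibrationCurve

__all__ = [
    "QuenchMeasurement",
    "PcaResult",
    "quench_norm",
    "pca_responses",
    "detection_limit",
    "enumerate_mixtures",
]


@dataclass(frozen=True)
class QuenchMeasurement:
    """Fluorescence intensities of untreated (f0) and treated (f) nanodiscs.

    ``nd_concentration`` is the nanodisc level in nM and
    ``odorant_concentration`` the odorant level in molar units; both are
    metadata only.  f > f0 (anti-quenching) is allowed but unusual.
    """

    f0: float
    f: float
    nd_concentration: float = float("nan")
    odorant_concentration: float = float("nan")

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError(f"f0 must be positive, got {self.f0}")
        if self.f < 0:
            raise ValueError(f"f must be >= 0, got {self.f}")


def quench_norm(m: QuenchMeasurement) -> float:
    """Normalized fluorescence quenching ΔF/F₀ = 100 · (F₀ − F)/F₀ (%)."""
    return 100.0 * (m.f0 - m.f) / m.f0


@dataclass(frozen=True)
class PcaResult:
    """Loadings (columns = components), explained-variance fractions, scores."""

    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    scores: np.ndarray
    mean: np.ndarray

    def __post_init__(self) -> None:
        evr = np.asarray(self.explained_variance_ratio, dtype=float)
        if np.any(evr < -1e-12) or evr.sum() > 1 + 1e-9:
            raise ValueError("explained-variance fractions must be in [0, 1] and sum <= 1")


def pca_responses(matrix, standardize: bool = False) -> PcaResult:
    """PCA of a samples × channels G_max matrix.

    Columns are mean-centered (optionally scaled to unit variance when
    ``standardize``); components are the eigenvectors of the covariance
    matrix ordered by decreasing variance, with each loading's sign fixed
    so its largest-magnitude entry is positive.  Rank-deficient inputs
    yield trailing zero variances.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a matrix with >= 2 samples and >= 2 channels")
    mean = X.mean(axis=0)
    Xc = X - mean
    if standardize:
        sd = Xc.std(axis=0, ddof=1)
        Xc = Xc / np.where(sd > 0, sd, 1.0)
    cov = np.cov(Xc, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic orientation: largest-magnitude loading entry positive
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(evecs.shape[1])])
    flip[flip == 0] = 1.0
    evecs = evecs * flip
    total = evals.sum()
    ratio = evals / total if total > 0 else np.zeros_like(evals)
    return PcaResult(
        loadings=evecs,
        explained_variance_ratio=ratio,
        scores=Xc @ evecs,
        mean=mean,
    )


def detection_limit(curve: CalibrationCurve) -> float:
    """3σ/S limit of detection (ppm) of one calibration curve."""
    if curve.slope <= 0:
        raise ValueError(
            f"LOD undefined for non-positive slope ({curve.slope} μS/ppm) "
            f"on {curve.channel}/{curve.odorant}"
        )
    if curve.blank_sd < 0:
        raise ValueError("blank_sd must be >= 0")
    return 3.0 * curve.blank_sd / curve.slope


def enumerate_mixtures(odorants, k: int) -> list:
    """All unordered equimolar k-mixtures of the odorant panel.

    Each composition maps odorant → 1/k; ``k = 1`` returns the single
    odorants themselves.  The count is C(len(odorants), k).
    """
    odorants = list(odorants)
    if not (1 <= k <= len(odorants)):
        raise ValueError(f"k must be in [1, {len(odorants)}], got {k}")
    out = [{o: 1.0 / k for o in subset} for subset in combinations(odorants, k)]
    assert len(out) == comb(len(odorants), k)
    return out
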