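"""Size-distribution statistics and bimodal deconvolution.

A size distribution is a histogram of hydrodynamic diameters with percent
weights.  The dispersity statistic is the weighted variance of the
diameter over the squared weighted mean (a relative polydispersity, the
only dimensionally consistent reading of the source expression).  Bimodal
deconvolution fits a sum of two Gaussians to the histogram weights and
reports area fractions, labelling the smaller-mean component "monomer".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize


@dataclass
class SizeDistribution:
    diameters: np.ndarray  # nm, bin centers, strictly increasing
    weights: np.ndarray  # percent, sum to 100

    def __post_init__(self) -> None:
        self.diameters = np.asarray(self.diameters, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.diameters) != len(self.weights):
            raise ValueError("diameters and weights must have equal length")
        if not np.all(np.diff(self.diameters) > 0):
            raise ValueError("diameters must be strictly increasing")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        total = self.weights.sum()
        if not np.isclose(total, 100.0, atol=1e-6):
            raise ValueError(f"weights must sum to 100, got {total}")

    @property
    def mean_d(self) -> float:
        """Weighted mean diameter <D> = Σ D_i q_i / 100."""
        return float(np.sum(self.diameters * self.weights) / 100.0)

    @classmethod
    def from_csv(cls, path) -> "SizeDistribution":
        df = pd.read_csv(path)
        return cls(
            diameters=df["diameter_nm"].to_numpy(),
            weights=df["weight_percent"].to_numpy(),
        )

    @classmethod
    def from_weights(cls, diameters, weights) -> "SizeDistribution":
        """Build from arbitrary non-negative weights, renormalized to 100%."""
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        s = w.sum()
        if s <= 0:
            raise ValueError("weights sum to zero")
        return cls(diameters=np.asarray(diameters, float), weights=100.0 * w / s)


def dispersity(dist: SizeDistribution) -> float:
    """[Σ (D_i − <D>)² q_i / 100] / <D>² — dimensionless relative spread."""
    mean = dist.mean_d
    if mean == 0:
        raise ValueError("mean diameter is zero; dispersity undefined")
    var = float(np.sum((dist.diameters - mean) ** 2 * dist.weights) / 100.0)
    return var / mean**2


@dataclass
class BimodalFit:
    means: tuple[float, float]  # nm, (monomer, trimer) i.e. ascending
    sds: tuple[float, float]
    fractions: tuple[float, float]  # area fractions, sum to 1
    labels: tuple[str, str]
    rss: float
    converged: bool


def _two_gaussians(d, a1, mu1, s1, a2, mu2, s2):
    return a1 * np.exp(-0.5 * ((d - mu1) / s1) ** 2) + a2 * np.exp(
        -0.5 * ((d - mu2) / s2) ** 2
    )


def _default_init(dist: SizeDistribution) -> tuple[float, float]:
    """Means of the two highest well-separated local maxima (fallback: quartiles)."""
    w = dist.weights
    d = dist.diameters
    maxima = [
        i
        for i in range(1, len(w) - 1)
        if w[i] >= w[i - 1] and w[i] >= w[i + 1] and w[i] > 0
    ]
    maxima.sort(key=lambda i: -w[i])
    span = d[-1] - d[0]
    for i in maxima:
        for j in maxima:
            if abs(d[i] - d[j]) > 0.15 * span:
                return (min(d[i], d[j]), max(d[i], d[j]))
    mean = dist.mean_d
    return (0.75 * mean, 1.25 * mean)


def fit_bimodal(
    dist: SizeDistribution,
    init: list[tuple[float, float, float]] | None = None,
    seed: int = 0,
) -> BimodalFit:
    """Nonlinear least squares of the weights against two Gaussians.

    ``init`` may give two (mean, sd, fraction) guesses; otherwise the two
    strongest well-separated histogram maxima seed the fit.  Widths are
    kept positive by bounds; area fractions are normalized and the
    smaller-mean component is labelled "monomer".
    """
    if len(dist.diameters) < 8:
        raise ValueError("need at least 8 bins for a bimodal fit")
    d, w = dist.diameters, dist.weights
    span = d[-1] - d[0]
    if init is not None:
        (m1, s1, f1), (m2, s2, f2) = init
        total = w.sum()
        p0 = [f1 * total / (s1 * np.sqrt(2 * np.pi)) * (d[1] - d[0]), m1, s1,
              f2 * total / (s2 * np.sqrt(2 * np.pi)) * (d[1] - d[0]), m2, s2]
    else:
        mu1, mu2 = _default_init(dist)
        amp = w.max()
        p0 = [amp, mu1, span / 10.0, amp, mu2, span / 10.0]
    lower = [0.0, d[0] - span, 1e-6, 0.0, d[0] - span, 1e-6]
    upper = [np.inf, d[-1] + span, span, np.inf, d[-1] + span, span]
    try:
        popt, _ = optimize.curve_fit(
            _two_gaussians, d, w, p0=p0, bounds=(lower, upper), maxfev=20000
        )
        converged = True
    except RuntimeError:
        popt = np.asarray(p0, float)
        converged = False
    a1, mu1, s1, a2, mu2, s2 = popt
    area1, area2 = a1 * s1, a2 * s2  # ∝ Gaussian areas
    if mu1 > mu2:  # order ascending by mean
        (a1, mu1, s1, area1), (a2, mu2, s2, area2) = (
            (a2, mu2, s2, area2),
            (a1, mu1, s1, area1),
        )
    total_area = area1 + area2
    fr1 = float(area1 / total_area) if total_area > 0 else float("nan")
    rss = float(np.sum((_two_gaussians(d, *popt) - w) ** 2))
    return BimodalFit(
        means=(float(mu1), float(mu2)),
        sds=(float(s1), float(s2)),
        fractions=(fr1, 1.0 - fr1),
        labels=("monomer", "trimer"),
        rss=rss,
        converged=converged,
    )


def fit_single_gaussian_rss(dist: SizeDistribution) -> float:
    """RSS of the best single-Gaussian fit (nested-model reference)."""
    d, w = dist.diameters, dist.weights
    span = d[-1] - d[0]
    mean = dist.mean_d

    def one(dd, a, mu, s):
        return a * np.exp(-0.5 * ((dd - mu) / s) ** 2)

    popt, _ = optimize.curve_fit(
        one,
        d,
        w,
        p0=[w.max(), mean, span / 6.0],
        bounds=([0.0, d[0] - span, 1e-6], [np.inf, d[-1] + span, 2 * span]),
        maxfev=20000,
    )
    return float(np.sum((one(d, *popt) - w) ** 2))
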