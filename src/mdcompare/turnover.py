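"""Cycloheximide-chase protein-turnover quantification.

In a chase assay, protein synthesis is blocked and the band intensity of a
protein of interest is followed over time by immunoblot, normalized to a
loading control (e.g. alpha-tubulin) and to the t = 0 sample.  Assuming
first-order degradation the remaining fraction follows
``f(t) = exp(-k t)``, and the half-life is ``t_1/2 = ln 2 / k``.

The default estimator is through-origin linear regression of ``-ln f`` on
``t`` — the standard approach for chase series, which respects the exact
normalization ``f(0) = 1`` — with nonlinear least squares on the linear
scale available via ``method="nls"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import DataError, MDCompareError

__all__ = [
    "DecaySeries",
    "DecayFit",
    "normalize_series",
    "fit_decay",
    "chx_vehicle_ratio",
    "cross_probability",
]


@dataclass(frozen=True)
class DecaySeries:
    """Normalized chase time course: fraction remaining vs hours.

    Times are strictly increasing, starting at 0 where the fraction is 1 by
    normalization.  ``protein`` and ``genotype`` label the condition.
    """

    times: tuple[float, ...]
    fractions: tuple[float, ...]
    protein: str = ""
    genotype: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        if t.shape != f.shape or t.size < 2:
            raise DataError("need matching times/fractions with >= 2 points")
        if t[0] != 0.0:
            raise DataError("first time point must be 0 h")
        if np.any(np.diff(t) <= 0):
            raise DataError("times must be strictly increasing")
        if abs(f[0] - 1.0) > 1e-9:
            raise DataError("fraction at t=0 must be 1 after normalization")
        if np.any(f <= 0):
            raise DataError("fractions must be positive")


@dataclass(frozen=True)
class DecayFit:
    """Fitted first-order decay: rate (1/h), half-life (h), residuals."""

    rate_k: float
    half_life: float
    rss: float
    n_points: int
    method: str = "log-linear"

    @property
    def stable(self) -> bool:
        """True when no decay was detected (k <= 0, infinite half-life)."""
        return not (self.rate_k > 0)


def normalize_series(raw_band: Sequence[float], loading_band: Sequence[float],
                     times: Sequence[float], protein: str = "",
                     genotype: str = "") -> DecaySeries:
    """Loading-control and t=0 normalization of band intensities.

    ``fraction(t) = (raw(t)/loading(t)) / (raw(0)/loading(0))``.
    """
    raw = np.asarray(raw_band, dtype=float)
    loading = np.asarray(loading_band, dtype=float)
    t = np.asarray(times, dtype=float)
    if not (raw.shape == loading.shape == t.shape):
        raise DataError("raw, loading and times must have equal lengths")
    if np.any(loading <= 0):
        raise DataError("loading-control intensities must be positive")
    if np.any(raw <= 0):
        raise DataError("band intensities must be positive")
    if t[0] != 0.0:
        raise DataError("series must include a t=0 point first")
    ratio = raw / loading
    fractions = ratio / ratio[0]
    return DecaySeries(times=tuple(t), fractions=tuple(fractions),
                       protein=protein, genotype=genotype)


def fit_decay(series: DecaySeries, method: str = "log-linear") -> DecayFit:
    """Fit ``f(t) = exp(-k t)`` constrained through (0, 1).

    ``method="log-linear"`` (default): through-origin least squares of
    ``-ln f`` on ``t``, i.e. ``k = sum(t * (-ln f)) / sum(t^2)``.
    ``method="nls"``: nonlinear least squares on the linear scale, seeded
    from the log-linear estimate.  A non-positive fitted rate is reported
    with ``half_life = inf`` (flagged via :attr:`DecayFit.stable`).
    """
    t = np.asarray(series.times, dtype=float)
    f = np.asarray(series.fractions, dtype=float)
    nonzero = t > 0
    if nonzero.sum() < 2:
        raise DataError("need at least two non-zero time points")
    if method not in ("log-linear", "nls"):
        raise MDCompareError(f"unknown fit method {method!r}")

    y = -np.log(f[nonzero])
    tt = t[nonzero]
    k = float((tt * y).sum() / (tt * tt).sum())
    if method == "nls":
        popt, _ = curve_fit(lambda x, kk: np.exp(-kk * x), t, f,
                            p0=[max(k, 1e-6)], maxfev=10000)
        k = float(popt[0])
    rss = float(((np.exp(-k * t) - f) ** 2).sum())
    half_life = math.log(2.0) / k if k > 0 else math.inf
    return DecayFit(rate_k=k, half_life=half_life, rss=rss,
                    n_points=int(t.size), method=method)


def chx_vehicle_ratio(chx: Sequence[float], vehicle: Sequence[float],
                      loading_chx: Sequence[float],
                      loading_vehicle: Sequence[float]) -> np.ndarray:
    """Per-protein ratio of treated to vehicle signal, loading-normalized.

    ``ratio = (chx/loading_chx) / (vehicle/loading_vehicle)``; a value of
    0.4 reads as a 60% decrease under treatment.
    """
    arrays = [np.asarray(a, dtype=float)
              for a in (chx, vehicle, loading_chx, loading_vehicle)]
    if len({a.shape for a in arrays}) != 1:
        raise DataError("all intensity arrays must have equal lengths")
    chx_a, veh_a, lc, lv = arrays
    if np.any(lc <= 0) or np.any(lv <= 0):
        raise DataError("loading-control intensities must be positive")
    if np.any(veh_a <= 0):
        raise DataError("vehicle intensities must be positive")
    return (chx_a / lc) / (veh_a / lv)


def cross_probability(loci: Sequence[float]) -> float:
    """Expected offspring percentage from independent loci.

    Each entry is the transmission probability of the required allele at
    one locus (e.g. 1/2 for a heterozygous mutant allele, a floxed allele,
    or a Cre transgene); the result is the product times 100.  Three
    independent 1/2 loci give 12.5%.
    """
    probs = np.asarray(loci, dtype=float)
    if probs.size == 0:
        raise DataError("at least one locus is required")
    if np.any((probs < 0) | (probs > 1)):
        raise DataError("locus probabilities must lie in [0, 1]")
    return float(np.prod(probs) * 100.0)
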