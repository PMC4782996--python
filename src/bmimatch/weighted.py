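"""Survey-weighted building blocks.

Percentile ranks, quantiles, prevalence with confidence intervals,
Kish effective sample size, and weight-proportional sampling.  These are
the primitives the matching algorithm and the validation tests are built
from; every operation reduces exactly to its unweighted textbook form
when the weights are integer replication counts.

Conventions
-----------
* Percentile ranks use the midrank (mean-rank) convention:
  ``rank(x) = (W_below + 0.5 * W_at) / W_total``.  It is symmetric under
  reflection and stable at distribution tails.
* Quantiles are the left-continuous generalized inverse of the weighted
  CDF: the smallest sample value whose cumulative weight reaches ``p``.
* Prevalence at a cutoff is inclusive (``bmi >= cutoff`` counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "WeightedSample",
    "PrevalenceEstimate",
    "bmi",
    "weighted_percentile_rank",
    "weighted_quantile",
    "weighted_prevalence",
    "effective_n",
    "weighted_draw",
    "weighted_ecdf",
]


@dataclass(frozen=True)
class WeightedSample:
    """A sample of real values with positive sampling weights."""

    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if values.shape != weights.shape or values.ndim != 1:
            raise ValueError("values and weights must be 1-d arrays of equal length")
        if values.size == 0:
            raise ValueError("sample is empty")
        if not np.all(weights > 0):
            raise ValueError("all weights must be strictly positive")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "weights", weights)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    @property
    def n_eff(self) -> float:
        return effective_n(self.weights)


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Survey-weighted prevalence above a cutoff, with a confidence interval.

    ``n`` is the unweighted record count, ``n_eff`` the Kish effective
    sample size used for the variance approximation.
    """

    prevalence: float
    ci_low: float
    ci_high: float
    n: int
    n_eff: float
    cutoff: float
    se: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must lie in [0, 1]")
        if not (self.ci_low - 1e-12 <= self.prevalence <= self.ci_high + 1e-12):
            raise ValueError("prevalence must lie inside its confidence interval")


def bmi(height_cm, weight_kg):
    """Body-mass index in kg/m^2 from height in cm and weight in kg."""
    height_cm = np.asarray(height_cm, dtype=float)
    weight_kg = np.asarray(weight_kg, dtype=float)
    if np.any(height_cm <= 0) or np.any(weight_kg <= 0):
        raise ValueError("height and weight must be positive")
    out = weight_kg / (height_cm / 100.0) ** 2
    return float(out) if out.ndim == 0 else out


def _sorted_arrays(sample: WeightedSample):
    order = np.argsort(sample.values, kind="stable")
    v = sample.values[order]
    w = sample.weights[order]
    return v, w, np.cumsum(w)


def weighted_percentile_rank(sample: WeightedSample, x) -> float | np.ndarray:
    """Midrank percentile rank of ``x`` within a weighted sample.

    ``(W_below + 0.5 * W_at) / W_total`` where ``W_below`` is the total
    weight of values strictly below ``x`` and ``W_at`` the weight tied
    at ``x``.  Vectorized over ``x``.
    """
    v, _, cw = _sorted_arrays(sample)
    xs = np.asarray(x, dtype=float)
    left = np.searchsorted(v, xs, side="left")
    right = np.searchsorted(v, xs, side="right")
    w_below = np.where(left > 0, cw[np.maximum(left - 1, 0)], 0.0)
    w_through = np.where(right > 0, cw[np.maximum(right - 1, 0)], 0.0)
    ranks = (w_below + 0.5 * (w_through - w_below)) / cw[-1]
    return float(ranks) if ranks.ndim == 0 else ranks


def weighted_quantile(sample: WeightedSample, p) -> float | np.ndarray:
    """Left-continuous weighted quantile.

    Returns the smallest sample value whose cumulative weight fraction
    reaches ``p``; ties resolve to the smallest qualifying value.
    """
    ps = np.asarray(p, dtype=float)
    if np.any(ps < 0) or np.any(ps > 1):
        raise ValueError("p must lie in [0, 1]")
    v, _, cw = _sorted_arrays(sample)
    frac = cw / cw[-1]
    idx = np.searchsorted(frac, ps, side="left")
    out = v[np.minimum(idx, v.size - 1)]
    return float(out) if out.ndim == 0 else out


def effective_n(weights) -> float:
    """Kish effective sample size ``(sum w)^2 / sum(w^2)``."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("weights are empty")
    if not np.all(w > 0):
        raise ValueError("weights must be strictly positive")
    return float(w.sum() ** 2 / np.square(w).sum())


def _design_variance(indicator: np.ndarray, weights: np.ndarray,
                     strata: np.ndarray, psu: np.ndarray, p_hat: float) -> float:
    """Taylor-linearized variance of a weighted proportion under a
    stratified cluster design (with-replacement PSU approximation)."""
    resid = weights * (indicator - p_hat)
    total_w = weights.sum()
    var = 0.0
    for s in np.unique(strata):
        in_s = strata == s
        psus = np.unique(psu[in_s])
        n_psu = psus.size
        if n_psu < 2:
            continue
        z = np.array([resid[in_s & (psu == u)].sum() for u in psus])
        var += n_psu / (n_psu - 1) * np.sum((z - z.mean()) ** 2)
    return var / total_w**2


def weighted_prevalence(sample: WeightedSample, cutoff: float,
                        design: tuple[Sequence, Sequence] | None = None,
                        alpha: float = 0.05) -> PrevalenceEstimate:
    """Weighted prevalence of ``value >= cutoff`` with a normal-theory CI.

    With no design information the variance uses ``p(1-p)/n_eff`` with
    the Kish effective sample size; when ``design=(strata, psu)`` labels
    are supplied a Taylor-linearized stratified-cluster variance is used
    instead.  The boundary value ``value == cutoff`` counts as positive.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ind = (sample.values >= cutoff).astype(float)
    p_hat = float(np.sum(sample.weights * ind) / sample.total_weight)
    n_eff = sample.n_eff
    if design is not None:
        strata = np.asarray(design[0])
        psu = np.asarray(design[1])
        var = _design_variance(ind, sample.weights, strata, psu, p_hat)
    else:
        var = p_hat * (1.0 - p_hat) / n_eff
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return PrevalenceEstimate(
        prevalence=p_hat,
        ci_low=max(0.0, p_hat - z * se),
        ci_high=min(1.0, p_hat + z * se),
        n=len(sample),
        n_eff=n_eff,
        cutoff=float(cutoff),
        se=se,
    )


def weighted_draw(rng: np.random.Generator, weights, size=None):
    """Draw indices with probability proportional to ``weights``.

    Reproducible given the generator state; returns a scalar index when
    ``size`` is None.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("cannot draw from an empty pool")
    if not np.all(w > 0):
        raise ValueError("weights must be strictly positive")
    cw = np.cumsum(w)
    u = rng.random(size) * cw[-1]
    idx = np.searchsorted(cw, u, side="right")
    return int(idx) if size is None else idx


def weighted_ecdf(sample: WeightedSample):
    """Return ``(sorted unique values, right-continuous CDF at each)``."""
    v, w, _ = _sorted_arrays(sample)
    uniq, start = np.unique(v, return_index=True)
    cw = np.cumsum(w)
    # cumulative weight through the last occurrence of each unique value
    end = np.append(start[1:], v.size) - 1
    return uniq, cw[end] / cw[-1]
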