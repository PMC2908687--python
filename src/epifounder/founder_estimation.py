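"""Founder (trophoblast stem) cell number from epigenetic score variance.

A tissue founded by ``N`` progenitor cells, each of which independently
carries the scored epiallele state with probability ``p``, produces sample
scores distributed as ``k/N`` with ``k ~ Binomial(N, p)``.  The score
variance is then ``p(1-p)/N``: the fewer the founder cells, the larger the
variance.  Two estimators of ``N`` are provided:

* moment matching — ``N = p(1-p) / Var`` (continuous, unrounded), and
* explicit distribution fitting — the integer ``N`` whose binomial score
  distribution is closest to the empirical one, by binned chi-square or
  Kolmogorov–Smirnov distance.

``founder_report`` applies both to a ratio table (pooling placenta sections
across individuals within a group) and returns the per-group summary used
to compare conception groups.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .vocab import Group, PLACENTA_TISSUES, ScoreKind, Tissue, coerce

__all__ = [
    "DegenerateDistributionError",
    "FounderEstimate",
    "BinomialScoreDistribution",
    "sample_variance",
    "moment_n",
    "binomial_score_pmf",
    "fit_n_distribution",
    "founder_report",
    "founder_table",
]

logger = logging.getLogger(__name__)


class DegenerateDistributionError(ValueError):
    """Raised when a score distribution has no usable variance."""


@dataclass(frozen=True)
class FounderEstimate:
    """Per-group founder-cell estimate and its inputs.

    ``n_moment`` is the continuous moment-matched estimate p·q/Var;
    ``n_fit`` is the best-fitting integer founder count on the search grid.
    """

    p: float
    q: float
    n_samples: int
    sample_mean: float
    sample_variance: float
    n_moment: float
    n_fit: int
    fit_metric_name: str
    fit_metric_value: float

    def __post_init__(self) -> None:
        if not math.isclose(self.q, 1 - self.p, rel_tol=0, abs_tol=1e-12):
            raise ValueError("q must equal 1 - p")


@dataclass(frozen=True)
class BinomialScoreDistribution:
    """Distribution of scores k/n for k ~ Binomial(n, p)."""

    n: int
    p: float
    support: np.ndarray  # k/n for k = 0..n
    mass: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.dot(self.support, self.mass))

    @property
    def variance(self) -> float:
        m = self.mean
        return float(np.dot((self.support - m) ** 2, self.mass))


def sample_variance(values: Sequence[float], ddof: int = 1) -> float:
    """Variance of ``values`` with ``ddof`` delta degrees of freedom.

    Default ddof=1 (unbiased sample variance). Requires more than ``ddof``
    values and at least 2.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if arr.size < 2 or arr.size <= ddof:
        raise ValueError(f"need more than {max(ddof, 1)} values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    if np.ptp(arr) == 0:
        return 0.0  # exact zero for constant data (no roundoff residue)
    return float(np.var(arr, ddof=ddof))


def moment_n(p: float, variance: float) -> float:
    """Moment-matched founder number ``p(1-p)/variance``.

    Continuous and unrounded: the variance relation, not the integer grid,
    defines this estimator.
    """
    if not 0 < p < 1:
        raise ValueError(f"p must lie strictly in (0, 1), got {p}")
    if variance < 0 or not math.isfinite(variance):
        raise ValueError(f"variance must be finite and >= 0, got {variance}")
    if variance == 0:
        raise DegenerateDistributionError(
            "degenerate distribution; founder number unbounded"
        )
    return p * (1 - p) / variance


def binomial_score_pmf(n: int, p: float) -> BinomialScoreDistribution:
    """Probability mass of the score k/n, k ~ Binomial(n, p)."""
    if n < 1 or int(n) != n:
        raise ValueError(f"n must be a positive integer, got {n}")
    if not 0 < p < 1:
        raise ValueError(f"p must lie strictly in (0, 1), got {p}")
    n = int(n)
    k = np.arange(n + 1)
    return BinomialScoreDistribution(
        n=n, p=p, support=k / n, mass=stats.binom.pmf(k, n, p)
    )


def _binned_expected(dist: BinomialScoreDistribution, edges: np.ndarray,
                     noise_sd: float) -> np.ndarray:
    """Probability mass of the candidate score distribution per histogram bin.

    With measurement noise, each atom is spread by a normal kernel (mass
    clipped outside [0, 1] is assigned to the boundary bins, mirroring score
    truncation in the generator).
    """
    if noise_sd > 0:
        # mass in bin = sum over atoms of N(atom, sd) mass between edges,
        # with the outermost edges absorbing the truncated tails
        lo = stats.norm.cdf(edges[:-1, None], loc=dist.support[None, :], scale=noise_sd)
        hi = stats.norm.cdf(edges[1:, None], loc=dist.support[None, :], scale=noise_sd)
        hi[-1, :] = 1.0
        lo[0, :] = 0.0
        return (hi - lo) @ dist.mass
    idx = np.clip(np.searchsorted(edges, dist.support, side="right") - 1,
                  0, len(edges) - 2)
    out = np.zeros(len(edges) - 1)
    np.add.at(out, idx, dist.mass)
    return out


def fit_n_distribution(
    scores: Sequence[float],
    p: float,
    n_min: int = 1,
    n_max: int = 100,
    metric: str = "chi2_binned",
    bins: int = 10,
    noise_sd: float = 0.0,
) -> tuple[int, float]:
    """Best-fitting integer founder number by distribution comparison.

    Parameters
    ----------
    scores
        Observed scores; values outside [0, 1] are excluded with a warning
        (the binomial score model has no support there).
    p
        Per-founder-cell success probability (0.5 for X-inactivation, ~0.1
        for maternal IGF2/H19 DMR methylation).
    metric
        ``chi2_binned`` (default): chi-square distance between observed
        counts in ``bins`` equal-width bins over [0, 1] and the counts
        expected under each candidate N; candidates whose support puts zero
        mass where observations fall are rejected outright.
        ``ks``: Kolmogorov–Smirnov sup-distance between the empirical CDF
        and the candidate CDF.
    noise_sd
        Optional Gaussian measurement noise convolved into the candidate
        distributions (default 0: the pure clonal-sampling model).

    Returns
    -------
    (n_fit, metric_value); ties broken toward smaller N.  A zero-variance
    score list is degenerate: every larger N fits better, so ``n_max`` is
    returned with a NaN metric and a warning.
    """
    if metric not in ("chi2_binned", "ks"):
        raise ValueError(f"unknown metric {metric!r}")
    if n_min > n_max or n_min < 1:
        raise ValueError(f"invalid search grid [{n_min}, {n_max}]")
    arr = np.asarray(scores, dtype=float)
    if arr.size < 20:
        raise ValueError(f"need at least 20 scores to fit a distribution, got {arr.size}")
    inside = (arr >= 0) & (arr <= 1)
    if not inside.all():
        logger.warning(
            "excluding %d score(s) outside [0, 1] from distribution fitting",
            int((~inside).sum()),
        )
        arr = arr[inside]
        if arr.size < 20:
            raise ValueError("fewer than 20 scores remain inside [0, 1]")
    if np.ptp(arr) == 0:
        warnings.warn(
            "degenerate (zero-variance) score distribution; "
            "fit is unbounded above and pinned to n_max",
            stacklevel=2,
        )
        return int(n_max), float("nan")

    n_obs = arr.size
    best_n, best_d = None, None
    if metric == "chi2_binned":
        edges = np.linspace(0.0, 1.0, bins + 1)
        obs, _ = np.histogram(arr, bins=edges)
        for cand in range(n_min, n_max + 1):
            exp = _binned_expected(binomial_score_pmf(cand, p), edges, noise_sd) * n_obs
            support_ok = exp > 0
            if obs[~support_ok].sum() > 0:
                continue  # observed mass where this N allows none
            d = float(np.sum((obs[support_ok] - exp[support_ok]) ** 2 / exp[support_ok]))
            if best_d is None or d < best_d:
                best_n, best_d = cand, d
    else:  # ks
        sorted_scores = np.sort(arr)
        for cand in range(n_min, n_max + 1):
            dist = binomial_score_pmf(cand, p)
            cdf = np.cumsum(dist.mass)
            # sup|F_n - F| over jump points of EITHER step function,
            # comparing both right values and left limits
            points = np.union1d(dist.support, sorted_scores)
            model = cdf[np.clip(
                np.searchsorted(dist.support, points, side="right") - 1, 0, cand)]
            model_left = np.concatenate([[0.0], cdf])[np.clip(
                np.searchsorted(dist.support, points, side="left"), 0, cand + 1)]
            ecdf = np.searchsorted(sorted_scores, points, side="right") / n_obs
            ecdf_left = np.searchsorted(sorted_scores, points, side="left") / n_obs
            d = float(max(np.max(np.abs(model - ecdf)),
                          np.max(np.abs(model_left - ecdf_left))))
            if best_d is None or d < best_d:
                best_n, best_d = cand, d
    if best_n is None:
        raise ValueError(
            "no candidate N in the search grid is compatible with the scores"
        )
    return int(best_n), float(best_d)


def _filter_scores(
    ratios: pd.DataFrame,
    group: Group | str,
    tissues: Iterable[Tissue | str] | None,
    score_kind: ScoreKind | str | None,
) -> np.ndarray:
    group = coerce(Group, group)
    mask = ratios["group"] == group.value
    if tissues is not None:
        tset = {coerce(Tissue, t).value for t in tissues}
        mask &= ratios["tissue"].isin(tset)
    if score_kind is not None:
        mask &= ratios["score_kind"] == coerce(ScoreKind, score_kind).value
    return ratios.loc[mask, "value"].to_numpy(dtype=float)


def founder_report(
    ratios: pd.DataFrame,
    p: float | None,
    group: Group | str,
    tissues: Iterable[Tissue | str] | None = PLACENTA_TISSUES,
    score_kind: ScoreKind | str | None = None,
    ddof: int = 1,
    n_min: int = 1,
    n_max: int = 100,
    metric: str = "chi2_binned",
    noise_sd: float = 0.0,
) -> FounderEstimate:
    """Founder-cell estimate for one group from a ratio table.

    All matching records (by default: every placenta section of every
    individual in the group) are pooled as independent draws of the
    binomial score model.  When ``p`` is None, the pooled group mean is
    used — appropriate for the DMR-methylation flavor, where the group mean
    estimates the per-molecule methylation probability.
    """
    values = _filter_scores(ratios, group, tissues, score_kind)
    if values.size == 0:
        raise ValueError("no records match the requested group/tissue/score filters")
    if not np.all(np.isfinite(values)):
        raise ValueError("score values must be finite")
    mean = float(values.mean())
    if p is None:
        p = mean
    var = sample_variance(values, ddof=ddof)
    n_mom = moment_n(p, var)  # raises DegenerateDistributionError on var == 0
    n_fit, d = fit_n_distribution(
        values, p, n_min=n_min, n_max=n_max, metric=metric, noise_sd=noise_sd
    )
    return FounderEstimate(
        p=float(p),
        q=1 - float(p),
        n_samples=int(values.size),
        sample_mean=mean,
        sample_variance=var,
        n_moment=n_mom,
        n_fit=n_fit,
        fit_metric_name=metric,
        fit_metric_value=d,
    )


def founder_table(
    ratios: pd.DataFrame,
    assays: Sequence[tuple[ScoreKind | str, float | None]] = (
        (ScoreKind.XI, 0.5),
        (ScoreKind.MP, 0.1),
    ),
    tissues: Iterable[Tissue | str] | None = PLACENTA_TISSUES,
    **kwargs,
) -> pd.DataFrame:
    """Machine-readable founder-cell summary, one row per (assay, group).

    ``assays`` pairs each score flavor with its model probability ``p``
    (None = use the group mean).  Groups without matching records are
    skipped with a warning.
    """
    rows = []
    tissue_label = "placenta" if tissues is not None and set(
        coerce(Tissue, t) for t in tissues
    ) == set(PLACENTA_TISSUES) else "custom"
    for kind, p in assays:
        kind = coerce(ScoreKind, kind)
        for group in Group:
            try:
                est = founder_report(
                    ratios, p, group, tissues=tissues, score_kind=kind, **kwargs
                )
            except ValueError as exc:
                logger.warning("skipping %s/%s: %s", kind.value, group.value, exc)
                continue
            rows.append(
                {
                    "assay": kind.value,
                    "tissue": tissue_label,
                    "group": group.value,
                    "p": est.p,
                    "n_samples": est.n_samples,
                    "mean": est.sample_mean,
                    "variance": est.sample_variance,
                    "n_moment": est.n_moment,
                    "n_fit": est.n_fit,
                    "fit_metric": est.fit_metric_value,
                }
            )
    if not rows:
        raise ValueError("no founder estimates could be computed for any assay/group")
    return pd.DataFrame(rows)
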