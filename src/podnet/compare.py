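"""Comparing empirical and simulated motif rankings.

The comparison works on motif-class frequency rankings: Spearman's rank
correlation r_s = cov(rg_X, rg_Y) / (sigma_rgX sigma_rgY) with average
ranks for ties, the fraction of the reference's top-k classes present in
the model histogram, and an ordinary least-squares fit of rank on rank
(reporting R^2).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .motifs import MotifHistogram, rank


@dataclass
class RankingComparison:
    """Summary of one reference-vs-model ranking comparison."""

    r_s: float
    p_value: float
    top_k_overlap: float
    k: int
    slope: float
    intercept: float
    r_squared: float
    n_classes: int
    universe: str

    def to_dict(self) -> dict:
        return {
            "r_s": self.r_s,
            "p_value": self.p_value,
            "top_k_overlap": self.top_k_overlap,
            "k": self.k,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_classes": self.n_classes,
            "universe": self.universe,
        }


def average_ranks(values: np.ndarray) -> np.ndarray:
    """Descending average ranks: rank 1 = largest value, ties averaged."""
    return stats.rankdata(-np.asarray(values, dtype=float), method="average")


def spearman(rank_x, rank_y) -> tuple[float, float]:
    """Spearman's r_s from two rank vectors, with a large-sample p-value.

    r_s is the covariance of the rank variables over the product of their
    standard deviations.  The p-value uses the standard t approximation
    with n - 2 degrees of freedom.  Raises on zero variance.
    """
    x = np.asarray(rank_x, dtype=float)
    y = np.asarray(rank_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("rank vectors must be equal-length 1-D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 ranked classes")
    sx, sy = x.std(ddof=0), y.std(ddof=0)
    if sx == 0 or sy == 0:
        raise ValueError("rank vector has zero variance; r_s undefined")
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    r_s = float(cov / (sx * sy))
    if abs(r_s) >= 1.0:
        p = 0.0
    else:
        t = r_s * np.sqrt((n - 2) / (1.0 - r_s**2))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return r_s, p


def _frequency_vectors(
    reference: MotifHistogram, model: MotifHistogram, universe: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if reference.n_nodes != model.n_nodes:
        raise ValueError(
            f"group sizes differ: {reference.n_nodes} vs {model.n_nodes}"
        )
    if universe == "union":
        codes = sorted(set(reference.counts) | set(model.counts))
    elif universe == "reference":
        codes = sorted(reference.counts)
    else:
        raise ValueError("universe must be 'union' or 'reference'")
    ref = np.array([reference.counts.get(c, 0) for c in codes], dtype=float)
    mod = np.array([model.counts.get(c, 0) for c in codes], dtype=float)
    return ref, mod, codes


def spearman_histograms(
    reference: MotifHistogram, model: MotifHistogram, universe: str = "union"
) -> tuple[float, float]:
    """r_s between the motif rankings of two histograms.

    Classes absent from one histogram enter with count 0 and share the tied
    last average rank (``universe='union'``); ``universe='reference'``
    restricts to classes the reference contains.
    """
    ref, mod, _ = _frequency_vectors(reference, model, universe)
    return spearman(average_ranks(ref), average_ranks(mod))


def top_k_overlap(
    reference: MotifHistogram, model: MotifHistogram, k: int = 20
) -> float:
    """Fraction of the reference's k most common classes present in the model."""
    top = rank(reference, top_k=k)["canonical_code"]
    k_eff = len(top)
    present = sum(1 for code in top if model.counts.get(code, 0) > 0)
    return present / k_eff


def rank_scatter_fit(rank_x, rank_y) -> tuple[float, float, float]:
    """OLS fit of model rank on reference rank: (slope, intercept, R^2).

    R^2 is the squared Pearson correlation of the two rank vectors.  Raises
    on degenerate (zero-variance) input.
    """
    x = np.asarray(rank_x, dtype=float)
    y = np.asarray(rank_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1-D vectors of length >= 3")
    if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        raise ValueError("degenerate rank vector: variance is zero")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def compare_histograms(
    reference: MotifHistogram,
    model: MotifHistogram,
    k: int = 20,
    universe: str = "union",
) -> RankingComparison:
    """Full ranking comparison of a model histogram against a reference."""
    ref, mod, codes = _frequency_vectors(reference, model, universe)
    rx, ry = average_ranks(ref), average_ranks(mod)
    r_s, p = spearman(rx, ry)
    slope, intercept, r2 = rank_scatter_fit(rx, ry)
    return RankingComparison(
        r_s=r_s,
        p_value=p,
        top_k_overlap=top_k_overlap(reference, model, k=min(k, len(reference.counts))),
        k=min(k, len(reference.counts)),
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n_classes=len(codes),
        universe=universe,
    )
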