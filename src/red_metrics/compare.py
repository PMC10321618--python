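"""Priority rankings and rank-concordance statistics between two indices.

Two ranking conventions coexist on purpose. Presentation tables use
*dense* ranks: tied scores share a rank and the next distinct score takes
the next integer, so a top-20 list can hold more than 20 species. The
concordance statistics (Kendall's W for two judges, Spearman's rho) use
*midranks*, the standard tie treatment for rank correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "dense_rank",
    "kendall_w",
    "spearman_rho",
    "topk_overlap",
    "ComparisonResult",
    "compare_rankings",
]


def dense_rank(scores: pd.Series) -> pd.Series:
    """Dense descending ranks: best score -> 1, ties share a rank, no gaps."""
    if len(scores) == 0:
        raise ValueError("cannot rank an empty score table")
    if not np.isfinite(scores.to_numpy(dtype=float)).all():
        raise ValueError("scores must be finite")
    return scores.rank(method="dense", ascending=False).astype(int)


def _align(rank_a: pd.Series, rank_b: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    if set(rank_a.index) != set(rank_b.index):
        diff = sorted(set(rank_a.index) ^ set(rank_b.index))
        raise ValueError(f"species sets differ; symmetric difference: {diff}")
    b = rank_b.reindex(rank_a.index)
    return rank_a.to_numpy(dtype=float), b.to_numpy(dtype=float)


def _midranks(values: np.ndarray) -> np.ndarray:
    # ranks ascending in rank number == descending in score; midranks are
    # invariant to any strictly monotone rescoring, so accepting either raw
    # scores (negated) or rank tables gives identical statistics
    return stats.rankdata(values, method="average")


def kendall_w(rank_a: pd.Series, rank_b: pd.Series) -> float:
    """Kendall's coefficient of concordance for two judges, tie-corrected.

    ``W = 12 S / (m^2 (n^3 - n) - m * sum_j T_j)`` with m=2 judges,
    ``S`` the sum of squared deviations of per-species rank sums from
    their mean, and ``T_j = sum (t^3 - t)`` over tie groups of judge j.
    For two untied rankings, ``W = (1 + rho)/2``.
    """
    a, b = _align(rank_a, rank_b)
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 species for Kendall's W")
    ra, rb = _midranks(a), _midranks(b)
    m = 2
    rank_sums = ra + rb
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    ties = 0.0
    for r in (ra, rb):
        _, counts = np.unique(r, return_counts=True)
        ties += float((counts**3 - counts).sum())
    denom = m**2 * (n**3 - n) - m * ties
    if denom <= 0:
        raise ValueError("degenerate rankings: all species tied in both judges")
    return 12.0 * s / denom


def spearman_rho(rank_a: pd.Series, rank_b: pd.Series) -> tuple[float, float]:
    """Spearman rank correlation of two rankings, with two-sided p-value."""
    a, b = _align(rank_a, rank_b)
    if len(a) < 3:
        raise ValueError("need at least 3 species for Spearman's rho")
    if len(np.unique(a)) == 1 or len(np.unique(b)) == 1:
        raise ValueError("zero rank variance: correlation undefined")
    res = stats.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)


def topk_overlap(
    rank_a: pd.Series, rank_b: pd.Series, k: int = 20
) -> tuple[int, float]:
    """Number and percentage (of k) of species in both top-k lists.

    Inputs are dense rank tables (or any score-derived ranks where 1 is
    best); species tied at the rank-k boundary are all included, so a list
    may exceed k species. Only species present in both tables are
    considered; the percentage is relative to k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    common = rank_a.index.intersection(rank_b.index)
    top_a = set(common[rank_a.loc[common] <= k])
    top_b = set(common[rank_b.loc[common] <= k])
    shared = len(top_a & top_b)
    return shared, 100.0 * shared / k


@dataclass(frozen=True)
class ComparisonResult:
    """Concordance summary between two priority rankings."""

    w: float
    rho: float
    p_value: float
    n: int
    k: int
    topk_shared: int
    topk_pct: float

    def to_dict(self) -> dict:
        return asdict(self)


def compare_rankings(
    scores_a: pd.Series, scores_b: pd.Series, k: int = 20
) -> ComparisonResult:
    """Full comparison of two score tables over their common species.

    Scores are converted to ranks internally (midranks for W/rho, dense
    ranks for the top-k overlap). Species missing from either table are
    dropped before comparison.
    """
    common = scores_a.index.intersection(scores_b.index)
    a, b = scores_a.loc[common], scores_b.loc[common]
    w = kendall_w(dense_rank(a), dense_rank(b))
    rho, p = spearman_rho(dense_rank(a), dense_rank(b))
    shared, pct = topk_overlap(dense_rank(a), dense_rank(b), k=k)
    return ComparisonResult(
        w=w, rho=rho, p_value=p, n=len(common), k=k, topk_shared=shared, topk_pct=pct
    )
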