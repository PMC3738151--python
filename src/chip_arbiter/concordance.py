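"""Replicate concordance, dynamic range and disputed-vs-random rank tests.

Reproducibility between replicate z-tracks is summarised by the Spearman
rank correlation; dynamic range by the fraction of probes with z strictly
below a threshold.  Whether disputed-target peak probes score higher than
chance on another study's track is assessed with a one-sided Mann–Whitney
U test against z-scores of randomly sampled probes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy import stats

from .io import CoordinateTable
from .null_model import ZTrack
from .targets import nearest_probe

__all__ = [
    "ConcordanceReport",
    "MWUResult",
    "spearman",
    "dynamic_range_summary",
    "mwu_test",
    "dst_vs_random_test",
    "replicate_concordance",
]

EXACT_ENUMERATION_MAX_N = 14  # C(14,7)=3432 labelings, instant


@dataclass(frozen=True)
class ConcordanceReport:
    spearman_rho: float
    n_probes: int
    frac_below_threshold: float
    threshold: float


@dataclass(frozen=True)
class MWUResult:
    """Mann–Whitney result; U is the rank-sum statistic for sample A."""

    U: float
    n_a: int
    n_b: int
    p_value: float
    method: str               # "exact" or "normal_approximation"
    alternative: str
    seed: int | None = None


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks on ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no rank correlation")
    return float(stats.spearmanr(x, y).statistic)


def dynamic_range_summary(z: ZTrack, threshold: float = 3.0) -> float:
    """Fraction of probes with z strictly below ``threshold``."""
    return float(np.mean(z.zscores < threshold))


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mwu_test(a, b, alternative: str = "greater", method: str = "auto") -> MWUResult:
    """Mann–Whitney U test of sample A against sample B.

    For tie-free data with n_a + n_b <= 14 the p-value is exact, by
    enumeration of all C(n_a+n_b, n_a) rank labelings.  Otherwise the
    normal approximation with midranks, tie correction and a 0.5 continuity
    correction is used.  ``method`` forces one branch ("exact" or
    "normal_approximation") regardless of sample size.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if method not in ("auto", "exact", "normal_approximation"):
        raise ValueError(f"unknown method {method!r}")
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    u_obs = _u_statistic(ranks[:n_a], n_a)
    has_ties = len(np.unique(pooled)) < n

    use_exact = method == "exact" or (method == "auto" and n <= EXACT_ENUMERATION_MAX_N
                                      and not has_ties)
    if method == "exact" and has_ties:
        raise ValueError("exact enumeration requires tie-free data")
    if use_exact:
        all_ranks = np.arange(1, n + 1)
        us = np.array([
            sum(c) - n_a * (n_a + 1) / 2.0 for c in combinations(all_ranks, n_a)
        ])
        total = comb(n, n_a)
        p_ge = np.count_nonzero(us >= u_obs) / total
        p_le = np.count_nonzero(us <= u_obs) / total
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return MWUResult(U=u_obs, n_a=n_a, n_b=n_b, p_value=float(p),
                         method="exact", alternative=alternative)

    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        # all observations identical: no evidence either way
        return MWUResult(U=u_obs, n_a=n_a, n_b=n_b, p_value=1.0,
                         method="normal_approximation", alternative=alternative)
    sd = sqrt(var)
    if alternative == "greater":
        p = float(stats.norm.sf((u_obs - mu - 0.5) / sd))
    elif alternative == "less":
        p = float(stats.norm.sf((mu - u_obs - 0.5) / sd))
    else:
        p = min(1.0, 2.0 * float(stats.norm.sf((abs(u_obs - mu) - 0.5) / sd)))
    return MWUResult(U=u_obs, n_a=n_a, n_b=n_b, p_value=p,
                     method="normal_approximation", alternative=alternative)


def dst_vs_random_test(
    z: ZTrack,
    dst_positions: CoordinateTable,
    n_random: int = 1000,
    seed: int = 0,
) -> MWUResult:
    """Test whether disputed-target peak z-scores exceed random probes'.

    Sample A is the z-score at the nearest probe to each disputed-target
    coordinate (probe grids differ between studies); sample B is the
    z-scores of ``n_random`` probes drawn uniformly without replacement.
    One draw, seeded, one-sided alternative "A greater".
    """
    if len(dst_positions) == 0:
        raise ValueError("dst_positions is empty")
    if n_random >= len(z):
        raise ValueError(f"n_random={n_random} must be below the probe count {len(z)}")
    a = np.array([nearest_probe(z, int(p))[1] for p in dst_positions.positions])
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(z), size=n_random, replace=False)
    b = z.zscores[idx]
    res = mwu_test(a, b, alternative="greater")
    return MWUResult(U=res.U, n_a=res.n_a, n_b=res.n_b, p_value=res.p_value,
                     method=res.method, alternative=res.alternative, seed=int(seed))


def replicate_concordance(z1: ZTrack, z2: ZTrack, threshold: float = 3.0) -> ConcordanceReport:
    """Spearman concordance of two replicate z-tracks on one probe grid.

    The fraction-below-threshold summary is computed on ``z1``.  The two
    tracks must share their probe grid exactly; intersect by position first
    if they do not.
    """
    if len(z1) != len(z2) or np.any(z1.track.starts != z2.track.starts) or np.any(
        z1.track.ends != z2.track.ends
    ):
        raise ValueError(
            "replicate probe grids differ; intersect the tracks by position "
            "before computing concordance"
        )
    rho = spearman(z1.zscores, z2.zscores)
    return ConcordanceReport(
        spearman_rho=rho,
        n_probes=len(z1),
        frac_below_threshold=dynamic_range_summary(z1, threshold),
        threshold=float(threshold),
    )
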