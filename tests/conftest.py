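"""Shared fixtures and independent oracles used across the test suite.

The oracle functions here deliberately use the dumbest possible algorithm
(per-base counting, exhaustive enumeration, exact rational arithmetic) so
they stay independent of the library code paths they check.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import chip_arbiter as ca

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# builders

def make_ztrack(zvals, spacing=100, probe_length=50, start=0, label="test",
                sequence_id="chr") -> ca.ZTrack:
    """Build a ZTrack directly from z-scores on a regular grid."""
    z = np.asarray(zvals, dtype=float)
    starts = start + spacing * np.arange(len(z))
    track = ca.ProbeTrack(sequence_id=sequence_id, starts=starts,
                          ends=starts + probe_length, values=z.copy(), label=label)
    fit = ca.NullFit(mode=0.0, sigma=1.0, n_below=len(z), n_total=len(z))
    return ca.ZTrack(track=track, zscores=z, fit=fit)


def make_annotation(genes, genome_length) -> ca.GeneAnnotation:
    """genes: iterable of (start, end, strand) or (start, end, strand, name)."""
    rows = []
    for i, g in enumerate(genes):
        start, end, strand = g[:3]
        name = g[3] if len(g) > 3 else f"g{i + 1}"
        rows.append({"sequence_id": "chr", "start": start, "end": end,
                     "strand": strand, "name": name})
    df = pd.DataFrame(rows, columns=["sequence_id", "start", "end", "strand", "name"])
    return ca.GeneAnnotation(genes=df, genome_length=genome_length)


@pytest.fixture
def small_annotation():
    return make_annotation([(100, 500, "+"), (800, 1200, "-"), (1500, 1900, "+")], 2500)


@pytest.fixture(scope="session")
def default_simulation():
    """One default simulation shared by read-only tests."""
    cfg = ca.SimulationConfig(seed=17)
    return cfg, *ca.simulate_all(cfg)


# ---------------------------------------------------------------------------
# oracles

def oracle_call_targets(track: ca.ProbeTrack, z: np.ndarray, threshold: float,
                        merge_distance: int):
    """Brute-force region grouping: list qualifying probes, split on midpoint
    gaps > merge_distance, report each group's argmax (leftmost on ties)."""
    mids = track.midpoints
    qual = [i for i in range(len(z)) if z[i] >= threshold]
    groups = []
    for i in qual:
        if groups and mids[i] - mids[groups[-1][-1]] <= merge_distance:
            groups[-1].append(i)
        else:
            groups.append([i])
    out = []
    for grp in groups:
        peak = grp[0]
        for i in grp[1:]:
            if z[i] > z[peak]:
                peak = i
        out.append((int(mids[peak]), float(z[peak]), int(track.starts[grp[0]]),
                    int(track.ends[grp[-1]])))
    return out


def oracle_genic_fraction(genes, genome_length) -> float:
    """Per-base-pair covered/total counting."""
    covered = np.zeros(genome_length, dtype=bool)
    for start, end in genes:
        covered[start:end] = True
    return covered.sum() / genome_length


def oracle_binomial_upper_tail(k: int, n: int, p0: float) -> Fraction:
    """Exact rational P(X >= k) for X ~ Binomial(n, p0)."""
    p = Fraction(p0)
    return sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


def oracle_mwu_exact(a, b, alternative="greater") -> float:
    """Exhaustive labeling enumeration of the rank-sum null (tie-free data)."""
    a, b = list(a), list(b)
    n_a, n = len(a), len(a) + len(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == n, "oracle requires tie-free data"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank[v] for v in a) - n_a * (n_a + 1) / 2
    total = comb(n, n_a)
    ge = le = 0
    for c in combinations(range(1, n + 1), n_a):
        u = sum(c) - n_a * (n_a + 1) / 2
        ge += u >= u_obs
        le += u <= u_obs
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2.0 * min(ge, le) / total)


def oracle_spearman_closed_form(x, y) -> float:
    """1 - 6*sum(d^2)/(n(n^2-1)) on tie-free data."""
    x, y = list(x), list(y)
    n = len(x)
    rx = {v: i + 1 for i, v in enumerate(sorted(x))}
    ry = {v: i + 1 for i, v in enumerate(sorted(y))}
    d2 = sum((rx[a] - ry[b]) ** 2 for a, b in zip(x, y))
    return 1 - 6 * d2 / (n * (n**2 - 1))
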