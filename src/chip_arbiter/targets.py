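"""Target calling, cross-study arbitration and genomic-context analysis.

A target region is a run of above-threshold probes; only the maximum-z
("peak") probe represents the region, suppressing adjacent high-scoring
probes.  Targets called on two studies with different probe grids are
matched peak-to-peak within a bp tolerance; targets of study A with no
study-B match are "disputed".  Peak positions are classified as genic,
intergenic, or intergenic between convergently transcribed genes, and the
intergenic count is tested against the genome's genic fraction with an
exact one-sided binomial test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .io import GeneAnnotation, CoordinateTable, ProbeTrack, ValidationError
from .null_model import ZTrack

logger = logging.getLogger("chip_arbiter")

__all__ = [
    "TargetRegion",
    "StudyComparison",
    "BinomialResult",
    "call_targets",
    "nearest_probe",
    "compare_studies",
    "classify_position",
    "genic_fraction",
    "positional_enrichment_test",
    "rank_analysis",
    "targets_to_frame",
    "frame_to_targets",
]

GENIC = "genic"
INTERGENIC = "intergenic"
INTERGENIC_CONVERGENT = "intergenic_convergent"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class TargetRegion:
    """A called binding region represented by its peak probe."""

    sequence_id: str
    peak_position: int          # midpoint of the peak probe, bp
    peak_z: float               # maximum z within the region
    region_start: int           # start of first above-threshold probe
    region_end: int             # end of last above-threshold probe
    context: str = UNCLASSIFIED
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.region_start <= self.peak_position < self.region_end):
            raise ValidationError(
                f"target {self.name!r}: peak {self.peak_position} outside "
                f"[{self.region_start}, {self.region_end})"
            )


@dataclass(frozen=True)
class StudyComparison:
    """Arbitration of study-A targets against study-B targets.

    ``matched``, ``disputed`` and ``excluded`` partition the A targets:
    matched holds (target_a, target_b, peak distance) triples within
    ``tolerance`` bp; disputed holds A targets with no B peak in range;
    excluded holds A targets removed by name before analysis (e.g. targets
    in repetitive sequence).
    """

    matched: list
    disputed: list
    excluded: list
    tolerance: int

    @property
    def disputed_names(self) -> set:
        return {t.name for t in self.disputed}


@dataclass(frozen=True)
class BinomialResult:
    """One-sided (upper-tail) exact binomial test result."""

    k: int
    n: int
    p0: float
    p_value: float
    alternative: str = "greater"

    @property
    def expected(self) -> float:
        return self.n * self.p0


def call_targets(z: ZTrack, threshold: float = 3.0, merge_distance: int = 500) -> list[TargetRegion]:
    """Group above-threshold probes into target regions, one peak per region.

    Successive probes with z >= ``threshold`` whose midpoints lie within
    ``merge_distance`` bp belong to one region; each region's single target
    is its maximum-z probe (leftmost wins exact ties).  Regions are returned
    in genomic order and named ``<label>_t<k>`` (1-based).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if merge_distance < 0:
        raise ValueError("merge_distance must be >= 0")
    track = z.track
    idx = np.flatnonzero(z.zscores >= threshold)
    mids = track.midpoints
    groups: list[list[int]] = []
    for i in idx:
        if groups and mids[i] - mids[groups[-1][-1]] <= merge_distance:
            groups[-1].append(int(i))
        else:
            groups.append([int(i)])
    targets = []
    for k, grp in enumerate(groups, start=1):
        zs = z.zscores[grp]
        peak = grp[int(np.argmax(zs))]  # argmax -> first max -> leftmost probe
        targets.append(
            TargetRegion(
                sequence_id=track.sequence_id,
                peak_position=int(mids[peak]),
                peak_z=float(z.zscores[peak]),
                region_start=int(track.starts[grp[0]]),
                region_end=int(track.ends[grp[-1]]),
                name=f"{track.label or 'track'}_t{k}",
            )
        )
    return targets


def nearest_probe(z: ZTrack | ProbeTrack, position: int) -> tuple[int, float, int]:
    """Return (index, z or value, |midpoint - position|) of the nearest probe.

    The probe whose midpoint minimises the distance to ``position`` is
    chosen; on an exact tie the leftmost probe wins.  Different studies use
    different probe grids, so mapping a coordinate from one study onto
    another's track goes through this lookup.
    """
    track = z.track if isinstance(z, ZTrack) else z
    values = z.zscores if isinstance(z, ZTrack) else track.values
    mids = track.midpoints
    j = int(np.searchsorted(mids, position))
    candidates = [i for i in (j - 1, j) if 0 <= i < len(mids)]
    # leftmost on tie: strict improvement required to move right
    best = candidates[0]
    for i in candidates[1:]:
        if abs(int(mids[i]) - position) < abs(int(mids[best]) - position):
            best = i
    return best, float(values[best]), abs(int(mids[best]) - position)


def compare_studies(
    targets_a: list[TargetRegion],
    targets_b: list[TargetRegion],
    tolerance: int = 500,
    exclude: tuple = (),
) -> StudyComparison:
    """Match study-A targets to the nearest study-B target within tolerance.

    Every non-excluded A target is either matched (nearest B peak within
    ``tolerance`` bp; a B target may serve several A targets) or disputed.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    names_a = [t.name for t in targets_a]
    if len(set(names_a)) != len(names_a):
        raise ValidationError("duplicate target names in study A")
    names_b = [t.name for t in targets_b]
    if len(set(names_b)) != len(names_b):
        raise ValidationError("duplicate target names in study B")
    exclude = set(exclude)
    b_peaks = np.array(sorted(t.peak_position for t in targets_b), dtype=np.int64)
    b_by_peak = sorted(targets_b, key=lambda t: t.peak_position)
    matched, disputed, excluded = [], [], []
    for t in targets_a:
        if t.name in exclude:
            excluded.append(t)
            continue
        if len(b_peaks) == 0:
            disputed.append(t)
            continue
        j = int(np.searchsorted(b_peaks, t.peak_position))
        best, best_d = None, None
        for i in (j - 1, j):
            if 0 <= i < len(b_peaks):
                d = abs(int(b_peaks[i]) - t.peak_position)
                if best is None or d < best_d:
                    best, best_d = b_by_peak[i], d
        if best_d is not None and best_d <= tolerance:
            matched.append((t, best, int(best_d)))
        else:
            disputed.append(t)
    return StudyComparison(matched=matched, disputed=disputed, excluded=excluded,
                           tolerance=int(tolerance))


def classify_position(ann: GeneAnnotation, position: int) -> str:
    """Classify a bp position as genic / intergenic / intergenic_convergent.

    A position inside any gene interval is genic (strand ignored).  An
    intergenic position is additionally "convergent" when its left flanking
    gene is on the + strand and its right flanking gene on the - strand,
    i.e. both 3' ends face the gap.  Gaps at the sequence ends are plain
    intergenic.
    """
    if not (0 <= position < ann.genome_length):
        raise ValidationError(f"position {position} outside [0, {ann.genome_length})")
    genes = ann.genes
    if len(genes) == 0:
        return INTERGENIC
    starts = genes["start"].to_numpy()
    ends = genes["end"].to_numpy()
    inside = (starts <= position) & (position < ends)
    if inside.any():
        return GENIC
    left = np.flatnonzero(ends <= position)
    right = np.flatnonzero(starts > position)
    if len(left) == 0 or len(right) == 0:
        return INTERGENIC
    left_gene = genes.iloc[left[np.argmax(ends[left])]]
    right_gene = genes.iloc[right[np.argmin(starts[right])]]
    if left_gene["strand"] == "+" and right_gene["strand"] == "-":
        return INTERGENIC_CONVERGENT
    return INTERGENIC


def genic_fraction(ann: GeneAnnotation) -> float:
    """Fraction of the genome covered by the strand-ignored union of genes."""
    if ann.genome_length <= 0:
        raise ValidationError("genome_length must be positive")
    if len(ann) == 0:
        return 0.0
    ivs = ann.genes[["start", "end"]].to_numpy()
    ivs = ivs[np.argsort(ivs[:, 0], kind="stable")]
    total = 0
    cur_s, cur_e = int(ivs[0, 0]), int(ivs[0, 1])
    for s, e in ivs[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, int(e))
        else:
            total += cur_e - cur_s
            cur_s, cur_e = int(s), int(e)
    total += cur_e - cur_s
    return total / ann.genome_length


def positional_enrichment_test(k: int, n: int, p0: float, alternative: str = "greater") -> BinomialResult:
    """Exact binomial tail probability by direct summation in log space.

    greater (default): P(X >= k) — the chance of seeing at least k
    intergenic peaks among n if placement were unbiased with success
    probability ``p0`` (one minus the genic fraction).  ``two_sided``
    doubles the smaller tail (capped at 1).
    """
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"p0 must be in (0, 1), got {p0}")

    def _log_tail(lo: int, hi: int) -> float:
        j = np.arange(lo, hi + 1)
        logpmf = (
            gammaln(n + 1) - gammaln(j + 1) - gammaln(n - j + 1)
            + j * np.log(p0) + (n - j) * np.log1p(-p0)
        )
        return float(logsumexp(logpmf))

    if alternative == "greater":
        p = 1.0 if k == 0 else min(1.0, float(np.exp(_log_tail(k, n))))
    elif alternative == "less":
        p = min(1.0, float(np.exp(_log_tail(0, k))))
    elif alternative == "two_sided":
        upper = 1.0 if k == 0 else np.exp(_log_tail(k, n))
        lower = np.exp(_log_tail(0, k))
        p = min(1.0, 2.0 * min(upper, lower))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return BinomialResult(k=int(k), n=int(n), p0=float(p0), p_value=p, alternative=alternative)


def rank_analysis(
    targets: list[TargetRegion], disputed_names: set, bottom_count: int
) -> tuple[int, int]:
    """Count disputed targets among the ``bottom_count`` weakest targets.

    Targets are ranked ascending by peak z (ties broken by position); the
    return value is (number of disputed names in the bottom slice,
    bottom_count).
    """
    if bottom_count > len(targets):
        raise ValueError("bottom_count exceeds number of targets")
    known = {t.name for t in targets}
    unknown = set(disputed_names) - known
    if unknown:
        logger.warning("rank_analysis: %d disputed name(s) not among targets: %s",
                       len(unknown), sorted(unknown)[:5])
    ranked = sorted(targets, key=lambda t: (t.peak_z, t.peak_position))
    bottom = ranked[:bottom_count]
    return sum(t.name in disputed_names for t in bottom), int(bottom_count)


# ---------------------------------------------------------------------------
# tabular conversion (for TSV round-trips)

_TARGET_COLS = ["sequence_id", "peak_position", "peak_z", "region_start",
                "region_end", "context", "name"]


def targets_to_frame(targets: list[TargetRegion]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(t, c) for c in _TARGET_COLS} for t in targets],
                        columns=_TARGET_COLS)


def frame_to_targets(df: pd.DataFrame) -> list[TargetRegion]:
    return [
        TargetRegion(
            sequence_id=str(r.sequence_id),
            peak_position=int(r.peak_position),
            peak_z=float(r.peak_z),
            region_start=int(r.region_start),
            region_end=int(r.region_end),
            context=str(r.context),
            name=str(r.name),
        )
        for r in df.itertuples(index=False)
    ]


def classify_targets(targets: list[TargetRegion], ann: GeneAnnotation) -> list[TargetRegion]:
    """Return targets with ``context`` filled from their peak positions."""
    from dataclasses import replace

    return [replace(t, context=classify_position(ann, t.peak_position)) for t in targets]
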