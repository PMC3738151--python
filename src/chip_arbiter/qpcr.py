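"""ChIP/qPCR occupancy: Ct values to background-subtracted fold enrichment.

Within one sample, the abundance of a target amplicon relative to a control
amplicon (a transcriptionally silent region) is ``E**(Ct_control -
Ct_target)`` with amplification efficiency E (2.0 for perfect doubling).
Fold enrichment normalises the IP sample's relative quantity by the input
sample's; occupancy units subtract the background fold enrichment (1.0 for
an unenriched region, or the fold enrichment observed in an untagged
strain).  Conditions are compared with a one-tailed two-sample t-test over
biological replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

__all__ = [
    "QPCRTable",
    "OccupancyResult",
    "read_qpcr_table",
    "relative_quantity",
    "fold_enrichment",
    "occupancy",
    "condition_compare",
    "summarize_occupancy",
]

_REQUIRED = ["region", "sample_type", "condition", "replicate", "ct"]


@dataclass(frozen=True)
class QPCRTable:
    """Ct measurements by region x sample type x condition x replicate.

    ``measurements`` needs columns region, sample_type (IP|input),
    condition, replicate, ct.  ``efficiency`` is the amplification
    efficiency, either a single float or a mapping region -> efficiency.
    """

    measurements: pd.DataFrame
    control_region: str
    efficiency: float | dict = 2.0

    def __post_init__(self) -> None:
        df = self.measurements.loc[:, _REQUIRED].copy()
        df["replicate"] = df["replicate"].astype(int)
        df["ct"] = df["ct"].astype(float)
        object.__setattr__(self, "measurements", df.reset_index(drop=True))
        bad_types = set(df["sample_type"]) - {"IP", "input"}
        if bad_types:
            raise ValidationError(f"unknown sample_type(s): {sorted(bad_types)}")
        if not np.all(np.isfinite(df["ct"])):
            raise ValidationError("non-finite Ct value")
        if self.control_region not in set(df["region"]):
            raise ValidationError(f"control region {self.control_region!r} absent from table")
        for region, eff in self._efficiencies().items():
            if not (1.0 < eff <= 2.0):
                raise ValidationError(f"efficiency for {region!r} must be in (1, 2], got {eff}")
        # every (region, condition, replicate) must carry both IP and input
        counts = df.pivot_table(index=["region", "condition", "replicate"],
                                columns="sample_type", values="ct", aggfunc="size")
        for st in ("IP", "input"):
            if st not in counts.columns or counts[st].isna().any():
                missing = counts.index[counts.get(st, pd.Series(dtype=float)).isna()].tolist() \
                    if st in counts.columns else counts.index.tolist()
                raise ValidationError(f"missing {st} measurement for {missing[:5]}")

    def _efficiencies(self) -> dict:
        regions = set(self.measurements["region"])
        if isinstance(self.efficiency, dict):
            return {r: float(self.efficiency.get(r, 2.0)) for r in regions}
        return {r: float(self.efficiency) for r in regions}

    def regions(self) -> list[str]:
        return sorted(set(self.measurements["region"]) - {self.control_region})

    def conditions(self) -> list[str]:
        return sorted(set(self.measurements["condition"]))


@dataclass(frozen=True)
class OccupancyResult:
    """Mean occupancy (background-subtracted fold enrichment) for one region/condition."""

    region: str
    condition: str
    occupancy_mean: float
    occupancy_sd: float          # sample sd (n-1); NaN for a single replicate
    n_replicates: int
    per_replicate: tuple
    any_negative: bool = False   # flags occupancy below background


def read_qpcr_table(path: str | Path, control_region: str, efficiency: float | dict = 2.0) -> QPCRTable:
    """Read a Ct table from CSV (default) or TSV (.tsv/.tab extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(_REQUIRED) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    return QPCRTable(measurements=df, control_region=control_region, efficiency=efficiency)


def relative_quantity(ct_target: float, ct_control: float, efficiency: float = 2.0) -> float:
    """Abundance of the target amplicon relative to the control amplicon."""
    if not (1.0 < efficiency <= 2.0):
        raise ValueError(f"efficiency must be in (1, 2], got {efficiency}")
    if not (math.isfinite(ct_target) and math.isfinite(ct_control)):
        raise ValueError("non-finite Ct")
    return float(efficiency ** (ct_control - ct_target))


def fold_enrichment(rq_ip: float, rq_input: float) -> float:
    """IP relative quantity normalised to input DNA."""
    if rq_input <= 0:
        raise ValueError(f"input relative quantity must be positive, got {rq_input}")
    return float(rq_ip / rq_input)


def occupancy(fe: float, background_fe: float = 1.0) -> float:
    """Background-subtracted fold enrichment ("occupancy units")."""
    if background_fe <= 0:
        raise ValueError(f"background fold enrichment must be positive, got {background_fe}")
    return float(fe - background_fe)


def condition_compare(
    occ_a, occ_b, alternative: str = "greater", equal_var: bool = True
) -> tuple[float, float]:
    """One-tailed two-sample t-test of occupancy between two conditions.

    Default is the Student (pooled-variance) test with df = n_a + n_b - 2;
    ``equal_var=False`` selects Welch.  Returns (t statistic, one-tailed p).
    """
    a = np.asarray(occ_a, dtype=float)
    b = np.asarray(occ_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 replicates per condition")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite occupancy value")
    if alternative not in ("greater", "less"):
        raise ValueError(f"alternative must be greater or less, got {alternative!r}")
    n_a, n_b = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if equal_var:
        pooled = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
        if pooled == 0:
            raise ValueError("zero pooled variance: both samples are constant")
        t = (a.mean() - b.mean()) / math.sqrt(pooled * (1 / n_a + 1 / n_b))
        df = n_a + n_b - 2
    else:
        if va == 0 and vb == 0:
            raise ValueError("zero variance in both samples")
        se2a, se2b = va / n_a, vb / n_b
        t = (a.mean() - b.mean()) / math.sqrt(se2a + se2b)
        df = (se2a + se2b) ** 2 / (se2a**2 / (n_a - 1) + se2b**2 / (n_b - 1))
    p = float(stats.t.sf(t, df)) if alternative == "greater" else float(stats.t.cdf(t, df))
    return float(t), p


def _replicate_fe(table: QPCRTable, region: str, condition: str) -> dict[int, float]:
    """Per-replicate fold enrichment of ``region`` vs the control region."""
    df = table.measurements
    eff = table._efficiencies()
    out = {}
    sel = df[(df["condition"] == condition)]
    reps = sorted(set(sel.loc[sel["region"] == region, "replicate"]))
    for rep in reps:
        cts = {}
        for reg, st in ((region, "IP"), (region, "input"),
                        (table.control_region, "IP"), (table.control_region, "input")):
            row = sel[(sel["region"] == reg) & (sel["sample_type"] == st) & (sel["replicate"] == rep)]
            if len(row) != 1:
                raise ValidationError(
                    f"expected one Ct for region={reg} sample_type={st} "
                    f"condition={condition} replicate={rep}, found {len(row)}"
                )
            cts[(reg, st)] = float(row["ct"].iloc[0])
        rq_ip = relative_quantity(cts[(region, "IP")], cts[(table.control_region, "IP")],
                                  eff[region])
        rq_in = relative_quantity(cts[(region, "input")], cts[(table.control_region, "input")],
                                  eff[region])
        out[rep] = fold_enrichment(rq_ip, rq_in)
    return out


def summarize_occupancy(
    table: QPCRTable, background: float | QPCRTable = 1.0
) -> list[OccupancyResult]:
    """Per-region, per-condition occupancy with replicate mean and sample sd.

    ``background`` is either a constant fold enrichment (default 1.0, an
    unenriched region) or an untagged-strain :class:`QPCRTable` whose mean
    per-region fold enrichment is subtracted instead.
    """
    untagged_bg: dict[str, float] = {}
    if isinstance(background, QPCRTable):
        for region in background.regions():
            fes = []
            for cond in background.conditions():
                fes.extend(_replicate_fe(background, region, cond).values())
            untagged_bg[region] = float(np.mean(fes))
    results = []
    for region in table.regions():
        bg = untagged_bg.get(region, 1.0) if isinstance(background, QPCRTable) else float(background)
        for condition in table.conditions():
            fes = _replicate_fe(table, region, condition)
            if not fes:
                continue
            occs = [occupancy(fe, bg) for fe in fes.values()]
            arr = np.array(occs)
            results.append(
                OccupancyResult(
                    region=region,
                    condition=condition,
                    occupancy_mean=float(arr.mean()),
                    occupancy_sd=float(arr.std(ddof=1)) if len(arr) > 1 else float("nan"),
                    n_replicates=len(arr),
                    per_replicate=tuple(float(x) for x in arr),
                    any_negative=bool((arr < 0).any()),
                )
            )
    return results
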