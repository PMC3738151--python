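"""End-to-end orchestration: normalize, call, arbitrate, classify, test, report.

``run_pipeline`` consumes a :class:`RunConfig` (usually loaded from YAML),
executes every analysis stage in a fixed order with explicit seeds, writes
one TSV per result plus a JSON report, and is bit-identical across runs for
identical inputs and configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concordance import dst_vs_random_test, dynamic_range_summary, replicate_concordance
from .io import (CoordinateTable, read_annotation, read_probe_track, read_table,
                 write_probe_track, write_table)
from .null_model import ZTrack, estimate_null, compute_zscores
from .qpcr import condition_compare, read_qpcr_table, summarize_occupancy
from .targets import (call_targets, classify_targets, compare_studies, frame_to_targets,
                      genic_fraction, positional_enrichment_test, rank_analysis,
                      targets_to_frame, INTERGENIC, INTERGENIC_CONVERGENT)

logger = logging.getLogger("chip_arbiter")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "PipelineError", "average_ztracks"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class RunConfig:
    """Declarative description of one full analysis run.

    ``tracks`` maps study name -> list of bedGraph paths (replicates).
    Study-B targets may alternatively be supplied pre-called via
    ``study_b_targets`` (a targets TSV), as when arbitrating against
    another group's published call set.
    """

    tracks: dict
    annotation: str
    outdir: str
    genome_length: int | None = None
    exclude: list = field(default_factory=list)
    threshold: float = 3.0
    merge_distance: int = 500
    match_tolerance: int = 500
    n_random: int = 1000
    seed: int = 0
    mode_method: str = "kde"
    bandwidth: float | str = "auto"
    study_b_targets: str | None = None
    bottom_count: int | None = None      # default: bottom tertile of study-A targets
    qpcr: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        for study, paths in self.tracks.items():
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(f"track for study {study!r} missing: {p}")
        if not Path(self.annotation).exists():
            raise FileNotFoundError(f"annotation missing: {self.annotation}")

    def canonical_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Aggregated results of one pipeline run (all also written as TSV/JSON)."""

    fits: pd.DataFrame
    concordance: dict
    targets: dict
    comparison: object
    binomial: object
    mwu: dict
    rank: tuple
    occupancy: pd.DataFrame | None
    provenance: dict


def average_ztracks(ztracks: list[ZTrack], label: str) -> ZTrack:
    """Probe-wise mean of replicate z-tracks (shared grid required).

    The carrier ProbeTrack keeps the first replicate's raw values; only the
    averaged z-scores are consumed downstream.
    """
    first = ztracks[0]
    for zt in ztracks[1:]:
        if np.any(zt.track.starts != first.track.starts):
            raise ValueError("replicate probe grids differ; cannot average")
    mean_z = np.mean([zt.zscores for zt in ztracks], axis=0)
    track = dataclasses.replace(first.track, label=label)
    return ZTrack(track=track, zscores=mean_z, fit=first.fit)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full arbitration analysis and write all outputs.

    Stage order: load -> normalize each replicate -> call targets per study
    on the replicate-averaged z-track -> arbitrate A against B -> classify
    contexts and run the intergenic binomial test on disputed targets ->
    disputed-vs-random Mann-Whitney per study-B replicate -> per-study
    replicate concordance -> rank analysis -> optional qPCR occupancy.
    On failure, partial outputs are retained and a FAILED marker names the
    stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "FAILED"
    if marker.exists():
        marker.unlink()
    try:
        return _run(config, outdir)
    except PipelineError as exc:
        marker.write_text(f"{exc.stage}\n{exc}\n")
        raise


def _run(config: RunConfig, outdir: Path) -> RunReport:
    ann = _stage("load_annotation")(read_annotation)(config.annotation, config.genome_length)

    # --- normalize ---------------------------------------------------------
    @_stage("normalize")
    def _normalize():
        zt: dict[str, list[ZTrack]] = {}
        fit_rows = []
        for study, paths in sorted(config.tracks.items()):
            zt[study] = []
            for i, path in enumerate(paths, start=1):
                track = read_probe_track(path, label=f"{study}_rep{i}")
                fit = estimate_null(track.values, method=config.mode_method,
                                    bandwidth=config.bandwidth)
                z = compute_zscores(track, fit)
                zt[study].append(z)
                write_probe_track(track, outdir / f"z_{track.label}.bedGraph", values=z.zscores)
                fit_rows.append({
                    "label": track.label, "mode": fit.mode, "sigma": fit.sigma,
                    "n_below": fit.n_below, "n_total": fit.n_total,
                    "n_dropped": track.n_dropped,
                    "frac_below_z3": dynamic_range_summary(z, 3.0),
                    **{f"param_{k}": v for k, v in fit.method_params.items()},
                })
                logger.info("normalized %s: %d probes, mode=%.4g sigma=%.4g",
                            track.label, len(track), fit.mode, fit.sigma)
        fits = pd.DataFrame(fit_rows)
        write_table(fits, outdir / "fits.tsv")
        return zt, fits

    ztracks, fits = _normalize()

    # --- call targets ------------------------------------------------------
    @_stage("call_targets")
    def _call():
        called = {}
        for study, reps in ztracks.items():
            if study == "B" and config.study_b_targets:
                called[study] = frame_to_targets(read_table(config.study_b_targets))
                continue
            combined = average_ztracks(reps, label=study)
            called[study] = call_targets(combined, threshold=config.threshold,
                                         merge_distance=config.merge_distance)
            logger.info("study %s: %d targets called", study, len(called[study]))
        return called

    called = _call()
    studies = sorted(called)
    study_a, study_b = studies[0], studies[-1]

    @_stage("classify_context")
    def _classify():
        out = {s: classify_targets(t, ann) for s, t in called.items()}
        for s, t in out.items():
            write_table(targets_to_frame(t), outdir / f"targets_{s}.tsv")
        return out

    called = _classify()

    # --- arbitration -------------------------------------------------------
    @_stage("compare_studies")
    def _compare():
        comp = compare_studies(called[study_a], called[study_b],
                               tolerance=config.match_tolerance,
                               exclude=tuple(config.exclude))
        rows = []
        for t, b, d in comp.matched:
            rows.append({"name": t.name, "peak_position": t.peak_position,
                         "peak_z": t.peak_z, "context": t.context, "status": "matched",
                         "matched_name": b.name, "distance": d})
        for t in comp.disputed:
            rows.append({"name": t.name, "peak_position": t.peak_position,
                         "peak_z": t.peak_z, "context": t.context, "status": "disputed",
                         "matched_name": "", "distance": np.nan})
        for t in comp.excluded:
            rows.append({"name": t.name, "peak_position": t.peak_position,
                         "peak_z": t.peak_z, "context": t.context, "status": "excluded",
                         "matched_name": "", "distance": np.nan})
        write_table(pd.DataFrame(rows, columns=["name", "peak_position", "peak_z",
                                                "context", "status", "matched_name",
                                                "distance"]),
                    outdir / "comparison.tsv")
        logger.info("arbitration: %d matched, %d disputed, %d excluded",
                    len(comp.matched), len(comp.disputed), len(comp.excluded))
        return comp

    comparison = _compare()

    # --- positional enrichment --------------------------------------------
    @_stage("positional_enrichment")
    def _binomial():
        k = sum(t.context in (INTERGENIC, INTERGENIC_CONVERGENT) for t in comparison.disputed)
        n = len(comparison.disputed)
        gf = genic_fraction(ann)
        if n == 0 or not (0.0 < 1.0 - gf < 1.0):
            return None
        res = positional_enrichment_test(k, n, p0=1.0 - gf)
        write_table(pd.DataFrame([{
            "k_intergenic_disputed": res.k, "n_disputed": res.n, "p0": res.p0,
            "expected": res.expected, "p_value": res.p_value,
            "alternative": res.alternative, "genic_fraction": gf,
        }]), outdir / "binomial.tsv")
        return res

    binomial = _binomial()

    # --- disputed vs random ------------------------------------------------
    @_stage("dst_vs_random")
    def _mwu():
        if not comparison.disputed:
            return {}
        coords = CoordinateTable(records=pd.DataFrame({
            "sequence_id": [t.sequence_id for t in comparison.disputed],
            "position": [t.peak_position for t in comparison.disputed],
            "name": [t.name for t in comparison.disputed],
        }))
        out, rows = {}, []
        for i, z in enumerate(ztracks[study_b]):
            n_random = min(config.n_random, len(z) - 1)
            res = dst_vs_random_test(z, coords, n_random=n_random, seed=config.seed + i)
            out[z.track.label] = res
            rows.append({"label": z.track.label, "U": res.U, "n_dst": res.n_a,
                         "n_random": res.n_b, "p_value": res.p_value,
                         "method": res.method, "alternative": res.alternative,
                         "seed": res.seed})
        write_table(pd.DataFrame(rows), outdir / "mwu.tsv")
        return out

    mwu = _mwu()

    # --- concordance -------------------------------------------------------
    @_stage("concordance")
    def _concordance():
        out, rows = {}, []
        for study, reps in ztracks.items():
            if len(reps) < 2:
                continue
            rep = replicate_concordance(reps[0], reps[1], threshold=config.threshold)
            out[study] = rep
            rows.append({"study": study, "spearman_rho": rep.spearman_rho,
                         "n_probes": rep.n_probes,
                         "frac_below_threshold": rep.frac_below_threshold,
                         "threshold": rep.threshold})
        write_table(pd.DataFrame(rows), outdir / "concordance.tsv")
        return out

    concordance = _concordance()

    # --- rank analysis -----------------------------------------------------
    @_stage("rank_analysis")
    def _rank():
        targets_a = called[study_a]
        if not targets_a:
            return (0, 0)
        bottom = config.bottom_count or max(1, len(targets_a) // 3)
        count, bottom = rank_analysis(targets_a, comparison.disputed_names, bottom)
        write_table(pd.DataFrame([{"disputed_in_bottom": count, "bottom_count": bottom,
                                   "n_targets": len(targets_a),
                                   "n_disputed": len(comparison.disputed)}]),
                    outdir / "rank.tsv")
        return count, bottom

    rank = _rank()

    # --- qPCR (optional) ---------------------------------------------------
    @_stage("qpcr")
    def _qpcr():
        if not config.qpcr:
            return None
        q = dict(config.qpcr)
        table = read_qpcr_table(q["path"], control_region=q["control_region"],
                                efficiency=q.get("efficiency", 2.0))
        background = q.get("background", 1.0)
        results = summarize_occupancy(table, background=background)
        rows = [dataclasses.asdict(r) for r in results]
        for r in rows:
            r["per_replicate"] = ",".join(f"{x:.6g}" for x in r["per_replicate"])
        df = pd.DataFrame(rows)
        compare = q.get("compare")
        if compare:
            cond_a, cond_b = compare["conditions"]
            alt = compare.get("alternative", "greater")
            trows = []
            by = {(r.region, r.condition): r for r in results}
            for region in sorted({r.region for r in results}):
                ra, rb = by.get((region, cond_a)), by.get((region, cond_b))
                if ra is None or rb is None:
                    continue
                t, p = condition_compare(list(ra.per_replicate), list(rb.per_replicate),
                                         alternative=alt)
                trows.append({"region": region, "condition_a": cond_a, "condition_b": cond_b,
                              "t": t, "p_value": p, "alternative": alt})
            write_table(pd.DataFrame(trows), outdir / "qpcr_tests.tsv")
        write_table(df, outdir / "occupancy.tsv")
        return df

    occupancy = _qpcr()

    # --- report ------------------------------------------------------------
    provenance = {
        "version": __version__,
        "config_hash": config.canonical_hash(),
        "seed": config.seed,
        "threshold": config.threshold,
        "merge_distance": config.merge_distance,
        "match_tolerance": config.match_tolerance,
    }
    report = {
        "provenance": provenance,
        "fits": fits.to_dict(orient="records"),
        "concordance": {s: dataclasses.asdict(c) for s, c in concordance.items()},
        "n_targets": {s: len(t) for s, t in called.items()},
        "arbitration": {
            "matched": len(comparison.matched),
            "disputed": len(comparison.disputed),
            "excluded": len(comparison.excluded),
            "disputed_names": sorted(comparison.disputed_names),
        },
        "binomial": dataclasses.asdict(binomial) if binomial else None,
        "mwu": {k: dataclasses.asdict(v) for k, v in mwu.items()},
        "rank_analysis": {"disputed_in_bottom": rank[0], "bottom_count": rank[1]},
        "multiple_testing": "raw p-values reported; no correction applied",
    }
    (Path(outdir) / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    return RunReport(fits=fits, concordance=concordance, targets=called,
                     comparison=comparison, binomial=binomial, mwu=mwu, rank=rank,
                     occupancy=occupancy, provenance=provenance)
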