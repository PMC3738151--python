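"""Synthetic two-study ChIP-chip data with recorded ground truth.

The generator emulates the study design being arbitrated: one annotated
bacterial chromosome, a set of true binding sites spanning a wide amplitude
range, and two "studies" of two replicate tiling-array tracks each on
different probe grids.  Study B applies a sensitivity attenuation to every
site's enrichment and adds extra per-replicate noise, reproducing the
lower-dynamic-range / lower-reproducibility contrast that makes weak sites
"disputed".  A qPCR Ct table is derived from the same per-site truth.

Signal model for a probe with midpoint m (all noise scales are multiples of
``null_sd``):

    value = null_mean + baseline(m) + attenuation * enrich(m) + rep_noise + extra_noise
    enrich(m) = sum_sites amplitude * null_sd * max(0, 1 - |m - site| / peak_halfwidth)

``baseline`` ~ Normal(0, null_sd) is drawn once per probe per study and
shared by that study's replicates (probe-affinity noise: this is what makes
replicate rank correlation high for mostly-null tracks); rep_noise is
Normal(0, replicate_noise_sd * null_sd) per replicate; extra_noise applies
to study B only.  Sites sit on study-A probe midpoints, so a site of
amplitude a yields an expected study-A peak z of about
a / sqrt(1 + replicate_noise_sd**2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GeneAnnotation, ProbeTrack, write_annotation, write_probe_track, write_table
from .qpcr import QPCRTable
from .targets import classify_position

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_genome",
    "simulate_tracks",
    "simulate_qpcr",
    "simulate_all",
    "qpcr_truth",
    "write_simulation",
]

SEQUENCE_ID = "synth_chr"
STUDIES = ("A", "B")
REPLICATES = (1, 2)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator, with desk-scale defaults.

    The default geometry (500 kb genome, 200 bp probe spacing, 40 genes,
    30 sites) runs in well under a second while leaving >90% of probes
    null.  ``study_b_attenuation`` scales every site's enrichment in study
    B; ``study_b_extra_noise_sd`` adds replicate-independent noise there,
    degrading both dynamic range and reproducibility.
    """

    genome_length: int = 500_000
    n_genes: int = 40
    gene_length_mean: int = 10_000
    probe_spacing: int = 200
    probe_length: int = 50
    null_mean: float = 10.0
    null_sd: float = 2.0
    n_sites: int = 30
    amplitude_range: tuple = (3.0, 15.0)       # multiples of null_sd
    frac_intergenic_sites: float = 0.33
    peak_halfwidth: int = 250
    replicate_noise_sd: float = 0.3            # multiples of null_sd
    study_b_attenuation: float = 0.4
    study_b_extra_noise_sd: float = 1.0        # multiples of null_sd
    qpcr_ct_noise_sd: float = 0.1              # cycles
    qpcr_induction_factor: float = 3.0
    qpcr_efficiency: float = 2.0
    qpcr_n_regions: int = 4
    qpcr_replicates: int = 3
    min_gene_gap: int = 1_000
    min_site_separation: int = 2_000
    seed: int = 17

    def validate(self) -> None:
        if min(self.genome_length, self.probe_spacing, self.probe_length,
               self.peak_halfwidth, self.gene_length_mean) <= 0:
            raise ValueError("lengths must be positive")
        if not (0.0 < self.study_b_attenuation <= 1.0):
            raise ValueError("study_b_attenuation must be in (0, 1]")
        low, high = self.amplitude_range
        if not low < high:
            raise ValueError("amplitude_range must satisfy low < high")
        if not (0.0 <= self.frac_intergenic_sites <= 1.0):
            raise ValueError("frac_intergenic_sites must be in [0, 1]")
        if self.null_sd <= 0:
            raise ValueError("null_sd must be positive")

    def stream_seeds(self) -> dict[str, np.random.SeedSequence]:
        """Derive independent per-stage seed sequences from the master seed."""
        genome, tracks, qpcr = np.random.SeedSequence(self.seed).spawn(3)
        return {"genome": genome, "tracks": tracks, "qpcr": qpcr}


@dataclass(frozen=True)
class SimulationTruth:
    """Everything the generator knows: annotation, sites and null params.

    ``sites`` columns: name, position, amplitude (multiples of null_sd),
    context (consistent with classify_position), true_fe (per-site true
    qPCR fold enrichment, 1 + amplitude).  ``null_params`` maps each track
    label to its generating null mean and effective null sd.
    """

    annotation: GeneAnnotation
    sites: pd.DataFrame
    config: SimulationConfig
    null_params: dict = field(default_factory=dict)


def _probe_grid(config: SimulationConfig, offset: int = 0) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(offset, config.genome_length - config.probe_length + 1,
                       config.probe_spacing, dtype=np.int64)
    return starts, starts + config.probe_length


def probe_midpoints(config: SimulationConfig, study: str = "A") -> np.ndarray:
    """Midpoints of a study's probe grid (study B is offset half a spacing)."""
    offset = 0 if study == "A" else config.probe_spacing // 2
    starts, ends = _probe_grid(config, offset)
    return (starts + ends) // 2


def simulate_genome(config: SimulationConfig, seed=None) -> tuple[GeneAnnotation, pd.DataFrame]:
    """Place non-overlapping genes and true binding sites; deterministic per seed.

    Genes are laid out left to right with random lengths and random gaps of
    at least ``min_gene_gap`` bp (sequential layout reaches high genic
    fractions that rejection sampling cannot).  Sites sit on study-A probe
    midpoints; the realized intergenic site fraction matches
    ``frac_intergenic_sites`` to within one site when both context classes
    offer enough candidates.
    """
    config.validate()
    rng = np.random.default_rng(config.stream_seeds()["genome"] if seed is None else seed)
    L, n = config.genome_length, config.n_genes
    if n > 0:
        lengths = np.maximum(
            300, np.round(rng.normal(config.gene_length_mean, 0.25 * config.gene_length_mean, n))
        ).astype(np.int64)
        free = L - int(lengths.sum()) - (n + 1) * config.min_gene_gap
        if free < 0:
            raise ValueError(
                f"genes cannot fit: total gene length {lengths.sum()} + gaps exceed "
                f"genome {L}; reduce n_genes or gene_length_mean, or lengthen the genome"
            )
        w = rng.exponential(1.0, n + 1)
        gaps = config.min_gene_gap + np.floor(w / w.sum() * free).astype(np.int64)
        starts = np.cumsum(gaps[:-1]) + np.concatenate([[0], np.cumsum(lengths[:-1])])
        strands = rng.choice(["+", "-"], size=n)
        genes = pd.DataFrame(
            {
                "sequence_id": SEQUENCE_ID,
                "start": starts,
                "end": starts + lengths,
                "strand": strands,
                "name": [f"gene_{i + 1:03d}" for i in range(n)],
            }
        )
    else:
        genes = pd.DataFrame(columns=["sequence_id", "start", "end", "strand", "name"])
    ann = GeneAnnotation(genes=genes, genome_length=L)

    mids = probe_midpoints(config, "A")
    contexts = np.array([classify_position(ann, int(m)) for m in mids])
    intergenic_pool = mids[contexts != "genic"]
    genic_pool = mids[contexts == "genic"]
    n_inter = int(round(config.frac_intergenic_sites * config.n_sites))

    def _draw(pool: np.ndarray, want: int, chosen: list[int]) -> list[int]:
        if want <= 0 or len(pool) == 0:
            return []
        order = rng.permutation(len(pool))
        out = []
        for i in order:
            p = int(pool[i])
            if all(abs(p - c) >= config.min_site_separation for c in chosen + out):
                out.append(p)
                if len(out) == want:
                    break
        return out

    chosen: list[int] = []
    inter_sites = _draw(intergenic_pool, min(n_inter, config.n_sites), chosen)
    chosen += inter_sites
    genic_sites = _draw(genic_pool, config.n_sites - len(inter_sites), chosen)
    chosen += genic_sites
    if len(chosen) < config.n_sites:
        # a context class ran out of candidates; fill from the other class
        extra = _draw(np.concatenate([intergenic_pool, genic_pool]),
                      config.n_sites - len(chosen), chosen)
        chosen += extra
    if len(chosen) < config.n_sites:
        raise ValueError(
            f"could only place {len(chosen)} of {config.n_sites} sites at "
            f"min separation {config.min_site_separation}; enlarge the genome"
        )
    positions = np.array(sorted(chosen), dtype=np.int64)
    low, high = config.amplitude_range
    amplitudes = rng.uniform(low, high, size=len(positions))
    sites = pd.DataFrame(
        {
            "name": [f"site_{i + 1:02d}" for i in range(len(positions))],
            "position": positions,
            "amplitude": amplitudes,
            "context": [classify_position(ann, int(p)) for p in positions],
            "true_fe": 1.0 + amplitudes,
        }
    )
    return ann, sites


def _enrichment(mids: np.ndarray, sites: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    e = np.zeros(len(mids), dtype=float)
    hw = config.peak_halfwidth
    for pos, amp in zip(sites["position"], sites["amplitude"]):
        kern = 1.0 - np.abs(mids - pos) / hw
        np.maximum(kern, 0.0, out=kern)
        e += amp * config.null_sd * kern
    return e


def simulate_tracks(truth: SimulationTruth, config: SimulationConfig | None = None,
                    seed=None) -> dict[tuple[str, int], ProbeTrack]:
    """Generate the four probe tracks, keyed by (study, replicate)."""
    config = config or truth.config
    config.validate()
    rng = np.random.default_rng(config.stream_seeds()["tracks"] if seed is None else seed)
    tracks: dict[tuple[str, int], ProbeTrack] = {}
    for study in STUDIES:
        offset = 0 if study == "A" else config.probe_spacing // 2
        starts, ends = _probe_grid(config, offset)
        mids = (starts + ends) // 2
        baseline = rng.normal(0.0, config.null_sd, size=len(mids))  # shared by replicates
        enrich = _enrichment(mids, truth.sites, config)
        if study == "B":
            enrich = enrich * config.study_b_attenuation
        for rep in REPLICATES:
            values = (
                config.null_mean
                + baseline
                + enrich
                + rng.normal(0.0, config.replicate_noise_sd * config.null_sd, size=len(mids))
            )
            if study == "B":
                values = values + rng.normal(
                    0.0, config.study_b_extra_noise_sd * config.null_sd, size=len(mids)
                )
            tracks[(study, rep)] = ProbeTrack(
                sequence_id=SEQUENCE_ID, starts=starts, ends=ends,
                values=values, label=f"{study}_rep{rep}",
            )
    return tracks


def qpcr_truth(truth: SimulationTruth, config: SimulationConfig | None = None) -> pd.DataFrame:
    """True fold enrichment per qPCR region and condition (no noise).

    Regions are ``qpcr_n_regions`` sites spread evenly across the amplitude
    ranking (strongest site included, mimicking a strong canonical control
    target plus weaker disputed ones) plus the unenriched control region.
    Heat shock multiplies each site's excess enrichment by
    ``qpcr_induction_factor``.
    """
    config = config or truth.config
    ranked = truth.sites.sort_values("amplitude", ascending=False).reset_index(drop=True)
    n = min(config.qpcr_n_regions, len(ranked))
    idx = np.unique(np.round(np.linspace(0, len(ranked) - 1, n)).astype(int))
    rows = []
    for _, site in ranked.iloc[idx].iterrows():
        fe = float(site["true_fe"])
        rows.append({"region": site["name"], "condition": "no_heat_shock", "true_fe": fe})
        rows.append({"region": site["name"], "condition": "heat_shock",
                     "true_fe": 1.0 + (fe - 1.0) * config.qpcr_induction_factor})
    return pd.DataFrame(rows)


CONTROL_REGION = "bglB_like_control"
_CT_INPUT_BASE = 20.0
_CT_IP_CONTROL_BASE = 24.0


def simulate_qpcr(truth: SimulationTruth, config: SimulationConfig | None = None,
                  seed=None, induction_factor: float | None = None) -> QPCRTable:
    """Generate a Ct table whose noiseless occupancy equals (true FE - 1).

    Input Cts are flat across regions (equal input abundance); the IP Ct of
    a region sits log_E(FE) cycles below the control amplicon's IP Ct.
    Gaussian noise of sd ``qpcr_ct_noise_sd`` cycles is added to every Ct
    independently.
    """
    config = config or truth.config
    rng = np.random.default_rng(config.stream_seeds()["qpcr"] if seed is None else seed)
    tf = qpcr_truth(truth, config)
    if induction_factor is not None:
        base = tf[tf["condition"] == "no_heat_shock"].copy()
        induced = base.copy()
        induced["condition"] = "heat_shock"
        induced["true_fe"] = 1.0 + (base["true_fe"] - 1.0) * induction_factor
        tf = pd.concat([base, induced], ignore_index=True)
    loge = np.log(config.qpcr_efficiency)
    rows = []
    conditions = sorted(set(tf["condition"]))
    for condition in conditions:
        sub = tf[tf["condition"] == condition]
        for rep in range(1, config.qpcr_replicates + 1):
            noise = lambda: float(rng.normal(0.0, config.qpcr_ct_noise_sd))
            rows.append({"region": CONTROL_REGION, "sample_type": "input",
                         "condition": condition, "replicate": rep,
                         "ct": _CT_INPUT_BASE + noise()})
            rows.append({"region": CONTROL_REGION, "sample_type": "IP",
                         "condition": condition, "replicate": rep,
                         "ct": _CT_IP_CONTROL_BASE + noise()})
            for _, r in sub.iterrows():
                ct_ip = _CT_IP_CONTROL_BASE - np.log(r["true_fe"]) / loge
                rows.append({"region": r["region"], "sample_type": "input",
                             "condition": condition, "replicate": rep,
                             "ct": _CT_INPUT_BASE + noise()})
                rows.append({"region": r["region"], "sample_type": "IP",
                             "condition": condition, "replicate": rep,
                             "ct": float(ct_ip) + noise()})
    return QPCRTable(measurements=pd.DataFrame(rows), control_region=CONTROL_REGION,
                     efficiency=config.qpcr_efficiency)


def simulate_all(config: SimulationConfig) -> tuple[
    SimulationTruth, dict[tuple[str, int], ProbeTrack], QPCRTable
]:
    """Run all three stages from the master seed."""
    ann, sites = simulate_genome(config)
    rep_var = 1.0 + config.replicate_noise_sd**2
    extra_var = config.study_b_extra_noise_sd**2
    null_params = {}
    for study in STUDIES:
        sd = config.null_sd * np.sqrt(rep_var + (extra_var if study == "B" else 0.0))
        for rep in REPLICATES:
            null_params[f"{study}_rep{rep}"] = {"mean": config.null_mean, "sd": float(sd)}
    truth = SimulationTruth(annotation=ann, sites=sites, config=config, null_params=null_params)
    tracks = simulate_tracks(truth, config)
    table = simulate_qpcr(truth, config)
    return truth, tracks, table


def write_simulation(outdir: str | Path, truth: SimulationTruth,
                     tracks: dict, table: QPCRTable) -> dict[str, Path]:
    """Write genome.gff3, truth_sites.tsv, the four bedGraphs, qpcr_ct.csv
    and a machine-readable truth manifest; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"annotation": outdir / "genome.gff3", "sites": outdir / "truth_sites.tsv",
             "qpcr": outdir / "qpcr_ct.csv", "manifest": outdir / "truth_manifest.tsv"}
    write_annotation(truth.annotation, paths["annotation"])
    write_table(truth.sites, paths["sites"])
    for (study, rep), track in tracks.items():
        p = outdir / f"{study}_rep{rep}.bedGraph"
        write_probe_track(track, p)
        paths[f"{study}_rep{rep}"] = p
    table.measurements.to_csv(paths["qpcr"], index=False)
    manifest = [{"key": k, "value": v} for k, v in asdict(truth.config).items()]
    manifest += [{"key": f"null_{label}_{k}", "value": v}
                 for label, pars in truth.null_params.items() for k, v in pars.items()]
    write_table(pd.DataFrame(manifest), paths["manifest"])
    return paths
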