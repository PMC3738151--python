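"""Ground-truth consistency and closed-loop recovery for the generator."""

import logging

import numpy as np
import pytest

import chip_arbiter as ca


class TestSimulateGenome:
    def test_deterministic_per_seed(self):
        cfg = ca.SimulationConfig(seed=3)
        ann1, sites1 = ca.simulate_genome(cfg)
        ann2, sites2 = ca.simulate_genome(cfg)
        assert ann1.genes.equals(ann2.genes)
        assert sites1.equals(sites2)

    def test_different_seeds_differ(self):
        s1 = ca.simulate_genome(ca.SimulationConfig(seed=1))[1]
        s2 = ca.simulate_genome(ca.SimulationConfig(seed=2))[1]
        assert not s1["position"].equals(s2["position"])

    def test_all_intergenic_when_requested(self):
        cfg = ca.SimulationConfig(frac_intergenic_sites=1.0, n_sites=10, seed=5)
        ann, sites = ca.simulate_genome(cfg)
        assert all(
            ca.classify_position(ann, int(p)) != "genic" for p in sites["position"]
        )

    def test_no_genes_all_intergenic(self):
        cfg = ca.SimulationConfig(n_genes=0, n_sites=10, seed=5)
        ann, sites = ca.simulate_genome(cfg)
        assert ca.genic_fraction(ann) == 0.0
        assert set(sites["context"]) == {"intergenic"}

    def test_intergenic_fraction_near_request(self):
        cfg = ca.SimulationConfig(seed=11)
        _, sites = ca.simulate_genome(cfg)
        n_inter = (sites["context"] != "genic").sum()
        want = round(cfg.frac_intergenic_sites * cfg.n_sites)
        assert abs(n_inter - want) <= 1

    def test_contexts_consistent_with_classifier(self):
        ann, sites = ca.simulate_genome(ca.SimulationConfig(seed=13))
        for _, s in sites.iterrows():
            assert s["context"] == ca.classify_position(ann, int(s["position"]))

    def test_unfittable_genes_rejected(self):
        cfg = ca.SimulationConfig(genome_length=50_000, n_genes=40,
                                  gene_length_mean=10_000)
        with pytest.raises(ValueError, match="cannot fit"):
            ca.simulate_genome(cfg)


class TestSimulateTracks:
    def test_null_recovery_with_zero_sites(self):
        cfg = ca.SimulationConfig(n_sites=0, replicate_noise_sd=0.0,
                                  genome_length=2_000_000, seed=7)
        ann, sites = ca.simulate_genome(cfg)
        truth = ca.SimulationTruth(annotation=ann, sites=sites, config=cfg)
        tracks = ca.simulate_tracks(truth)
        t = tracks[("A", 1)]
        fit = ca.estimate_null(t.values)
        assert abs(fit.mode - cfg.null_mean) <= 0.1 * cfg.null_sd
        assert abs(fit.sigma / cfg.null_sd - 1.0) <= 0.10

    def test_amplitude_maps_to_peak_z(self):
        """A site of amplitude 10 on a probe midpoint shows z ~ 10 at that probe."""
        import pandas as pd

        zs = []
        for seed in range(20):
            cfg = ca.SimulationConfig(n_sites=0, genome_length=1_000_000, seed=seed)
            ann, _ = ca.simulate_genome(cfg)
            mids = ca.probe_midpoints(cfg, "A")
            site = pd.DataFrame({"name": ["s"], "position": [int(mids[len(mids) // 2])],
                                 "amplitude": [10.0], "context": ["genic"],
                                 "true_fe": [11.0]})
            truth = ca.SimulationTruth(annotation=ann, sites=site, config=cfg)
            track = ca.simulate_tracks(truth)[("A", 1)]
            z = ca.compute_zscores(track, ca.estimate_null(track.values))
            zs.append(z.zscores[len(mids) // 2])
        assert abs(np.mean(zs) / (10.0 / np.sqrt(1 + cfg.replicate_noise_sd**2)) - 1) < 0.15

    def test_identity_limit_study_b_matches_a(self):
        """With attenuation 1 and no extra noise, study B concordance equals A's."""
        cfg = ca.SimulationConfig(study_b_attenuation=1.0, study_b_extra_noise_sd=0.0,
                                  genome_length=5_000_000, probe_spacing=50,
                                  probe_length=50, n_genes=40, seed=21)
        ann, sites = ca.simulate_genome(cfg)
        truth = ca.SimulationTruth(annotation=ann, sites=sites, config=cfg)
        tracks = ca.simulate_tracks(truth)
        rhos = {}
        for study in ("A", "B"):
            z1, z2 = (ca.normalize_track(tracks[(study, r)]) for r in (1, 2))
            rhos[study] = ca.replicate_concordance(z1, z2).spearman_rho
        assert abs(rhos["A"] - rhos["B"]) < 0.02

    def test_degradation_monotone_in_extra_noise(self):
        rhos = []
        for extra in (0.0, 1.0, 2.0):
            per_seed = []
            for seed in range(5):
                cfg = ca.SimulationConfig(study_b_extra_noise_sd=extra, seed=seed)
                ann, sites = ca.simulate_genome(cfg)
                truth = ca.SimulationTruth(annotation=ann, sites=sites, config=cfg)
                tracks = ca.simulate_tracks(truth)
                z1, z2 = (ca.normalize_track(tracks[("B", r)]) for r in (1, 2))
                per_seed.append(ca.replicate_concordance(z1, z2).spearman_rho)
            rhos.append(np.mean(per_seed))
        assert rhos[0] > rhos[1] > rhos[2]

    def test_closed_loop_site_recovery(self):
        """Sites of amplitude >= 5 null-sd are recalled as called targets, and
        strong false calls (z >= 4.5) away from any site are absent."""
        recovered_ok = strong_fp_free = runs = 0
        for seed in range(15):
            cfg = ca.SimulationConfig(seed=seed)
            truth, tracks, _ = ca.simulate_all(cfg)
            za = [ca.normalize_track(tracks[("A", r)]) for r in (1, 2)]
            combined = ca.average_ztracks(za, label="A")
            targets = ca.call_targets(combined, threshold=3.0, merge_distance=500)
            peaks = np.array([t.peak_position for t in targets])
            strong = truth.sites[truth.sites["amplitude"] >= 5.0]
            hit = sum(np.any(np.abs(peaks - p) <= cfg.peak_halfwidth)
                      for p in strong["position"])
            recovered_ok += hit >= 0.95 * len(strong)
            strong_targets = [t for t in targets if t.peak_z >= 4.5]
            site_pos = truth.sites["position"].to_numpy()
            fp = sum(np.all(np.abs(site_pos - t.peak_position) > cfg.peak_halfwidth)
                     for t in strong_targets)
            strong_fp_free += fp == 0
            runs += 1
        assert recovered_ok >= 0.9 * runs
        assert strong_fp_free >= 0.9 * runs


class TestSimulateQpcr:
    def test_deterministic_per_seed(self):
        cfg = ca.SimulationConfig(seed=9)
        truth, _, t1 = ca.simulate_all(cfg)
        t2 = ca.simulate_qpcr(truth)
        assert t1.measurements.equals(t2.measurements)

    def test_noiseless_inverts_to_true_fold_enrichment(self):
        cfg = ca.SimulationConfig(qpcr_ct_noise_sd=0.0, seed=9)
        truth, _, table = ca.simulate_all(cfg)
        tf = ca.qpcr_truth(truth)
        by = {(r.region, r.condition): r.occupancy_mean
              for r in ca.summarize_occupancy(table)}
        for _, row in tf.iterrows():
            assert by[(row["region"], row["condition"])] == pytest.approx(
                row["true_fe"] - 1.0, abs=1e-9)

    def test_emitted_files_parse_cleanly(self, tmp_path, caplog):
        cfg = ca.SimulationConfig(seed=4)
        truth, tracks, table = ca.simulate_all(cfg)
        paths = ca.write_simulation(tmp_path, truth, tracks, table)
        with caplog.at_level(logging.WARNING, logger="chip_arbiter"):
            ann = ca.read_annotation(paths["annotation"])
            for study in ("A", "B"):
                for rep in (1, 2):
                    t = ca.read_probe_track(paths[f"{study}_rep{rep}"])
                    assert len(t) > 0
            back = ca.read_qpcr_table(paths["qpcr"], control_region="bglB_like_control")
        assert ann.genome_length == cfg.genome_length
        assert not caplog.records
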