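"""Call targets in two studies and derive the disputed-target set.

Both studies see the same true binding sites, but study B's enrichment is
attenuated (40%) and noisier, so its call set is smaller; study-A targets
without a study-B match within 500 bp become "disputed".  Their genomic
context (genic / intergenic) is then tested against the genome's genic
fraction with an exact one-sided binomial test.
"""

import chip_arbiter as ca

cfg = ca.SimulationConfig(seed=17)
truth, tracks, _ = ca.simulate_all(cfg)

targets = {}
for study in ("A", "B"):
    zreps = [ca.normalize_track(tracks[(study, r)]) for r in (1, 2)]
    combined = ca.average_ztracks(zreps, label=study)
    called = ca.call_targets(combined, threshold=3.0, merge_distance=500)
    targets[study] = ca.classify_targets(called, truth.annotation)
    print(f"study {study}: {len(called)} targets called (of {len(truth.sites)} true sites)")

comp = ca.compare_studies(targets["A"], targets["B"], tolerance=500)
print(f"matched {len(comp.matched)}, disputed {len(comp.disputed)}")

k = sum(t.context != "genic" for t in comp.disputed)
p0 = 1.0 - ca.genic_fraction(truth.annotation)
res = ca.positional_enrichment_test(k, len(comp.disputed), p0)
print(f"{k}/{res.n} disputed targets are intergenic; expected {res.expected:.1f} "
      f"by chance -> one-sided binomial p = {res.p_value:.3g}")
# A small p says disputed targets favour intergenic positions more than a
# random placement would - an argument that they are real promoters.
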