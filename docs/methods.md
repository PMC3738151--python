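# Methods

## The problem being modelled

Two ChIP-chip studies of the same DNA-binding protein on one bacterial
chromosome disagree: study A calls many targets, study B far fewer, and
the A-only ("disputed") targets are suspected artifacts. The package
implements the quantitative arguments that settle such a dispute from the
data alone: if the disputed targets are real but weakly bound, they should
(i) sit at the bottom of study A's enrichment ranking, (ii) still score
above chance on study B's own tracks, and (iii) show a genomic-position
bias (toward intergenic promoters) that random artifacts would not have.

## Mode-anchored null estimation

Per-probe signals are modelled as null noise plus non-negative enrichment.
Enrichment only inflates the right tail, so the signal distribution below
its mode is taken as the left half of a normal null.

- **Mode.** Gaussian KDE evaluated by linear binning on a 2,048-point
  uniform grid spanning the data range, smoothed with bandwidth
  `h = 0.9 * min(sd, IQR/1.349) * n^(-1/7)`; the argmax is snapped to the
  nearest observed value (ties toward the smaller signal). Two deliberate
  choices here:
  - the n^(−1/7) rate rather than a density-oriented n^(−1/5) rule
    (Silverman). Argmax estimation is a harder problem than density
    estimation and needs heavier smoothing; with Silverman's rule the mode
    estimate's spread on 2×10⁵-probe normal data is ≈0.08 σ, versus
    ≈0.03 σ at the n^(−1/7) rate. Silverman remains available via
    `bandwidth="silverman"`, and a histogram variant (Freedman–Diaconis,
    Scott fallback when the IQR is zero) via `method="hist"`.
  - binned evaluation rather than exact pairwise KDE: O(n + grid) instead
    of O(n·grid), identical to within grid resolution (≲0.01 σ for
    typical ranges).
  - snapping to an observed value keeps the mode inside the signal range
    and makes the "at or below the mode" subset robust to floating-point
    placement of grid centres for discrete data.
- **Spread.** `sigma² = mean over {v ≤ mode} of (v − mode)²` — the
  population (divide-by-n) half-normal moment plug-in. Values exactly at
  the mode are included so the subset cannot be empty for discrete data.
  For a symmetric null this estimates the full null sd; right-tail
  contamination of a few percent moves it by far less than its sampling
  error (tested property: ≤5% contamination beyond μ+3σ shifts mode and
  sigma by ≤10%).
- **z-scores.** `(value − mode)/sigma` per probe. Both estimators are
  exactly affine-equivariant, so z-tracks are invariant under linear
  rescaling of the raw signal — the property that makes z-scores a
  cross-study dynamic-range measure despite arbitrary signal units.

Degenerate inputs (constant vectors, <10 values, zero sub-modal spread)
raise typed errors rather than returning numbers.

## Target calling and arbitration

Probes with z ≥ threshold (default 3, the conventional noise boundary)
whose midpoints lie within `merge_distance` (default 500 bp, the
sonication-fragment scale) of the previous qualifying probe form one
region; the region's single representative is its maximum-z probe,
leftmost on exact ties. This is deliberate local-maximum suppression: a
high-scoring probe adjacent to a higher one is the same binding event.

Arbitration matches each study-A peak to the nearest study-B peak
(peak-to-peak distance, `searchsorted` on sorted B peaks, leftmost on
ties); matches within `tolerance` (default 500 bp — the studies' probe
grids differ, so exact coordinates cannot agree) are "matched", the rest
"disputed". Named targets (e.g. in repetitive sequence) can be excluded
up front and are counted in neither set. A B target may serve several A
targets; the A side is always partitioned exactly.

**Context classes.** A peak position inside any gene interval is genic
(strand ignored); otherwise intergenic, with the sub-class
`intergenic_convergent` when the left flanking gene is on `+` and the
right on `−` (both 3′ ends face the gap — such gaps cannot hold a
canonical promoter for either flanking gene, making binding there
non-canonical). Classification uses only the peak probe midpoint.

**Intergenic enrichment.** With genic fraction g (length of the
strand-ignored union of genes over genome length), the number of disputed
targets at intergenic peaks is tested against Binomial(n, 1−g), upper
tail, by direct summation of log-pmf terms (`gammaln` + `logsumexp`) —
exact to ~1e-14 relative for n in the hundreds. One-sided because the
scientific claim is directional (more intergenic than chance); a
two-sided variant (doubled smaller tail) is available. At the printed
field-scale inputs (15 intergenic of 46 targets, 12% intergenic genome)
this exact tail is 2.02e-4.

**Rank analysis.** Targets sorted ascending by peak z (position breaks
ties); the count of disputed names among the bottom k (default: the
bottom tertile) quantifies "disputed targets are the weakly bound ones".

## Concordance and the disputed-vs-random test

Replicate agreement is the Spearman rank correlation of paired z-scores
on a shared probe grid (tracks on different grids are refused rather than
silently interpolated). Dynamic range is summarised as the fraction of
probes with z strictly below a threshold.

The disputed-vs-random Mann–Whitney test takes sample A as the z-score at
the nearest probe to each disputed-target coordinate (nearest-midpoint,
leftmost on ties — the mapping needed because probe grids differ between
studies) and sample B as z at `n_random` (default 1,000) probes drawn
uniformly without replacement with a mandatory seed; a single draw, no
averaging, so the result is bit-reproducible. The U statistic uses
midranks. For tie-free pooled samples of ≤14 the p-value is exact by
enumerating all C(n, n_a) labelings (≤3,432); larger samples use the
normal approximation with tie correction and 0.5 continuity correction,
whose error at the sizes involved (tens vs 1,000) is far below any
decision threshold. The alternative is one-sided "disputed greater",
matching the directional claim.

## qPCR occupancy

Within one sample, relative quantity of target vs control amplicon is
`E^(Ct_control − Ct_target)` with amplification efficiency E ∈ (1, 2]
(default 2.0, perfect doubling; per-primer-pair overrides accepted). Fold
enrichment is IP relative quantity over input relative quantity;
occupancy units subtract a background fold enrichment — by default the
constant 1.0 (an unenriched region), optionally the per-region mean fold
enrichment of an untagged-strain table. Subtraction order follows
normalisation, and negative occupancies are reported and flagged, not
clipped. Replicate summaries use the sample (n−1) standard deviation.
Conditions are compared with the pooled-variance Student t-test, one
tailed, df = n_a + n_b − 2 (Welch available); at n = 3 per group the
pooled test is the conventional reading of a one-tailed t-test on
biological replicates.

## The synthetic generator

The generator emulates exactly the contrasts the analysis must detect; it
is specified, not fitted.

- **Geometry.** 500 kb genome, 40 genes laid out left-to-right with
  random lengths (mean 10 kb) and random gaps ≥1 kb (sequential layout
  reaches genic fractions ~75–85%, which rejection placement cannot), 200
  bp probe spacing (2,500 probes per track, ≥90% of them null), 30 sites.
- **Sites** sit on study-A probe midpoints (so amplitude→peak-z is exactly
  analyzable), at least 2 kb apart, with a configured intergenic fraction
  (default 0.33, the field-typical share) realised to ±1 site, and
  amplitudes uniform in 3–15 null sd — weak sites that only a good study
  calls, through strong sites every study calls.
- **Signal.** Probe value = null_mean + baseline + attenuation·enrichment
  + replicate noise (+ study-B extra noise), with a triangular peak of
  half-width 250 bp (sonication-overlap geometry; linear decay keeps the
  peak-probe amplitude exact). The per-probe baseline Normal(0, null_sd)
  is drawn once per study and shared between its replicates: it models
  probe-affinity effects, and it is what gives replicate Spearman ≈0.9
  for mostly-null tracks — with purely independent noise, replicate
  correlation would be ≈0 and the reproducibility contrast could not be
  expressed at all. Study B's grid is offset half a probe spacing, its
  enrichment is multiplied by 0.4 and each replicate gets 1 null-sd of
  extra noise: defaults chosen so the A-vs-B Spearman contrast is
  qualitatively like a strong study against a weak one (≈0.92 vs ≈0.48),
  not calibrated to any particular printed pair.
- **qPCR.** Four regions spread across the site-amplitude ranking plus an
  unenriched control region; true fold enrichment 1 + amplitude; heat
  shock multiplies excess enrichment by 3; Ct values constructed so the
  noiseless table inverts exactly to FE − 1, then Gaussian Ct noise
  (sd 0.1 cycles) on every Ct.
- **Seeding.** One master seed spawns independent per-stage
  `SeedSequence`s (genome, tracks, qPCR), so stages regenerate
  independently and every emitted file is bit-reproducible.

What the generator does *not* model — and hence what passing tests do not
show about real arrays: dye bias and spatial artifacts, cross-
hybridisation, repetitive sequence, non-Gaussian or skewed null noise
(the mode-anchored fit assumes only sub-modal normality, which the
generator satisfies by construction), probe GC effects, and input-DNA
coverage bias.

## Numerical and design notes

- Internal coordinates are 0-based half-open everywhere; GFF3 (1-based
  inclusive) converts at the I/O boundary. Tracks are single-sequence;
  multi-sequence files split into per-sequence tracks.
- NaN probe values are dropped at load with a logged count; the null fit
  and all rank statistics are defined on observed values only.
- Pipeline target calling uses the probe-wise mean of the replicate
  z-tracks per study (replicates share a grid within a study); study-B
  calls can instead be supplied as a published table.
- All p-values are reported raw; the report states explicitly that no
  multiple-testing correction is applied.
- The pipeline writes deterministic outputs (no timestamps; fixed float
  formatting; JSON with sorted keys) so that reruns are byte-identical.
- Problem sizes in the test suite (2,500-probe tracks, 20-seed contrast
  batches, 100–200-seed calibration loops) are the package's desk-scale
  defaults: large enough that every qualitative contrast is stable across
  seeds, small enough that the whole suite runs in well under a minute.

## Known limitations

- The mode/sigma estimators assume a unimodal null; strongly bimodal
  backgrounds (e.g. copy-number structure) would need a mixture model,
  which is out of scope.
- Context classification uses peak midpoints only; a region straddling a
  gene boundary is classified by its single peak probe.
- The exact Mann–Whitney branch requires tie-free data; heavily rounded
  small samples fall back to the approximation.
- qPCR efficiency is taken as given (default 2.0); standard-curve
  estimation is not implemented.
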