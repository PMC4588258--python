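# Methods

## The analysis

All analyses operate on an integer OTU count table (samples × OTUs) with
per-sample metadata: donor (A/B/C/pool), vessel, day (day 0 = fecal
inoculum), and sample class (fecal or reactor).

**Rarefaction.** Sequencing depth varies between samples, so within-sample
metrics are computed on rarefied counts: each sample is subsampled without
replacement (multivariate hypergeometric) to a fixed depth. Alpha metrics
use 100 independent subsamples at depth 10,000 and report mean ± SD (SD is
0 by convention at one iteration); distance matrices use a single
subsample at the same depth, and core presence is evaluated on that same
subsample so distances and cores describe the same data. Samples below the
depth are dropped with a warning rather than upsampled, keeping depths
comparable. An OTU counts as present when its subsampled count is ≥1.
A mouse-comparison preset runs the identical operations at depth 3,500.

**Alpha diversity.** Inverse Simpson 1/Σp², Shannon −Σp ln p (natural
log), observed richness, and Simpson evenness D/S_obs, with the evenness
denominator being per-subsample observed richness (all three panel metrics
describe the same subsampled vector).

**Beta diversity.** Bray-Curtis on untransformed counts and Sorenson =
Bray-Curtis on binarized vectors. ANOSIM uses mid-ranks and
R = (r̄_between − r̄_within)/(M/2), M = n(n−1)/2. PERMANOVA uses the
distance (Gower) formulation — SS_total = (1/N)Σ_{i<j} d²_ij, SS_within
summed per group with 1/n_g — which avoids explicit centroids and is exact
for non-Euclidean dissimilarities. Permutation p-values use the
(1+b)/(1+m) estimator with the observed statistic included, so p is never
0 and its floor at 999 permutations is 0.001; an exhaustive mode
enumerates every distinct label arrangement (p = hit fraction of the
enumeration) and is feasible for n ≲ 9. Label shuffles are global (no
strata). NMDS minimizes Kruskal stress-1 by SMACOF with isotonic
regression (scikit-learn), best of 20 random restarts by default, seed
logged.

**Stability.** A vessel's curve is the mean similarity (1 − Bray-Curtis)
between each sampled day and every other sampled day. Slopes are OLS fits
over a centered three-point window (equal to the endpoint secant for
evenly spaced days). The stabilization day is the center of the first
window whose slope turns non-positive after at least two positive-slope
windows; zero counts as non-positive, and all crossings are recorded.
Day-1 (pre-flow) samples are included in curves by default; the day range
is configurable. Interval similarity pools all within-vessel day pairs at
each gap inside a window across vessels; transitioning (days 2–7) and
stable (days 8–13) windows are compared per gap with an equal-variance
unpaired t test (Welch available). The technical baseline is the mean ± SD
similarity over designated replicate-sequencing pairs.

**Cores.** An OTU is in a vessel's individual core if present on at least
⌈0.9 × n⌉ of the n sampled days in days 8–21 (ceiling, because the
threshold is a lower bound; missing days shrink the denominator). Fecal
type cores intersect the individual cores of a donor's replicates (the
pool's six replicates count as one fecal type); the all-MBRA core
intersects the fecal-type cores. Nesting is asserted on every run.
Accounting reports, per sample, the fraction of observed OTUs and of
sequences inside a core. The fecal-abundant-absent set contains OTUs at
≥0.5 % relative abundance in at least one inoculum and absent from every
individual core.

**Trajectories.** Per vessel, each OTU present in the donor's inoculum is
classified in precedence order: *lost* if absent from every reactor day or
if its maximum relative abundance over the early (days 3–4) and stable
(days 8–21) windows is more than 5-fold below the inoculum; *persistent*
if its stable-window mean is within 3-fold of the inoculum; *increased*
otherwise. Fold changes use a pseudocount of 0.1/depth. The early window
starts at day 3 because day 1 is pre-flow (it still carries the whole
non-growing inoculum — amplicon sequencing cannot distinguish live from
dead cells) and day 2 is only ~3 reactor turnovers in, too early for
washout to register as a 5-fold relative drop regardless of the community;
by day 3 (≥6 turnovers, e⁻⁶ ≈ 1/400 absolute retention) it always can. The
pseudocount is a tenth of a read rather than a full read because a
one-read pseudocount makes a >5-fold drop arithmetically impossible for
OTUs at the one-read detection limit. Both choices are configurable.
Heatmap matrices bin counts into log2 classes (0, [1,2), [2,4), …, top bin
saturating at ≥256 by default, ≥1024 selectable).

## The simulator

`synthetic_data.simulate_study` emulates the downstream product of a
multi-donor MBRA experiment. Defaults describe the study design the
analyses assume: 3 donors × 3 replicate reactors plus a pooled inoculum
(equal-mass mixture of the three donors) × 6 reactors, 21 daily samples
per vessel plus one inoculum sample per donor (319 samples), 10,000 reads
per sample, 15-ml vessels at 8-h retention.

Latent dynamics per vessel, daily steps (sampling is daily, so a
discrete-time update at the two governing rates — dilution and logistic
growth — suffices):

* A universe of 220 OTUs; each donor carries a random 90 % of it with
  lognormal(σ=1.5) fecal abundances (uneven, fecal-like evenness).
* A universe-level "growable" set (28 % of OTUs — growability is a
  property of the organism under the culture conditions, which is also
  what makes donor cores overlap); a donor's growers are the growable OTUs
  it carries (~15–25 % of its fecal OTUs persist, the rest wash out).
* **Day 1** is the 16-h pre-flow equilibration: growers take 16 h of
  logistic outgrowth, non-growers are preserved — the transient in which
  the sample contains both growing and never-growing members.
* **From day 2**, non-growers decay by e^(−24/retention) = e⁻³ per day
  (pure washout; ~21 turnovers by day 8 puts any non-grower far below one
  read), while growers take an exact logistic step toward a per-OTU
  carrying capacity, multiplied by mean-one lognormal noise, then the
  community is renormalized.
* **Capacities are bimodal**: "core" growers (80 % of a donor's growers)
  carry a floor of 0.008 relative abundance (≥80 expected reads — present
  every day), the rest sit at 5 × 10⁻⁵ (~0.5 expected reads — present well
  under 90 % of days). The planted core is therefore exactly the
  prevalence core the extractor should find.
* **Rates** are solved per OTU from the continuous-logistic travel time so
  every grower reaches 80 % of capacity by the planted stabilization day
  τ (default 8), clamped to [0.35, 4]/day (the floor keeps the restoring
  force at capacity stronger than the noise; near-capacity OTUs have
  negligible travel, so it does not advance stabilization) and jittered by
  a gamma multiplier (shape 100). Replicates share the donor's fecal
  vector, grower set, capacities, and rates.
* **Noise** has two parts, both in log space and mean-corrected so
  renormalization exerts no systematic pressure: an iid day-to-day
  component (σ = 0.10) and a mean-reverting per-vessel walk
  (AR(1), ρ = 0.85, innovation σ = 0.07). The walk is what makes
  replicate reactors diverge while single reactors stay self-similar
  day-to-day; a pure iid noise would make between-replicate pairs
  statistically identical to within-vessel day pairs and the observed
  within > between-replicates similarity ordering could not arise. Its
  mean reversion bounds excursions so core OTUs do not wander below
  detection.
* **Sequencing** is a multinomial draw per sample; re-drawing from one
  latent state emulates technical replicates.

The noise and rate defaults were calibrated, once, on a τ ∈ {6, 8, 10}
grid of 50 studies each so that the generator meets its qualitative design
goals simultaneously — median detected inflection within one day of τ
(7/8/9), exact planted-core recovery ≥99 %, planted non-growers classified
lost ≥99 % — and then frozen. They are design constants of the generator,
not fitted quantities.

**What the simulator does and does not emulate.** It reproduces the
washout/outgrowth structure, the replicate-variation hierarchy, donor
distinctness, fecal-to-reactor richness loss, stabilization timing, and
sequencing noise. It does not model cross-feeding, pH or metabolite
dynamics, spatial structure, primer/extraction bias, chimeras, or
day-to-day depth variation (every sample has exactly the configured
depth); taxonomy sidecars are synthetic labels for exercising display
logic, not phylogeny. Passing recovery tests therefore shows the analyses
are correct under the model's assumptions — clean washout kinetics and
capacity-structured growers — not that real cultures satisfy them.
Quantitatively, its technical-replicate baseline (~0.96) is tighter than
wet-lab resequencing (which adds extraction/PCR variation), and its stable
day-to-day similarity (~0.89) is correspondingly high; the *ordering*
technical > within-vessel > between-replicates > between-donors is the
emulated feature, not the absolute levels.

## Numerical choices

* Permutation p-values: (1+b)/(1+m); ties in ANOSIM broken by mid-ranks;
  statistic comparisons use a 10⁻¹² tolerance so exact ties count as hits.
* Exhaustive permutation mode deduplicates label arrangements, so p is the
  exact enumeration fraction (minimum 1/#arrangements, reached only by the
  observed labeling and its group-preserving images).
* Window slopes are NaN where a full window does not fit; inflection
  scanning skips NaNs and requires a ≥2-window positive run.
* Subsampling, simulation, and permutation seeds all derive from one
  master seed through a fixed stage table (`pipeline.STAGES`); reruns are
  byte-identical, and output headers echo the full configuration.
* Degenerate inputs raise typed errors (`FormatError`, `MetadataError`,
  `InsufficientDataError`) rather than returning partial results; samples
  with zero totals are skipped with warnings where the operation allows.

## Problem sizes

Tests and the acceptance script run the default 319-sample study design
end to end; recovery experiments use 25–50 independent studies per
condition, enough for stable medians of the per-vessel inflection
distribution (n = 375–750 vessels) while keeping the suite inside a few
minutes on one core. NMDS on the full study uses 20 random restarts;
reduced restart counts are used in smoke tests only.

## Known limitations

* The inflection rule detects the first noise crossing of the window
  slope; on very noisy curves this is an early-biased estimator, which is
  why recovery is validated as a median over many vessels.
* ANOSIM/PERMANOVA treat daily samples within a reactor as exchangeable
  units under permutation; autocorrelated time series violate this, so
  their p-values on reactor time series are descriptive (as is standard
  for such designs), and the package reports unadjusted p per comparison.
* Exhaustive permutation enumeration is O(n!) and intended for n ≤ 9.
* `read_shared` loads the table densely; tables far larger than amplicon
  studies (~10⁵ samples) would need a sparse path.
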