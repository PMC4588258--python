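# mbratools

Community-dynamics analysis for **minibioreactor arrays (MBRAs)** —
continuous-flow (chemostat-like) cultures of human fecal microbial
communities — together with a ground-truthed simulator of such studies.

MBRAs are strips of small (15 ml) anaerobic bioreactors run under continuous
flow at an 8-h retention time, inoculated from human fecal samples and
sampled daily while 16S rRNA V4 amplicon sequencing tracks the community.
Starting from OTU count tables (mothur `shared` format), this package
answers the questions such an experiment poses:

* **Alpha diversity** — inverse Simpson $D = 1/\sum_i p_i^2$, Shannon
  $H = -\sum_i p_i \ln p_i$, observed richness $S_{obs}$, and Simpson
  evenness $E = D/S_{obs}$, reported as mean ± SD over iterated rarefaction
  (default 100 subsamples of 10,000 reads).
* **Beta diversity** — Bray-Curtis $d = \sum_i |x_i-y_i| / \sum_i (x_i+y_i)$
  on untransformed counts and Sorenson (its presence/absence analog) after a
  single rarefaction; NMDS ordination (Kruskal stress-1); ANOSIM and
  PERMANOVA permutation tests (999 permutations, mid-ranks, distance
  formulation) for donor separation.
* **Stability** — per-vessel curves of mean similarity between each day and
  all other days, three-point sliding-window OLS slopes, and the
  stabilization (inflection) day where the slope first turns non-positive;
  similarity at increasing day gaps in transitioning (days 2–7) vs stable
  (days 8–13) windows compared by unpaired t test; technical-replicate
  similarity baselines.
* **Core communities** — nested prevalence cores (OTUs present in ≥90 % of
  a vessel's days 8–21 → *individual core*; intersected across replicates →
  *fecal type core*; across donors → *all-MBRA core*) with per-sample
  OTU- and sequence-fraction accounting, plus the set of fecally abundant
  (≥0.5 %) OTUs absent from every core.
* **OTU trajectories** — classification of each fecal OTU per vessel as
  *lost* (>5-fold drop or disappearance), *persistent* (stable-window mean
  within 3-fold of the inoculum), or *increased*, plus log2-binned count
  matrices for heatmap rendering.
* **Simulation** — `synthetic_data` generates complete studies (3 donors ×
  3 replicates + pooled inoculum × 6, 21 days) from a washout/outgrowth
  model: non-growers decay at the dilution rate $e^{-24h/\tau_R}$ per day,
  growers follow an exact logistic toward planted carrying capacities, and
  sequencing is multinomial. Grower sets, planted cores, and the true
  stabilization day are recorded as ground truth.

## Worked example

```bash
python analysis/01_simulate_study.py
python analysis/04_structure_experiment.py
```

prints

```
simulated 319 samples (3 donors x 3 + pool x 6, 21 days, depth 10000)
planted stabilization day tau = 8
...
mean Bray-Curtis similarity (days 8-21):
  within vessel       0.889
  between replicates  0.837
  between donor types 0.446
  ordering holds: True
fecal richness 200 vs stable reactor richness 51 (3.9-fold reduction)
technical-replicate similarity 0.965 vs stable day-to-day 0.888
```

Reading this: single reactors are more self-similar day-to-day (0.889) than
replicate reactors are to each other (0.837), and communities from different
donors are far more distinct (0.446) — the replicate-variation hierarchy
such cultures show. Cultivation keeps a subset of the inoculum (richness
drops ~4-fold), and repeated sequencing of the same sample (0.965) is more
similar than biological day-to-day variation (0.888), so the day-to-day
variation is real, not sequencing noise.

`analysis/02_run_pipeline.py` runs the complete pipeline on the simulated
study (every table listed above, under `results/full/`), and
`analysis/03_recovery_experiment.py` measures ground-truth recovery over
150 simulated studies:

```
tau=6: median detected inflection 7 (n=750), exact core recovery 99.7 %, non-growers lost 99.2 %
tau=8: median detected inflection 8 (n=750), exact core recovery 99.5 %, non-growers lost 99.0 %
tau=10: median detected inflection 9 (n=750), exact core recovery 99.6 %, non-growers lost 98.8 %
```

The same operations are available as a CLI
(`mbratools simulate|alpha|beta|stability|cores|dynamics|full`), e.g.

```bash
mbratools simulate --out study --seed 1
mbratools full --shared study/study.shared --metadata study/study.metadata.tsv \
    --taxonomy study/study.cons.taxonomy --out out --seed 1
```

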