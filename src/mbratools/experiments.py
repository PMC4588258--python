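"""Ground-truth recovery and structural experiments on simulated studies.

These experiments quantify whether the analysis stack recovers what the
continuous-flow simulator planted: the stabilization day from similarity
curves, the prevalence cores from planted capacity structure, and washout
("lost") classifications for planted non-growers.  They are the package's
validation surface and back the numbered analysis drivers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import beta_diversity, core_communities, otu_dynamics, stability
from . import synthetic_data as sd
from .otu_io import subsample


@dataclass
class RecoveryResult:
    """Aggregated parameter-recovery outcomes over simulator seeds."""

    tau: int
    n_seeds: int
    inflection_days: list[int] = field(default_factory=list)
    core_exact: int = 0
    core_total: int = 0
    core_eligible_exact: int = 0
    core_eligible: int = 0
    lost_rates: list[float] = field(default_factory=list)
    individual_sizes: list[int] = field(default_factory=list)
    fecal_type_sizes: list[int] = field(default_factory=list)
    all_mbra_sizes: list[int] = field(default_factory=list)
    individual_seq_fractions: list[float] = field(default_factory=list)

    @property
    def median_inflection(self) -> float:
        return float(np.median(self.inflection_days))

    @property
    def core_exact_rate(self) -> float:
        return self.core_exact / max(self.core_total, 1)

    @property
    def mean_lost_rate(self) -> float:
        return float(np.mean(self.lost_rates))


def _core_eligible(sub, vessel, planted, prevalence=0.90, day_range=range(8, 22)):
    """True when realized prevalences match the planted design exactly.

    Planted core OTUs must reach the required day count and every other OTU
    must miss it; under that condition the prevalence extractor's output is
    determined and must equal the planted set.
    """
    vt = sub.filter(vessel=vessel, days=list(day_range))
    presence = (vt.counts > 0).sum(axis=0)
    required = math.ceil(prevalence * vt.n_samples)
    return all(presence[o] >= required for o in planted) and all(
        presence[o] < required for o in vt.otu_ids if o not in planted
    )


def run_recovery(
    n_seeds: int = 50,
    tau: int = 8,
    base_seed: int = 0,
    depth: int = 10_000,
    sim_overrides: dict | None = None,
) -> RecoveryResult:
    """Simulate ``n_seeds`` studies and measure ground-truth recovery.

    Per study: per-vessel inflection days from Bray-Curtis similarity
    curves, exact planted-core recovery of the prevalence extractor, and
    the fraction of fecally detected planted non-growers classified lost.
    """
    res = RecoveryResult(tau=tau, n_seeds=n_seeds)
    overrides = sim_overrides or {}
    for k in range(n_seeds):
        seed = (base_seed + k) % (2**31)
        study = sd.simulate_study(sd.SimConfig(seed=seed, tau=tau, **overrides))
        meta = study.table.metadata
        dm = beta_diversity.distance_matrix(
            study.table, "bray_curtis", depth, seed=(seed + 10_007) % (2**31)
        )
        for vessel, day_map in sorted(
            stability.vessel_day_samples(meta).items()
        ):
            curve = stability.similarity_curve(dm, day_map, vessel)
            stability.window_slopes(curve)
            day = stability.inflection_day(curve)
            if day is not None:
                res.inflection_days.append(day)

        sub = subsample(study.table, depth, seed=(seed + 20_011) % (2**31))
        cores = core_communities.extract_cores(sub)
        for vessel, core_res in cores["individual"].items():
            donor = meta.loc[meta["vessel"] == vessel, "donor"].iloc[0]
            planted = frozenset(study.truth.planted_core[donor])
            res.core_total += 1
            exact = core_res.members == planted
            res.core_exact += exact
            if _core_eligible(sub, vessel, planted):
                res.core_eligible += 1
                res.core_eligible_exact += exact
            res.individual_sizes.append(len(core_res.members))
            res.individual_seq_fractions.append(
                float(core_res.fractions["fraction_of_sequences"].mean())
            )
        res.fecal_type_sizes.extend(
            len(r.members) for r in cores["fecal_type"].values()
        )
        res.all_mbra_sizes.append(len(cores["all_mbra"].members))

        fecal = meta[meta["sample_class"] == "fecal"]
        for donor in fecal["donor"]:
            if donor == "pool":
                continue
            fecal_id = fecal.index[fecal["donor"] == donor][0]
            vessels = meta.loc[
                (meta["donor"] == donor) & (meta["sample_class"] == "reactor"),
                "vessel",
            ].unique()
            for vessel in vessels:
                cls = otu_dynamics.classify_trajectories(
                    study.table, vessel, fecal_id
                ).set_index("otu")
                nong = [
                    o for o in study.truth.non_growers
                    if o in cls.index and cls.loc[o, "fecal_abundance"] > 0
                ]
                if nong:
                    res.lost_rates.append(
                        float(np.mean([cls.loc[o, "class"] == "lost"
                                       for o in nong]))
                    )
    return res


@dataclass
class StructureResult:
    """Structural summary of one simulated study."""

    partition_means: dict[str, float]
    fecal_richness: float
    reactor_richness: float
    technical_similarity: float
    stable_within_similarity: float
    anosim_table: pd.DataFrame


def run_structure(
    seed: int = 0, depth: int = 10_000, permutations: int = 999
) -> StructureResult:
    """Default-size study: similarity partitioning, richness, baselines."""
    study = sd.simulate_study(sd.SimConfig(seed=seed))
    table = study.table
    meta = table.metadata
    dm = beta_diversity.distance_matrix(
        table, "bray_curtis", depth, seed=(seed + 40_009) % (2**31)
    )
    part = beta_diversity.similarity_partition(dm, meta)
    means = part.groupby("comparison")["mean_similarity"].mean().to_dict()

    fecal = table.filter(sample_class="fecal")
    stable = table.filter(sample_class="reactor", days=range(8, 22))
    fecal_rich = float((fecal.counts > 0).sum(axis=1).mean())
    reactor_rich = float((stable.counts > 0).sum(axis=1).mean())

    # technical replicates: resequence three stable latent states
    rng = np.random.default_rng((seed + 50_021) % (2**31))
    sims = []
    for vessel in list(study.latent)[:3]:
        latent = study.latent[vessel][10]
        x = sd.sequence_sample(latent, depth, rng)
        y = sd.sequence_sample(latent, depth, rng)
        sims.append(1.0 - beta_diversity.bray_curtis(x, y))
    vm = stability.vessel_day_samples(meta)
    stable_iv = stability.interval_similarity(dm, vm, range(8, 22), "stable")
    stable_mean = float(np.concatenate(list(stable_iv.values.values())).mean())

    from .pipeline import AnalysisConfig, group_comparisons

    cfg = AnalysisConfig(permutations=permutations, master_seed=seed)
    anosim_table = group_comparisons(dm, meta, cfg, (seed + 60_013) % (2**31))
    return StructureResult(
        partition_means=means,
        fecal_richness=fecal_rich,
        reactor_richness=reactor_rich,
        technical_similarity=float(np.mean(sims)),
        stable_within_similarity=stable_mean,
        anosim_table=anosim_table,
    )
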