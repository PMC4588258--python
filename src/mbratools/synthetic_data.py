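"""Ground-truthed synthetic MBRA studies.

Generates the downstream product of a multi-donor minibioreactor experiment
— per-sample OTU count vectors for fecal inocula (day 0) and daily reactor
samples (days 1-21) — from a continuous-flow community model:

* Fecal communities are lognormal-abundance OTU vectors on a donor-specific
  support; the pooled inoculum is the equal-mass mixture of the donors.
* Under flow, non-growing OTUs wash out exponentially at the dilution rate
  (24 h / retention time volume turnovers per day; e^-3 per day at the 8-h
  default, ~21 turnovers in 7 days).
* Growing OTUs follow an exact discrete logistic toward a per-OTU carrying
  capacity, with rates solved so every grower saturates by the planted
  stabilization day tau, times multiplicative lognormal noise (an iid
  day-to-day component plus a mean-reverting per-vessel walk that makes
  replicate reactors diverge while single reactors stay self-similar
  day-to-day).
* Sequencing is a multinomial draw of `depth` reads per sample; repeated
  draws from one latent state emulate technical replicates.

Grower capacities are bimodal by construction: "core" growers carry a
capacity floor that keeps them above ~50 expected reads at depth 10,000
(present every day), while "rare" growers sit near 0.5 expected reads
(present well under 90 % of days), so the planted per-donor core is exactly
the prevalence-core the analyses should recover.  All ground truth (grower
sets, planted cores, tau) is recorded alongside the count table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .otu_io import OtuTable, attach_metadata

DONOR_NAMES = ("A", "B", "C", "D", "E", "F", "G", "H")


@dataclass
class ReactorConfig:
    """Physical operating parameters of one minibioreactor."""

    operating_volume_ml: float = 15.0
    retention_time_h: float = 8.0
    days: int = 21
    depth: int = 10_000

    def __post_init__(self) -> None:
        if self.operating_volume_ml <= 0 or self.retention_time_h <= 0:
            raise ValueError("volume and retention time must be positive")
        if self.days < 1 or self.depth < 1:
            raise ValueError("days and depth must be >= 1")

    @property
    def flow_rate_ml_per_h(self) -> float:
        """flow rate = operating volume / retention time (1.875 ml/h default)."""
        return self.operating_volume_ml / self.retention_time_h

    @property
    def dilution_per_day(self) -> float:
        """Volume turnovers per day = 24 / retention time (3/day default)."""
        return 24.0 / self.retention_time_h


@dataclass
class SimConfig:
    """Statistical parameters of a synthetic multi-donor study."""

    n_donors: int = 3
    replicates_per_donor: int = 3
    pool_replicates: int = 6
    n_otus: int = 220
    support_fraction: float = 0.9  # fraction of the OTU universe each donor carries
    fecal_sigma: float = 1.5  # sigma of log fecal abundances (unevenness)
    grower_fraction: float = 0.28  # fraction of the universe able to grow in culture
    core_fraction: float = 0.8  # fraction of a donor's growers given core capacity
    core_capacity_floor: float = 0.008  # min relative capacity of a core grower
    rare_capacity: float = 5e-5  # relative capacity of a rare grower
    capacity_sigma: float = 1.0  # sigma of log capacity weights
    saturation_target: float = 0.80  # fraction of capacity reached by day tau
    rate_min: float = 0.35  # floor on logistic rates (noise-restoring force)
    rate_jitter_shape: float = 100.0  # gamma shape of per-OTU rate multipliers
    fluctuation_sigma: float = 0.10  # iid day-to-day lognormal noise (log scale)
    ou_sigma: float = 0.07  # innovation sigma of the replicate-divergence OU noise
    ou_rho: float = 0.85  # day-to-day autocorrelation of the OU noise
    tau: int = 8  # planted stabilization day
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("support_fraction", "grower_fraction", "core_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.fecal_sigma < 0 or self.fluctuation_sigma < 0 or self.ou_sigma < 0:
            raise ValueError("sigmas must be non-negative")
        if not 0.0 <= self.ou_rho < 1.0:
            raise ValueError("ou_rho must lie in [0, 1)")
        if self.tau < 2:
            raise ValueError("tau must be >= 2")
        if self.n_donors > len(DONOR_NAMES):
            raise ValueError(f"at most {len(DONOR_NAMES)} donors supported")


@dataclass
class SimTruth:
    """Ground truth recorded with a synthetic study."""

    growers: set[str]  # universe-level growable OTUs
    non_growers: set[str]
    donor_growers: dict[str, set[str]]
    planted_core: dict[str, set[str]]  # per donor (shared by its replicates)
    tau: int
    seed: int

    def to_json(self, path, config: SimConfig | None = None) -> None:
        payload = {
            "growers": sorted(self.growers),
            "non_growers": sorted(self.non_growers),
            "donor_growers": {d: sorted(v) for d, v in self.donor_growers.items()},
            "planted_core": {d: sorted(v) for d, v in self.planted_core.items()},
            "tau": self.tau,
            "seed": self.seed,
        }
        if config is not None:
            payload["config"] = asdict(config)
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass
class SimStudy:
    """Synthetic OTU table bundled with its ground truth."""

    table: OtuTable
    truth: SimTruth
    latent: dict[str, np.ndarray] = field(default_factory=dict)  # vessel -> days x otus


def simulate_fecal(n_otus: int, sigma: float, rng) -> np.ndarray:
    """Relative-abundance vector with lognormal(0, sigma) abundances.

    ``sigma = 0`` gives a uniform community; large sigma gives the uneven,
    low-evenness profile typical of fecal samples.
    """
    if n_otus < 2:
        raise ValueError("need >= 2 OTUs")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(rng)
    x = np.exp(rng.normal(0.0, sigma, size=n_otus))
    return x / x.sum()


def saturation_rate(
    n0: float, capacity: float, tau: int, target: float = 0.80,
    rate_min: float = 0.35,
) -> float:
    """Logistic rate bringing n0 to ``target`` * capacity by day ``tau``.

    Solves the continuous-logistic travel time from n0 (at day 1) over
    tau - 1 days, so every grower — whatever its inoculum abundance —
    saturates on the same horizon and the community's systematic
    compositional change dies out near ``tau``.  Clamped to
    [``rate_min``, 4] per day: the floor keeps the restoring force of
    near-capacity OTUs stronger than the day-to-day fluctuation noise
    (their travel is negligible, so the floor does not advance
    stabilization).
    """
    if n0 <= 0 or capacity <= 0:
        raise ValueError("n0 and capacity must be positive")
    if not 0.5 < target < 1.0:
        raise ValueError("target must lie in (0.5, 1)")
    if tau < 2:
        raise ValueError("tau must be >= 2")
    odds = target / (1.0 - target)
    ratio = max((capacity - n0) / n0, 1e-3)
    r = np.log(odds * ratio) / (tau - 1)
    return float(np.clip(r, rate_min, 4.0))


def _logistic_step(n: np.ndarray, rate: np.ndarray, capacity: np.ndarray) -> np.ndarray:
    # Exact one-day solution of dn/dt = r n (1 - n/K): monotone, no overshoot.
    er = np.exp(rate)
    return capacity * n * er / (capacity + n * (er - 1.0))


def simulate_reactor(
    fecal: np.ndarray,
    grower_mask: np.ndarray,
    capacity: np.ndarray,
    rates: np.ndarray,
    reactor: ReactorConfig,
    sim: SimConfig,
    rng,
) -> np.ndarray:
    """Latent relative-abundance matrix, one row per day 1..days.

    Day 1 is the pre-flow sample after the 16-h equilibration: non-growers
    are preserved at their inoculum proportions (no washout yet) while
    growers have taken 16 h of logistic outgrowth — the transient burst in
    which the sample contains both the growing and the never-growing
    community members.  From day 2 non-growers decay by exp(-dilution) per
    day while growers take an exact logistic step toward capacity times
    lognormal fluctuation (iid + mean-reverting walk), with daily
    renormalization.
    """
    fecal = np.asarray(fecal, dtype=float)
    if not np.isclose(fecal.sum(), 1.0):
        raise ValueError("fecal abundances must sum to 1")
    if not grower_mask.any():
        # Pure washout: uniform decay cancels in renormalization, so the
        # relative composition stays frozen at the inoculum.
        import warnings

        warnings.warn("community has no growers; simulating pure washout")
    rng = np.random.default_rng(rng)
    n_days = reactor.days
    n_otus = len(fecal)
    washout = np.exp(-reactor.dilution_per_day)
    out = np.zeros((n_days, n_otus))
    g = grower_mask
    current = fecal.copy()
    if g.any():
        current[g] = _logistic_step(fecal[g], rates * (16.0 / 24.0), capacity)
        current = current / current.sum()
    out[0] = current
    walk = np.zeros(grower_mask.sum())  # mean-reverting per-vessel drift (log scale)
    for t in range(1, n_days):
        nxt = current * washout  # everything dilutes ...
        grown = _logistic_step(current[g], rates, capacity)  # ... growers regrow
        walk = sim.ou_rho * walk + rng.normal(0.0, sim.ou_sigma, size=walk.size)
        # log-mean correction keeps the noise mean-one so renormalization
        # exerts no systematic downward pressure on individual growers
        bias = 0.5 * (
            sim.fluctuation_sigma**2 + sim.ou_sigma**2 / (1.0 - sim.ou_rho**2)
        )
        noise = np.exp(
            rng.normal(0.0, sim.fluctuation_sigma, size=walk.size) + walk - bias
        )
        nxt[g] = grown * noise
        total = nxt.sum()
        if total <= 0:
            raise ValueError("degenerate community: zero total latent mass")
        current = nxt / total
        out[t] = current
    return out


def sequence_sample(latent: np.ndarray, depth: int, rng) -> np.ndarray:
    """Multinomial draw of ``depth`` reads from a latent abundance vector."""
    latent = np.asarray(latent, dtype=float)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if latent.ndim != 1 or (latent < 0).any() or not np.isclose(latent.sum(), 1.0):
        raise ValueError("latent abundances must be a probability vector")
    rng = np.random.default_rng(rng)
    return rng.multinomial(depth, latent / latent.sum())


_TAXA = [
    # (phylum, family, genus) pools for synthetic consensus lineages
    ("Firmicutes", "Lachnospiraceae", "Blautia"),
    ("Firmicutes", "Lachnospiraceae", "Roseburia"),
    ("Firmicutes", "Ruminococcaceae", "Faecalibacterium"),
    ("Firmicutes", "Ruminococcaceae", "Flavonifractor"),
    ("Firmicutes", "Clostridiaceae", "Clostridium"),
    ("Bacteroidetes", "Bacteroidaceae", "Bacteroides"),
    ("Bacteroidetes", "Porphyromonadaceae", "Parabacteroides"),
    ("Proteobacteria", "Enterobacteriaceae", "Escherichia"),
    ("Proteobacteria", "Desulfovibrionaceae", "Desulfovibrio"),
    ("Verrucomicrobia", "Verrucomicrobiaceae", "Akkermansia"),
    ("Actinobacteria", "Bifidobacteriaceae", "Bifidobacterium"),
]

_CLASS_ORDER = {
    "Firmicutes": ("Clostridia", "Clostridiales"),
    "Bacteroidetes": ("Bacteroidia", "Bacteroidales"),
    "Proteobacteria": ("Gammaproteobacteria", "Enterobacteriales"),
    "Verrucomicrobia": ("Verrucomicrobiae", "Verrucomicrobiales"),
    "Actinobacteria": ("Actinobacteria", "Bifidobacteriales"),
}


def simulate_taxonomy(otu_ids: list[str], rng, low_confidence_fraction: float = 0.2):
    """Synthetic consensus-taxonomy table for a simulated OTU universe.

    Lineages are drawn from a small pool of gut taxa; a fraction of OTUs
    get sub-80 % genus (and sometimes family) confidence to exercise the
    "unclassified" display rule.  Synthetic stand-in — not derived from any
    reference database.
    """
    from .otu_io import TaxonomyTable

    rng = np.random.default_rng(rng)
    tax = TaxonomyTable()
    for otu in otu_ids:
        phylum, family, genus = _TAXA[rng.integers(len(_TAXA))]
        klass, order = _CLASS_ORDER[phylum]
        confs = [100.0, 100.0, 100.0, 100.0, 100.0, 100.0]
        if rng.random() < low_confidence_fraction:
            confs[5] = float(rng.integers(30, 80))
            if rng.random() < 0.3:
                confs[4] = float(rng.integers(30, 80))
        tax.lineages[otu] = ["Bacteria", phylum, klass, order, family, genus]
        tax.confidences[otu] = confs
        tax.sizes[otu] = int(rng.integers(10, 10_000))
    return tax


def _donor_parameters(support: np.ndarray, growable: np.ndarray, sim: SimConfig, rng):
    """Capacities, rates and core membership for one donor's grower set."""
    growers = np.flatnonzero(support & growable)
    n_core = max(int(round(sim.core_fraction * len(growers))), 1)
    order = rng.permutation(len(growers))
    core_idx = growers[order[:n_core]]
    rare_idx = growers[order[n_core:]]
    capacity = np.zeros(len(growers))
    is_core = np.isin(growers, core_idx)
    weights = np.exp(rng.normal(0.0, sim.capacity_sigma, size=n_core))
    weights /= weights.sum()
    core_mass = 1.0 - len(rare_idx) * sim.rare_capacity
    floor_mass = n_core * sim.core_capacity_floor
    capacity[is_core] = sim.core_capacity_floor + weights * (core_mass - floor_mass)
    capacity[~is_core] = sim.rare_capacity
    return growers, set(core_idx.tolist()), capacity


def simulate_study(
    sim: SimConfig | None = None, reactor: ReactorConfig | None = None
) -> SimStudy:
    """Full synthetic study: fecal inocula plus all replicate reactor series.

    Replicates of one donor share the fecal community, grower assignment,
    capacities, and rates, and differ only in their fluctuation noise
    streams and sequencing draws.  The pooled inoculum is the equal-mass
    mixture of the donor fecal vectors.
    """
    sim = sim or SimConfig()
    reactor = reactor or ReactorConfig()
    rng = np.random.default_rng(sim.seed)
    n = sim.n_otus
    otu_ids = [f"Otu{i + 1:04d}" for i in range(n)]
    growable = np.zeros(n, dtype=bool)
    growable[rng.choice(n, size=max(int(round(sim.grower_fraction * n)), 1),
                        replace=False)] = True

    donors = list(DONOR_NAMES[: sim.n_donors])
    fecal_vectors: dict[str, np.ndarray] = {}
    supports: dict[str, np.ndarray] = {}
    for donor in donors:
        support = np.zeros(n, dtype=bool)
        support[rng.choice(n, size=int(round(sim.support_fraction * n)),
                           replace=False)] = True
        vec = np.zeros(n)
        vec[support] = simulate_fecal(int(support.sum()), sim.fecal_sigma, rng)
        supports[donor] = support
        fecal_vectors[donor] = vec
    if sim.pool_replicates > 0:
        pool_vec = np.mean([fecal_vectors[d] for d in donors], axis=0)
        fecal_vectors["pool"] = pool_vec / pool_vec.sum()
        supports["pool"] = pool_vec > 0
        donors = donors + ["pool"]

    replicate_counts = {
        d: (sim.pool_replicates if d == "pool" else sim.replicates_per_donor)
        for d in donors
    }

    rows: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    latent_store: dict[str, np.ndarray] = {}
    donor_growers: dict[str, set[str]] = {}
    planted_core: dict[str, set[str]] = {}
    for donor in donors:
        fecal_vec = fecal_vectors[donor]
        growers, core_set, capacity = _donor_parameters(
            supports[donor], growable, sim, rng
        )
        donor_growers[donor] = {otu_ids[i] for i in growers}
        planted_core[donor] = {otu_ids[i] for i in core_set}
        rates = np.array(
            [saturation_rate(max(fecal_vec[i], 1e-8), capacity[k], sim.tau,
                             sim.saturation_target, sim.rate_min)
             for k, i in enumerate(growers)]
        )
        rates *= rng.gamma(sim.rate_jitter_shape, 1.0 / sim.rate_jitter_shape,
                           size=rates.size)
        grower_mask = np.zeros(n, dtype=bool)
        grower_mask[growers] = True

        fecal_id = f"{donor}F"
        rows[fecal_id] = sequence_sample(fecal_vec, reactor.depth, rng)
        meta_rows.append(
            {"sample": fecal_id, "donor": donor, "vessel": fecal_id, "day": 0,
             "sample_class": "fecal"}
        )
        for rep in range(1, replicate_counts[donor] + 1):
            vessel = f"{donor}{rep}"
            latent = simulate_reactor(
                fecal_vec, grower_mask, capacity, rates, reactor, sim, rng
            )
            latent_store[vessel] = latent
            for day in range(1, reactor.days + 1):
                sid = f"{vessel}_d{day:02d}"
                rows[sid] = sequence_sample(latent[day - 1], reactor.depth, rng)
                meta_rows.append(
                    {"sample": sid, "donor": donor, "vessel": vessel, "day": day,
                     "sample_class": "reactor"}
                )

    counts = pd.DataFrame.from_dict(rows, orient="index", columns=otu_ids)
    counts.index.name = "sample"
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    table = attach_metadata(OtuTable(counts), metadata)
    grower_names = {otu_ids[i] for i in np.flatnonzero(growable)}
    truth = SimTruth(
        growers=grower_names,
        non_growers=set(otu_ids) - grower_names,
        donor_growers=donor_growers,
        planted_core=planted_core,
        tau=sim.tau,
        seed=sim.seed,
    )
    return SimStudy(table=table, truth=truth, latent=latent_store)
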