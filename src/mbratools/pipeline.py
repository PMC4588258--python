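"""Full-analysis orchestration with deterministic seeding.

``run_full`` chains every stage of the reactor-community analysis — iterated
alpha diversity, rarefied distance matrices, NMDS, ANOSIM/PERMANOVA donor
comparisons, similarity partitioning, per-vessel stability curves and
inflection detection, interval-similarity window comparison, nested core
extraction, taxonomy rollups, and trajectory classification — writing
TSV-first outputs plus a JSON manifest.  One master seed spawns per-stage
child seeds through a fixed stage table, so reruns under the same seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alpha_diversity, beta_diversity, core_communities, otu_dynamics
from . import otu_io, stability, synthetic_data
from .otu_io import OtuTable

# Fixed stage order for child-seed derivation; appending is safe, reordering
# would change every downstream seed.
STAGES = (
    "simulate",
    "alpha",
    "beta_bray_curtis",
    "beta_sorenson",
    "nmds_bray_curtis",
    "nmds_sorenson",
    "tests_bray_curtis",
    "tests_sorenson",
)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic child seed (< 2^31) for a named pipeline stage."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(int(master_seed), spawn_key=(idx,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class AnalysisConfig:
    """Every numeric constant of the analysis, echoed into output headers."""

    alpha_depth: int = 10_000
    beta_depth: int = 10_000
    alpha_iterations: int = 100
    permutations: int = 999
    prevalence: float = 0.90
    core_day_range: tuple[int, int] = (8, 21)
    transitioning_window: tuple[int, int] = (2, 7)
    stable_window: tuple[int, int] = (8, 13)
    comparison_days: tuple[int, int] = (2, 21)
    early_window: tuple[int, int] = (3, 4)  # >=6 turnovers in: washout visible, day 1-2 excluded
    lost_fold: float = 5.0
    persist_fold: float = 3.0
    fecal_abundance_threshold: float = 0.005
    nmds_restarts: int = 20
    nmds_dimensions: int = 2
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence <= 1:
            raise ValueError("prevalence must lie in (0, 1]")
        if self.permutations < 1 or self.alpha_iterations < 1:
            raise ValueError("permutations and iterations must be >= 1")
        if self.lost_fold <= 1 or self.persist_fold <= 1:
            raise ValueError("fold thresholds must exceed 1")

    @classmethod
    def mouse_mode(cls, **overrides) -> "AnalysisConfig":
        """Preset for the external-comparison workflow: depth 3,500."""
        defaults = dict(alpha_depth=3_500, beta_depth=3_500)
        defaults.update(overrides)
        return cls(**defaults)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def load_config(path) -> AnalysisConfig:
    """Read a ``key = value`` config file into an :class:`AnalysisConfig`."""
    fields = {f: t for f, t in AnalysisConfig.__dataclass_fields__.items()}
    kwargs: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            default = getattr(AnalysisConfig, key)
            if isinstance(default, tuple):
                parts = [int(v) for v in value.replace(",", " ").split()]
                kwargs[key] = tuple(parts)
            elif isinstance(default, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = int(value)
    return AnalysisConfig(**kwargs)


def _span(window: tuple[int, int]) -> range:
    return range(window[0], window[1] + 1)


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g",
                  lineterminator="\n")


def group_comparisons(
    dm: beta_diversity.DistanceMatrix,
    metadata: pd.DataFrame,
    config: AnalysisConfig,
    seed: int,
) -> pd.DataFrame:
    """ANOSIM + PERMANOVA for every donor pair on reactor samples."""
    days = set(_span(config.comparison_days))
    keep = [
        s for s in dm.ids
        if metadata.loc[s, "sample_class"] == "reactor"
        and int(metadata.loc[s, "day"]) in days
    ]
    donors = metadata.loc[keep, "donor"]
    records = []
    rng = np.random.default_rng(seed)
    for a, b in _donor_pairs(sorted(donors.unique())):
        ids = [s for s in keep if donors[s] in (a, b)]
        sub = dm.submatrix(ids)
        groups = donors[ids].to_numpy()
        for test in (beta_diversity.anosim, beta_diversity.permanova):
            child = int(rng.integers(0, 2**31 - 1))
            res = test(sub, groups, permutations=config.permutations, seed=child)
            records.append(
                {
                    "comparison": f"{a}-{b}",
                    "statistic": res.statistic_name,
                    "value": res.statistic,
                    "R2": res.r_squared if res.r_squared is not None else "",
                    "p": res.p_value,
                    "permutations": res.permutations,
                    "seed": child,
                }
            )
    return pd.DataFrame(records)


def _donor_pairs(donors):
    for i, a in enumerate(donors):
        for b in donors[i + 1 :]:
            yield a, b


def stability_analysis(
    dm: beta_diversity.DistanceMatrix,
    metadata: pd.DataFrame,
    config: AnalysisConfig,
):
    """Curves, slopes, inflections, and interval-window comparison."""
    vessel_maps = stability.vessel_day_samples(metadata, dm.ids)
    curves = []
    for vessel, day_map in sorted(vessel_maps.items()):
        curve = stability.similarity_curve(dm, day_map, vessel)
        stability.window_slopes(curve)
        stability.inflection_day(curve)
        curves.append(curve)
    transitioning = stability.interval_similarity(
        dm, vessel_maps, _span(config.transitioning_window), "transitioning"
    )
    stable = stability.interval_similarity(
        dm, vessel_maps, _span(config.stable_window), "stable"
    )
    window_tests = stability.compare_windows(transitioning, stable)
    return curves, transitioning, stable, window_tests


def trajectory_analysis(
    table: OtuTable, config: AnalysisConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-vessel trajectory classes plus per-vessel class proportions."""
    meta = table.metadata
    fecal = meta[meta["sample_class"] == "fecal"]
    frames = []
    prop_rows = []
    for vessel, grp in meta[meta["sample_class"] == "reactor"].groupby(
        "vessel", sort=True
    ):
        donor = grp["donor"].iloc[0]
        fecal_ids = fecal.index[fecal["donor"] == donor]
        if len(fecal_ids) == 0:
            continue
        cls = otu_dynamics.classify_trajectories(
            table,
            str(vessel),
            fecal_ids[0],
            early_window=_span(config.early_window),
            stable_window=_span(config.core_day_range),
            lost_fold=config.lost_fold,
            persist_fold=config.persist_fold,
        )
        frames.append(cls)
        props = otu_dynamics.class_proportions(cls)
        prop_rows.append(
            {"vessel": vessel, "donor": donor, **{k: float(v) for k, v in props.items()}}
        )
    return pd.concat(frames, ignore_index=True), pd.DataFrame(prop_rows)


def run_full(
    table: OtuTable,
    outdir,
    config: AnalysisConfig | None = None,
    taxonomy: otu_io.TaxonomyTable | None = None,
    plot: bool = False,
) -> dict:
    """Run every analysis stage on ``table`` and write outputs to ``outdir``.

    Returns a manifest dict (also written as ``manifest.json``).  All
    randomness derives from ``config.master_seed`` through the stage table;
    a rerun with the same inputs and seed is byte-identical.
    """
    config = config or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = (
        f"config {config.config_hash()}: "
        + json.dumps(asdict(config), sort_keys=True)
    )
    manifest: dict = {"config": asdict(config), "outputs": [], "seeds": {}}

    def emit(df: pd.DataFrame, name: str) -> None:
        _write_tsv(df, outdir / name, tag)
        manifest["outputs"].append(name)

    # -- alpha diversity -------------------------------------------------
    seed = stage_seed(config.master_seed, "alpha")
    manifest["seeds"]["alpha"] = seed
    summary = alpha_diversity.iterated_alpha(
        table, config.alpha_depth, config.alpha_iterations, seed
    )
    alpha_df = summary.table.copy()
    alpha_df["depth"] = summary.depth
    alpha_df["iterations"] = summary.iterations
    emit(alpha_df, "alpha_summary.tsv")

    # -- beta diversity, ordination, tests -------------------------------
    dms = {}
    for metric in beta_diversity.METRICS:
        seed = stage_seed(config.master_seed, f"beta_{metric}")
        manifest["seeds"][f"beta_{metric}"] = seed
        dm = beta_diversity.distance_matrix(
            table, metric, config.beta_depth, seed
        )
        dms[metric] = dm
        dm.write_tsv(outdir / f"distance_{metric}.tsv")
        manifest["outputs"].append(f"distance_{metric}.tsv")

        nmds_seed = stage_seed(config.master_seed, f"nmds_{metric}")
        manifest["seeds"][f"nmds_{metric}"] = nmds_seed
        ord_res = beta_diversity.nmds(
            dm, config.nmds_dimensions, config.nmds_restarts, nmds_seed
        )
        ord_res.to_tsv(outdir / f"nmds_{metric}.tsv")
        manifest["outputs"].append(f"nmds_{metric}.tsv")
        manifest.setdefault("nmds_stress", {})[metric] = ord_res.stress

        tests_seed = stage_seed(config.master_seed, f"tests_{metric}")
        manifest["seeds"][f"tests_{metric}"] = tests_seed
        emit(
            group_comparisons(dm, table.metadata, config, tests_seed),
            f"tests_{metric}.tsv",
        )
        emit(
            beta_diversity.similarity_partition(
                dm, table.metadata, _span(config.core_day_range)
            ),
            f"similarity_partition_{metric}.tsv",
        )

    # -- stability (Bray-Curtis by convention) ---------------------------
    curves, transitioning, stable, window_tests = stability_analysis(
        dms["bray_curtis"], table.metadata, config
    )
    emit(pd.concat([c.to_frame() for c in curves], ignore_index=True),
         "stability_curves.tsv")
    emit(
        pd.DataFrame(
            [{"vessel": c.vessel,
              "inflection_day": c.inflection if c.inflection is not None else "",
              "all_crossings": ",".join(map(str, c.all_crossings))}
             for c in curves]
        ),
        "inflection_summary.tsv",
    )
    emit(pd.concat([transitioning.to_frame(), stable.to_frame()],
                   ignore_index=True), "interval_similarity.tsv")
    emit(window_tests, "window_tests.tsv")

    # -- cores ------------------------------------------------------------
    # Presence evaluated on the single beta-diversity rarefaction for
    # consistency with the distance analyses.
    sub = otu_io.subsample(
        table, config.beta_depth, stage_seed(config.master_seed, "beta_bray_curtis")
    )
    cores = core_communities.extract_cores(
        sub, _span(config.core_day_range), config.prevalence
    )
    core_rows, fraction_rows = [], []
    for level, results in cores.items():
        items = results.items() if isinstance(results, dict) else [("all", results)]
        for scope, res in items:
            for otu in sorted(res.members):
                row = {"level": level, "scope": scope, "otu": otu}
                if taxonomy is not None and otu in taxonomy:
                    row["taxonomy"] = otu_io.display_rank(taxonomy, otu, "genus")
                core_rows.append(row)
            frac = res.fractions.assign(level=level, scope=scope)
            fraction_rows.append(frac)
    emit(pd.DataFrame(core_rows), "cores.tsv")
    emit(pd.concat(fraction_rows, ignore_index=True)[
        ["level", "scope", "sample", "fraction_of_otus", "fraction_of_sequences"]
    ], "core_fractions.tsv")

    individual_cores = [r.members for r in cores["individual"].values()]
    absent = core_communities.fecal_abundant_absent(
        sub, individual_cores, config.fecal_abundance_threshold
    )
    emit(pd.DataFrame({"otu": sorted(absent)}), "fecal_abundant_absent.tsv")

    # -- taxonomy rollup (Fig 5 surface) ----------------------------------
    if taxonomy is not None:
        emit(phylum_rollup(sub, cores, absent, taxonomy,
                           _span(config.core_day_range)), "phylum_rollup.tsv")

    # -- trajectories ------------------------------------------------------
    classes, proportions = trajectory_analysis(table, config)
    emit(classes, "trajectories.tsv")
    emit(proportions, "trajectory_proportions.tsv")

    focus = sorted(set().union(*individual_cores) | absent)
    if taxonomy is not None:
        focus.sort(key=lambda o: (otu_io.display_rank(taxonomy, o, "phylum"),
                                  otu_io.display_rank(taxonomy, o, "genus"), o))
    for vessel, day_map in sorted(
        stability.vessel_day_samples(table.metadata).items()
    ):
        vt = table.filter(vessel=vessel)
        hm = otu_dynamics.heatmap_matrix(vt, focus)
        hm.to_tsv(outdir / f"heatmap_{vessel}.tsv")
        manifest["outputs"].append(f"heatmap_{vessel}.tsv")

    if plot:
        from . import plots

        for metric, dm in dms.items():
            plots.nmds_plot(
                beta_diversity.nmds(dm, config.nmds_dimensions,
                                    config.nmds_restarts,
                                    stage_seed(config.master_seed,
                                               f"nmds_{metric}")),
                table.metadata, outdir / f"nmds_{metric}.png",
            )
        plots.stability_plot(curves, outdir / "stability_curves.png")

    with open(outdir / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def phylum_rollup(
    table: OtuTable,
    cores: dict,
    absent: frozenset[str],
    taxonomy: otu_io.TaxonomyTable,
    day_range,
) -> pd.DataFrame:
    """Mean percent of sequences per phylum-level display label, per donor.

    Restricted to the union of individual-core OTUs and fecally abundant
    core-absent OTUs, with fecal inocula reported separately from reactors.
    """
    focus = sorted(
        set().union(*(r.members for r in cores["individual"].values())) | absent
    )
    rel = table.relative_abundance()[focus]
    labels = {o: otu_io.display_rank(taxonomy, o, "phylum") for o in focus}
    meta = table.metadata
    records = []
    for (donor, sample_class), grp in meta.groupby(["donor", "sample_class"],
                                                   sort=True):
        ids = [s for s in grp.index if s in rel.index]
        if sample_class == "reactor":
            ids = [s for s in ids if int(meta.loc[s, "day"]) in set(day_range)]
        if not ids:
            continue
        mean_rel = rel.loc[ids].mean(axis=0)
        by_phylum = mean_rel.groupby(labels).sum()
        for phylum, value in by_phylum.sort_index().items():
            records.append(
                {"donor": donor, "sample_class": sample_class,
                 "phylum": phylum, "percent_of_sequences": 100.0 * float(value)}
            )
    return pd.DataFrame(records)


def run_simulate(
    sim: synthetic_data.SimConfig | None = None,
    reactor: synthetic_data.ReactorConfig | None = None,
    outdir=".",
) -> dict:
    """Simulate a study and write shared + metadata + taxonomy + truth files."""
    sim = sim or synthetic_data.SimConfig()
    reactor = reactor or synthetic_data.ReactorConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = synthetic_data.simulate_study(sim, reactor)
    otu_io.write_shared(study.table, outdir / "study.shared")
    otu_io.write_metadata(study.table.metadata, outdir / "study.metadata.tsv")
    tax = synthetic_data.simulate_taxonomy(
        study.table.otu_ids, np.random.default_rng(sim.seed + 1)
    )
    otu_io.write_cons_taxonomy(tax, outdir / "study.cons.taxonomy")
    study.truth.to_json(outdir / "study.truth.json", sim)
    return {
        "shared": str(outdir / "study.shared"),
        "metadata": str(outdir / "study.metadata.tsv"),
        "taxonomy": str(outdir / "study.cons.taxonomy"),
        "truth": str(outdir / "study.truth.json"),
        "n_samples": study.table.n_samples,
    }
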