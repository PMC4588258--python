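"""Alpha diversity under iterated rarefaction.

Four within-sample metrics are computed on repeatedly rarefied count
vectors: inverse Simpson diversity (effective number of OTUs), Shannon
entropy (natural log), observed richness, and Simpson evenness (inverse
Simpson divided by observed richness).  Summaries are means and standard
deviations over independent subsampling iterations at a fixed depth, the
standard way of comparing samples of unequal sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .otu_io import OtuTable, subsample

METRICS = ("inverse_simpson", "shannon", "richness", "simpson_evenness")


def _as_props(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D abundance vector")
    if (x < 0).any():
        raise ValueError("negative abundances")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    return x / total


def inverse_simpson(counts) -> float:
    """Inverse Simpson diversity 1 / sum(p_i^2); lies in [1, S_obs]."""
    p = _as_props(counts)
    return 1.0 / float(np.sum(p**2))


def shannon(counts) -> float:
    """Shannon entropy -sum(p_i ln p_i) in nats, over OTUs with p_i > 0."""
    p = _as_props(counts)
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def richness(counts) -> int:
    """Observed richness: number of OTUs with count >= 1."""
    x = np.asarray(counts, dtype=float)
    return int(np.count_nonzero(x > 0))


def simpson_evenness(counts) -> float:
    """Inverse Simpson divided by observed richness; lies in (0, 1]."""
    return inverse_simpson(counts) / richness(counts)


_METRIC_FUNCS = {
    "inverse_simpson": inverse_simpson,
    "shannon": shannon,
    "richness": lambda c: float(richness(c)),
    "simpson_evenness": simpson_evenness,
}


@dataclass
class AlphaSummary:
    """Long-format per-(sample, metric) means and SDs over rarefaction."""

    table: pd.DataFrame  # columns: sample, metric, mean, sd
    depth: int
    iterations: int

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["depth"] = self.depth
        out["iterations"] = self.iterations
        out.to_csv(path, sep="\t", index=False, float_format="%.6g",
                   lineterminator="\n")


def iterated_alpha(
    table: OtuTable,
    depth: int = 10_000,
    iterations: int = 100,
    seed=None,
    metrics=METRICS,
) -> AlphaSummary:
    """Mean +/- SD of each alpha metric over ``iterations`` rarefactions.

    Every iteration independently rarefies each retained sample to ``depth``
    sequences; samples below ``depth`` are dropped (by :func:`subsample`).
    With ``iterations=1`` the SD is reported as 0.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    values: dict[str, dict[str, list[float]]] = {}
    retained: list[str] | None = None
    for _ in range(iterations):
        sub = subsample(table, depth, rng)
        if retained is None:
            retained = sub.sample_ids
            values = {s: {m: [] for m in metrics} for s in retained}
        for sample in retained:
            row = sub.counts.loc[sample].to_numpy()
            for m in metrics:
                values[sample][m].append(_METRIC_FUNCS[m](row))
    if not retained:
        raise InsufficientDataError(f"no sample reaches depth {depth}")
    records = []
    for sample in retained:
        for m in metrics:
            v = np.asarray(values[sample][m])
            sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
            records.append(
                {"sample": sample, "metric": m, "mean": float(v.mean()), "sd": sd}
            )
    return AlphaSummary(pd.DataFrame(records), depth=depth, iterations=iterations)
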