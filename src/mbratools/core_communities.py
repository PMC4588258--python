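"""Nested core-community extraction and abundance accounting.

Core membership is prevalence based: an OTU belongs to a vessel's
"individual core" when it is present (count >= 1) in at least 90 % of that
vessel's sampled days over the stable window (days 8-21 by default).  Cores
nest upward by intersection: the "fecal type core" is the intersection of
the individual cores of replicate vessels seeded from the same donor, and
the "all MBRA core" the intersection of fecal-type cores across donors.
Per-sample accounting reports the fraction of observed OTUs and of
sequences captured by a core set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .errors import InsufficientDataError
from .otu_io import OtuTable

logger = logging.getLogger(__name__)

DEFAULT_DAY_RANGE = range(8, 22)


@dataclass
class CoreResult:
    level: str  # "individual", "fecal_type", or "all_mbra"
    scope: str  # vessel id, donor, or "all"
    members: frozenset[str]
    fractions: pd.DataFrame | None = None  # per-sample OTU/sequence fractions


def individual_core(
    table: OtuTable,
    vessel: str,
    day_range=DEFAULT_DAY_RANGE,
    prevalence: float = 0.90,
) -> frozenset[str]:
    """OTUs present in >= ``prevalence`` of a vessel's sampled days in range.

    The required day count is ceil(prevalence * n_days) — "at least 90 %"
    is a lower bound — and the denominator is the number of days actually
    sampled in the range.
    """
    days = list(day_range)
    if not days:
        raise ValueError("empty day range")
    sub = table.filter(vessel=vessel, days=days, sample_class="reactor")
    n_days = sub.n_samples
    if n_days < 2:
        raise InsufficientDataError(
            f"vessel {vessel!r} has {n_days} sampled day(s) in range; need >= 2"
        )
    required = math.ceil(prevalence * n_days)
    presence_days = (sub.counts > 0).sum(axis=0)
    return frozenset(presence_days.index[presence_days >= required])


def fecal_type_core(individual_cores: list[frozenset[str]]) -> frozenset[str]:
    """Intersection of the individual cores of replicate vessels."""
    if len(individual_cores) < 2:
        raise InsufficientDataError("need >= 2 replicate cores to intersect")
    return frozenset(frozenset.intersection(*individual_cores))


def all_mbra_core(fecal_type_cores: list[frozenset[str]]) -> frozenset[str]:
    """Intersection of fecal-type cores across donors (pool included)."""
    if len(fecal_type_cores) < 2:
        raise InsufficientDataError("need >= 2 fecal-type cores to intersect")
    return frozenset(frozenset.intersection(*fecal_type_cores))


def core_fractions(
    table: OtuTable, core: frozenset[str], day_range=DEFAULT_DAY_RANGE
) -> pd.DataFrame:
    """Per-sample fraction of observed OTUs and of sequences in ``core``.

    Restricted to reactor samples within ``day_range``; samples with zero
    total counts are skipped with a warning.
    """
    sub = table.filter(days=list(day_range), sample_class="reactor")
    core_cols = [o for o in sub.otu_ids if o in core]
    records = []
    for sample, row in sub.counts.iterrows():
        total = int(row.sum())
        if total == 0:
            logger.warning("sample %s has zero total counts; skipped", sample)
            continue
        present = row > 0
        n_present = int(present.sum())
        n_core_present = int(present[core_cols].sum())
        records.append(
            {
                "sample": sample,
                "fraction_of_otus": n_core_present / n_present,
                "fraction_of_sequences": int(row[core_cols].sum()) / total,
            }
        )
    return pd.DataFrame(records)


def fecal_abundant_absent(
    table: OtuTable,
    individual_cores: list[frozenset[str]],
    abundance_threshold: float = 0.005,
) -> frozenset[str]:
    """Fecally abundant OTUs missing from every individual core.

    OTUs with relative abundance >= ``abundance_threshold`` in at least one
    fecal sample and absent from all individual cores — the part of the
    inoculum that did not establish in any reactor.
    """
    fecal = table.filter(sample_class="fecal")
    if fecal.n_samples == 0:
        raise InsufficientDataError("no fecal samples in table")
    rel = fecal.relative_abundance()
    abundant = set(rel.columns[(rel >= abundance_threshold).any(axis=0)])
    in_any_core = set().union(*individual_cores) if individual_cores else set()
    return frozenset(abundant - in_any_core)


def extract_cores(
    table: OtuTable,
    day_range=DEFAULT_DAY_RANGE,
    prevalence: float = 0.90,
) -> dict[str, CoreResult | dict]:
    """Full nested core extraction for every vessel, donor, and the study.

    Returns ``{"individual": {vessel: CoreResult}, "fecal_type":
    {donor: CoreResult}, "all_mbra": CoreResult}`` with per-sample fraction
    accounting attached at each level.  Nesting (all_mbra <= fecal_type <=
    individual) holds by construction and is asserted.
    """
    if table.metadata is None:
        raise InsufficientDataError("table has no metadata attached")
    meta = table.metadata
    reactors = meta[meta["sample_class"] == "reactor"]
    individual: dict[str, CoreResult] = {}
    by_donor: dict[str, list[frozenset[str]]] = {}
    for vessel, grp in reactors.groupby("vessel", sort=True):
        donor = str(grp["donor"].iloc[0])
        core = individual_core(table, str(vessel), day_range, prevalence)
        vt = table.filter(vessel=str(vessel))
        individual[str(vessel)] = CoreResult(
            "individual", str(vessel), core, core_fractions(vt, core, day_range)
        )
        by_donor.setdefault(donor, []).append(core)
    fecal_type: dict[str, CoreResult] = {}
    for donor, cores in sorted(by_donor.items()):
        core = fecal_type_core(cores)
        dt = table.filter(donor=donor)
        fecal_type[donor] = CoreResult(
            "fecal_type", donor, core, core_fractions(dt, core, day_range)
        )
    study_core = all_mbra_core([r.members for r in fecal_type.values()])
    all_mbra = CoreResult(
        "all_mbra", "all", study_core, core_fractions(table, study_core, day_range)
    )
    for vessel, res in individual.items():
        donor = str(reactors.loc[reactors["vessel"] == vessel, "donor"].iloc[0])
        assert fecal_type[donor].members <= res.members
        assert all_mbra.members <= fecal_type[donor].members
    return {"individual": individual, "fecal_type": fecal_type, "all_mbra": all_mbra}
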