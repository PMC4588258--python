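"""OTU count tables, taxonomy tables, and the mothur text dialects.

The central container is :class:`OtuTable`, an integer count matrix of
samples x OTUs with per-sample metadata (donor, vessel, day, and whether the
sample is a fecal inoculum or a reactor sample).  Tables are read from and
written to the mothur ``shared`` format (tab-delimited: label, Group,
numOtus, then one column per OTU); consensus taxonomy comes from the mothur
``cons.taxonomy`` format.  Metadata lives in a separate TSV because the
shared format has no metadata slots.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, MetadataError

logger = logging.getLogger(__name__)

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

DONOR_CODES = frozenset({"A", "B", "C", "pool"})

METADATA_COLUMNS = ("donor", "vessel", "day", "sample_class")


@dataclass
class OtuTable:
    """Integer OTU count matrix (samples x OTUs) with per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integer counts, index = sample ids,
        columns = OTU ids.
    metadata
        DataFrame indexed by sample id with columns ``donor``, ``vessel``,
        ``day`` (int, day 0 = fecal inoculum) and ``sample_class``
        (``"fecal"`` or ``"reactor"``), or ``None`` before
        :func:`attach_metadata` has been applied.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = None
    label: str = "0.03"

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].tolist()
            raise MetadataError(f"duplicate sample ids: {dupes}")
        if counts.columns.has_duplicates:
            raise FormatError("duplicate OTU ids in count table")
        arr = counts.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise ValueError("counts must be integers")
                self.counts = counts = counts.round().astype(np.int64)
                arr = counts.to_numpy()
            if (arr < 0).any():
                raise ValueError("counts must be non-negative")
        if self.metadata is not None:
            self._validate_metadata(self.metadata)

    def _validate_metadata(self, meta: pd.DataFrame) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
        if missing:
            raise MetadataError(f"metadata missing columns: {missing}")
        bad_class = set(meta["sample_class"]) - {"fecal", "reactor"}
        if bad_class:
            raise MetadataError(f"unknown sample_class values: {sorted(bad_class)}")
        # Convention: day 0 <=> fecal inoculum.
        fecal = meta["sample_class"] == "fecal"
        if not (meta.loc[fecal, "day"] == 0).all() or not (
            meta.loc[~fecal, "day"] > 0
        ).all():
            raise MetadataError("day 0 must coincide exactly with fecal samples")

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances p_i = count_i / total."""
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            raise ValueError(f"samples with zero total counts: {empty}")
        return self.counts.div(totals, axis=0)

    def select_samples(self, sample_ids) -> "OtuTable":
        ids = list(sample_ids)
        meta = self.metadata.loc[ids] if self.metadata is not None else None
        return OtuTable(self.counts.loc[ids].copy(), meta, self.label)

    def filter(self, *, donor=None, vessel=None, days=None, sample_class=None) -> "OtuTable":
        """Subset samples by metadata fields (each filter optional)."""
        if self.metadata is None:
            raise MetadataError("table has no metadata attached")
        mask = pd.Series(True, index=self.metadata.index)
        if donor is not None:
            mask &= self.metadata["donor"] == donor
        if vessel is not None:
            mask &= self.metadata["vessel"] == vessel
        if days is not None:
            mask &= self.metadata["day"].isin(list(days))
        if sample_class is not None:
            mask &= self.metadata["sample_class"] == sample_class
        return self.select_samples(self.metadata.index[mask])


@dataclass
class TaxonomyTable:
    """Consensus taxonomy: per OTU a ranked lineage with confidences (0-100)."""

    lineages: dict[str, list[str]] = field(default_factory=dict)
    confidences: dict[str, list[float]] = field(default_factory=dict)
    sizes: dict[str, int] = field(default_factory=dict)

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.lineages


def read_shared(path) -> OtuTable:
    """Read a mothur ``shared`` file into an :class:`OtuTable`.

    Metadata fields are unset until :func:`attach_metadata`.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: empty shared file")
        cols = header.rstrip("\r\n").split("\t")
        if cols[:3] != ["label", "Group", "numOtus"]:
            raise FormatError(
                f"{path}: shared header must start with label/Group/numOtus, got {cols[:3]}"
            )
        otu_ids = cols[3:]
        rows: list[list[int]] = []
        groups: list[str] = []
        label = "0.03"
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\r\n").split("\t")
            if len(parts) != 3 + len(otu_ids):
                raise FormatError(
                    f"{path}:{lineno}: expected {3 + len(otu_ids)} fields, got {len(parts)}"
                )
            label, group, num_otus = parts[0], parts[1], parts[2]
            if int(num_otus) != len(otu_ids):
                raise FormatError(
                    f"{path}:{lineno}: numOtus={num_otus} disagrees with {len(otu_ids)} OTU columns"
                )
            if group in groups:
                raise MetadataError(f"{path}:{lineno}: duplicate Group {group!r}")
            try:
                values = [int(v) for v in parts[3:]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer count ({exc})") from None
            if any(v < 0 for v in values):
                raise ValueError(f"{path}:{lineno}: negative count")
            groups.append(group)
            rows.append(values)
    counts = pd.DataFrame(
        np.asarray(rows, dtype=np.int64).reshape(len(groups), len(otu_ids)),
        index=pd.Index(groups, name="sample"),
        columns=otu_ids,
    )
    return OtuTable(counts, label=label)


def write_shared(table: OtuTable, path) -> None:
    """Write an :class:`OtuTable` as a mothur ``shared`` file (UTF-8, LF)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(["label", "Group", "numOtus", *table.otu_ids]) + "\n")
        n = table.n_otus
        for sample, row in table.counts.iterrows():
            fh.write(
                "\t".join([table.label, str(sample), str(n), *map(str, row.tolist())])
                + "\n"
            )


_TAXON_RE = re.compile(r"^(?P<name>.*?)(?:\((?P<conf>\d+(?:\.\d+)?)\))?$")


def read_cons_taxonomy(path) -> TaxonomyTable:
    """Read a mothur ``cons.taxonomy`` file.

    Lineages are semicolon-separated, optionally with parenthesized percent
    confidences; lineages without confidences default to 100.  A trailing
    semicolon is tolerated.
    """
    tax = TaxonomyTable()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if len(header) < 3 or header[0].lower() != "otu":
            raise FormatError(f"{path}: cons.taxonomy header must be OTU/Size/Taxonomy")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\r\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            otu_id, size, lineage = parts[0], parts[1], parts[2]
            names: list[str] = []
            confs: list[float] = []
            for token in lineage.rstrip(";").split(";"):
                token = token.strip()
                if not token:
                    continue
                m = _TAXON_RE.match(token)
                name = m.group("name")
                conf = float(m.group("conf")) if m.group("conf") else 100.0
                if not 0.0 <= conf <= 100.0:
                    raise ValueError(
                        f"{path}:{lineno}: confidence {conf} outside [0, 100]"
                    )
                names.append(name)
                confs.append(conf)
            tax.lineages[otu_id] = names
            tax.confidences[otu_id] = confs
            tax.sizes[otu_id] = int(size)
    return tax


def write_cons_taxonomy(tax: TaxonomyTable, path) -> None:
    """Write a :class:`TaxonomyTable` in mothur ``cons.taxonomy`` format."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("OTU\tSize\tTaxonomy\n")
        for otu_id in tax.lineages:
            lineage = "".join(
                f"{name}({conf:g});"
                for name, conf in zip(tax.lineages[otu_id], tax.confidences[otu_id])
            )
            fh.write(f"{otu_id}\t{tax.sizes.get(otu_id, 1)}\t{lineage}\n")


def read_metadata(path) -> pd.DataFrame:
    """Read the sample-metadata TSV (columns sample, donor, vessel, day, class)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample": str, "vessel": str})
    required = {"sample", "donor", "vessel", "day", "class"}
    missing = required - set(meta.columns)
    if missing:
        raise MetadataError(f"{path}: metadata missing columns {sorted(missing)}")
    meta = meta.rename(columns={"class": "sample_class"}).set_index("sample")
    meta["day"] = meta["day"].astype(int)
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.rename(columns={"sample_class": "class"}).reset_index(names="sample")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def attach_metadata(
    table: OtuTable, metadata: pd.DataFrame, known_donors=None
) -> OtuTable:
    """Return a copy of ``table`` with per-sample metadata populated.

    ``metadata`` must cover every sample exactly once; donors must be in
    ``known_donors`` if given (pass ``None`` to accept simulator-assigned
    codes).
    """
    if metadata.index.has_duplicates:
        dupes = metadata.index[metadata.index.duplicated()].tolist()
        raise MetadataError(f"duplicate metadata rows for samples: {dupes}")
    samples = set(table.sample_ids)
    meta_samples = set(metadata.index)
    absent = sorted(samples - meta_samples)
    if absent:
        raise MetadataError(f"samples missing from metadata: {absent}")
    extra = sorted(meta_samples - samples)
    if extra:
        raise MetadataError(f"metadata rows for unknown samples: {extra}")
    if known_donors is not None:
        bad = sorted(set(metadata["donor"]) - set(known_donors))
        if bad:
            raise MetadataError(f"unknown donor codes: {bad}")
    meta = metadata.loc[table.sample_ids, list(METADATA_COLUMNS)].copy()
    return OtuTable(table.counts.copy(), meta, table.label)


def display_rank(tax: TaxonomyTable, otu_id: str, rank: str) -> str:
    """Taxonomy label for display at ``rank``.

    Returns the lineage label at ``rank`` when its consensus confidence is
    >= 80 %; otherwise ``"unclassified "`` plus the deepest ancestor label
    whose confidence is >= 80 %.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if otu_id not in tax:
        raise KeyError(f"unknown OTU id {otu_id!r}")
    names = tax.lineages[otu_id]
    confs = tax.confidences[otu_id]
    depth = RANKS.index(rank)
    if depth < len(names) and confs[depth] >= 80.0:
        return names[depth]
    for d in range(min(depth, len(names)) - 1, -1, -1):
        if confs[d] >= 80.0:
            return f"unclassified {names[d]}"
    return "unclassified"


def subsample(table: OtuTable, depth: int, seed) -> OtuTable:
    """Rarefy every sample to exactly ``depth`` sequences without replacement.

    Each retained sample's counts are a multivariate-hypergeometric draw of
    ``depth`` sequences from its observed counts; samples whose total is
    below ``depth`` are dropped with a logged warning.  Deterministic under a
    fixed ``seed``.
    """
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    kept = totals.index[totals >= depth].tolist()
    dropped = totals.index[totals < depth].tolist()
    if dropped:
        logger.warning(
            "dropping %d sample(s) below depth %d: %s", len(dropped), depth, dropped
        )
    rows = np.empty((len(kept), table.n_otus), dtype=np.int64)
    for i, sample in enumerate(kept):
        colors = table.counts.loc[sample].to_numpy()
        rows[i] = rng.multivariate_hypergeometric(colors, depth)
    counts = pd.DataFrame(
        rows, index=pd.Index(kept, name="sample"), columns=table.otu_ids
    )
    meta = table.metadata.loc[kept].copy() if table.metadata is not None else None
    return OtuTable(counts, meta, table.label)
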