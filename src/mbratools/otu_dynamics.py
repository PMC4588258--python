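"""Fecal-to-reactor OTU trajectory classification and heatmap export.

Each OTU present in a fecal inoculum is assigned one trajectory class per
vessel by comparing its relative abundance in the inoculum with its
abundance during the early (days 3-4) and stable (days 8-21) culture
windows: "lost" when it disappears or drops more than ``lost_fold``
(default 5x) at every point, "persistent" when its stable-window mean stays
within ``persist_fold`` (default 3x) of the fecal level, "increased"
otherwise.  OTUs detected only in the reactor are "absent_in_feces".
Pseudocounts (default a tenth of a read at the sequencing depth) keep fold
changes finite.  Count heatmaps are exported as integer log2-bin matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .otu_io import OtuTable

CLASSES = ("lost", "persistent", "increased", "absent_in_feces")


def fold_change(fecal_p: float, reactor_p: float, pseudo: float = 1e-5) -> float:
    """Pseudocounted abundance ratio (reactor + pseudo) / (fecal + pseudo)."""
    if pseudo <= 0:
        raise ValueError("pseudocount must be positive")
    if fecal_p < 0 or reactor_p < 0:
        raise ValueError("negative relative abundance")
    return (reactor_p + pseudo) / (fecal_p + pseudo)


def classify_trajectories(
    table: OtuTable,
    vessel: str,
    fecal_sample: str,
    early_window=range(3, 5),
    stable_window=range(8, 22),
    lost_fold: float = 5.0,
    persist_fold: float = 3.0,
    pseudo: float | None = None,
) -> pd.DataFrame:
    """Classify every OTU's fecal-to-reactor trajectory for one vessel.

    Classes are assigned in the order lost -> persistent -> increased, so
    each fecal-present OTU receives exactly one class.  The early window
    defaults to days 3-4: day 1 is pre-flow (it still carries the whole
    non-growing inoculum) and day 2 is only ~3 reactor turnovers in, so
    earlier samples cannot yet witness washout as a 5-fold relative drop.  ``pseudo`` defaults to
    0.1/median sample total, a tenth of a read at the sequencing depth,
    which keeps fold changes finite without blunting the lost threshold at
    the 1-read detection limit.
    """
    if fecal_sample not in table.sample_ids:
        raise KeyError(f"fecal sample {fecal_sample!r} not in table")
    vt = table.filter(vessel=vessel, sample_class="reactor")
    if vt.n_samples == 0:
        raise InsufficientDataError(f"vessel {vessel!r} has no reactor samples")
    days = vt.metadata["day"]
    stable_ids = days.index[days.isin(list(stable_window))]
    if len(stable_ids) == 0:
        raise InsufficientDataError(
            f"vessel {vessel!r} has no samples in the stable window"
        )
    early_ids = days.index[days.isin(list(early_window))]
    if pseudo is None:
        pseudo = 0.1 / float(table.sample_totals().median())

    fecal_rel = table.select_samples([fecal_sample]).relative_abundance().iloc[0]
    vrel = vt.relative_abundance()
    early_max = (
        vrel.loc[early_ids].max(axis=0) if len(early_ids) else pd.Series(0.0, index=vrel.columns)
    )
    stable_max = vrel.loc[stable_ids].max(axis=0)
    stable_mean = vrel.loc[stable_ids].mean(axis=0)
    ever_present = (vt.counts > 0).any(axis=0)

    records = []
    for otu in table.otu_ids:
        f = float(fecal_rel[otu])
        in_feces = f > 0
        in_reactor = bool(ever_present[otu])
        if not in_feces and not in_reactor:
            continue
        window_max = max(float(early_max[otu]), float(stable_max[otu]))
        fc_stable = fold_change(f, float(stable_mean[otu]), pseudo)
        if not in_feces:
            cls = "absent_in_feces"
        elif not in_reactor or fold_change(f, window_max, pseudo) < 1.0 / lost_fold:
            cls = "lost"
        elif 1.0 / persist_fold < fc_stable < persist_fold:
            cls = "persistent"
        else:
            cls = "increased"
        records.append(
            {
                "vessel": vessel,
                "otu": otu,
                "class": cls,
                "fecal_abundance": f,
                "early_max": float(early_max[otu]),
                "stable_mean": float(stable_mean[otu]),
                "fold_change": fc_stable,
            }
        )
    return pd.DataFrame(records)


def class_proportions(classification: pd.DataFrame) -> pd.Series:
    """Fraction of fecal-present OTUs per trajectory class."""
    fecal_present = classification[classification["class"] != "absent_in_feces"]
    props = fecal_present["class"].value_counts(normalize=True)
    return props.reindex(["lost", "persistent", "increased"], fill_value=0.0)


@dataclass
class HeatmapMatrix:
    """Integer log2-bin abundance matrix (rows = OTUs, columns = samples)."""

    bins: list[int]
    matrix: pd.DataFrame

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            edges = ", ".join(str(b) for b in self.bins)
            fh.write(f"# bin edges (counts): 0, then [{edges}) with top bin >= {self.bins[-1]}\n")
            self.matrix.to_csv(fh, sep="\t", index_label="otu", lineterminator="\n")


def heatmap_matrix(
    table: OtuTable, otus: list[str], bins=None
) -> HeatmapMatrix:
    """Bin counts into log2 shading classes for heatmap rendering.

    ``bins`` are increasing powers of 2 starting at 1 (default 1..256);
    entry = index of the bin containing the count, with zero counts in bin 0
    and the top bin saturating (counts >= the last edge).
    """
    if bins is None:
        bins = [1, 2, 4, 8, 16, 32, 64, 128, 256]
    bins = list(bins)
    if bins[0] != 1 or any(b2 != 2 * b1 for b1, b2 in zip(bins, bins[1:])):
        raise ValueError("bins must be increasing powers of 2 starting at 1")
    missing = [o for o in otus if o not in set(table.otu_ids)]
    if missing:
        raise KeyError(f"OTUs not in table: {missing[:5]}")
    counts = table.counts[otus].to_numpy().T  # rows = OTUs
    binned = np.digitize(counts, bins)  # 0 for count 0, len(bins) for >= top
    mat = pd.DataFrame(binned, index=otus, columns=table.sample_ids)
    return HeatmapMatrix(bins, mat)
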