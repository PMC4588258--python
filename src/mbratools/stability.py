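"""Community stabilization: similarity-vs-time curves and inflection days.

A vessel's stability curve plots, for each sampled day, the mean Bray-Curtis
similarity between that day's sample and every other sampled day of the same
vessel.  The curve rises while the community restructures and plateaus once
it stabilizes; the stabilization day is detected as the first transition of
the three-point sliding-window slope from positive to non-positive.  Two
companion summaries quantify stability: similarity at increasing day gaps
within a time window (transitioning vs stable windows compared by unpaired
t test), and the technical-replicate similarity baseline against which
day-to-day biological variation is judged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .beta_diversity import DistanceMatrix
from .errors import InsufficientDataError


@dataclass
class StabilityCurve:
    """Per-vessel day -> mean-similarity series with windowed slopes."""

    vessel: str
    days: np.ndarray  # ordered ints
    mean_similarity: np.ndarray
    window_slopes: np.ndarray | None = None  # NaN where no full window fits
    inflection: int | None = None
    all_crossings: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        slopes = (
            self.window_slopes
            if self.window_slopes is not None
            else np.full(len(self.days), np.nan)
        )
        return pd.DataFrame(
            {
                "vessel": self.vessel,
                "day": self.days,
                "mean_similarity": self.mean_similarity,
                "window_slope": slopes,
                "is_inflection": [d == self.inflection for d in self.days],
            }
        )


def similarity_curve(
    dm: DistanceMatrix, vessel_samples: dict[int, str], vessel: str = ""
) -> StabilityCurve:
    """Mean similarity of each day's sample to all other sampled days.

    ``vessel_samples`` maps day -> sample id for one vessel; similarity is
    1 - dissimilarity under the matrix's metric.
    """
    if len(vessel_samples) < 3:
        raise InsufficientDataError("need >= 3 sampled days for a stability curve")
    days = np.asarray(sorted(vessel_samples), dtype=int)
    ids = [vessel_samples[d] for d in days]
    sub = dm.submatrix(ids)
    sim = 1.0 - sub.data
    np.fill_diagonal(sim, np.nan)
    means = np.nanmean(sim, axis=1)
    return StabilityCurve(vessel, days, means)


def window_slopes(curve: StabilityCurve, window: int = 3) -> StabilityCurve:
    """OLS slope of similarity on day over a sliding window centered per day.

    Slopes are defined only where a full window fits (NaN at the edges).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    n = len(curve.days)
    if n < window:
        raise InsufficientDataError(f"curve has {n} points, window is {window}")
    half = window // 2
    slopes = np.full(n, np.nan)
    for i in range(half, n - half):
        x = curve.days[i - half : i + half + 1].astype(float)
        y = curve.mean_similarity[i - half : i + half + 1]
        slopes[i] = np.polyfit(x, y, 1)[0]
    curve.window_slopes = slopes
    return curve


def inflection_day(curve: StabilityCurve, min_positive_run: int = 2) -> int | None:
    """Day of the first window-slope transition from positive to non-positive.

    Zero slope counts as non-positive; the transition must follow a run of
    at least ``min_positive_run`` positive-slope windows.  All crossings are
    recorded on the curve; ``None`` if slopes never transition.
    """
    if curve.window_slopes is None:
        window_slopes(curve)
    slopes = curve.window_slopes
    crossings: list[int] = []
    run = 0
    for i, s in enumerate(slopes):
        if np.isnan(s):
            continue
        if s > 0:
            run += 1
        else:
            if run >= min_positive_run:
                crossings.append(int(curve.days[i]))
            run = 0
    curve.all_crossings = crossings
    curve.inflection = crossings[0] if crossings else None
    return curve.inflection


@dataclass
class IntervalSimilarity:
    """Similarity at increasing day gaps within one time window."""

    window_label: str  # "transitioning" or "stable"
    gaps: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    values: dict[int, np.ndarray]  # gap -> pooled pairwise similarities

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window": self.window_label,
                "gap": self.gaps,
                "mean_similarity": self.means,
                "sd": self.sds,
                "n_pairs": [len(self.values[g]) for g in self.gaps],
            }
        )


def interval_similarity(
    dm: DistanceMatrix,
    vessel_samples: dict[str, dict[int, str]],
    day_window,
    label: str = "",
) -> IntervalSimilarity:
    """Mean +/- SD similarity per day gap, pooled over vessels.

    For each gap k, collects similarity of every within-vessel pair of days
    (d, d+k) with both days inside ``day_window``; empty gap classes are
    omitted.
    """
    days = sorted(set(day_window))
    if len(days) < 2:
        raise InsufficientDataError("day window must contain >= 2 days")
    pooled: dict[int, list[float]] = {}
    for vessel, day_map in vessel_samples.items():
        have = [d for d in days if d in day_map]
        for i, d1 in enumerate(have):
            for d2 in have[i + 1 :]:
                gap = d2 - d1
                s = 1.0 - dm.between(day_map[d1], day_map[d2])
                pooled.setdefault(gap, []).append(s)
    gaps = np.asarray(sorted(pooled), dtype=int)
    values = {int(g): np.asarray(pooled[g]) for g in gaps}
    means = np.asarray([values[g].mean() for g in gaps])
    sds = np.asarray(
        [values[g].std(ddof=1) if len(values[g]) > 1 else 0.0 for g in gaps]
    )
    return IntervalSimilarity(label, gaps, means, sds, values)


def compare_windows(
    transitioning: IntervalSimilarity,
    stable: IntervalSimilarity,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gap unpaired t test between two interval-similarity windows.

    Equal-variance Student's t by default (``equal_var=False`` gives Welch).
    Gaps present in both windows but with < 2 pairs in either are skipped.
    """
    records = []
    common = sorted(set(transitioning.values) & set(stable.values))
    for gap in common:
        a = transitioning.values[gap]
        b = stable.values[gap]
        if len(a) < 2 or len(b) < 2:
            continue
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        records.append(
            {
                "gap": gap,
                "transitioning_mean": float(a.mean()),
                "stable_mean": float(b.mean()),
                "t": float(t),
                "p": float(p),
                "n_transitioning": len(a),
                "n_stable": len(b),
            }
        )
    return pd.DataFrame(records)


def technical_baseline(
    dm: DistanceMatrix, replicate_pairs: list[tuple[str, str]]
) -> tuple[float, float]:
    """Mean +/- SD similarity over designated technical-replicate pairs."""
    if not replicate_pairs:
        raise InsufficientDataError("no technical replicate pairs designated")
    sims = np.asarray([1.0 - dm.between(a, b) for a, b in replicate_pairs])
    sd = float(sims.std(ddof=1)) if len(sims) > 1 else 0.0
    return float(sims.mean()), sd


def vessel_day_samples(metadata: pd.DataFrame, sample_ids=None) -> dict[str, dict[int, str]]:
    """Map vessel -> {day -> sample id} for reactor samples in ``metadata``."""
    out: dict[str, dict[int, str]] = {}
    meta = metadata if sample_ids is None else metadata.loc[list(sample_ids)]
    for sample, row in meta.iterrows():
        if row["sample_class"] != "reactor":
            continue
        out.setdefault(str(row["vessel"]), {})[int(row["day"])] = sample
    return out
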