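"""Optional matplotlib renderings of the TSV-first pipeline outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

DONOR_COLORS = {"A": "tab:blue", "B": "tab:green", "C": "tab:purple",
                "pool": "black"}


def nmds_plot(result, metadata, path) -> None:
    """Scatter of the first two NMDS axes, colored by donor."""
    fig, ax = plt.subplots(figsize=(5, 4))
    coords = result.coordinates
    for sample, row in coords.iterrows():
        donor = str(metadata.loc[sample, "donor"])
        fecal = metadata.loc[sample, "sample_class"] == "fecal"
        ax.scatter(
            row.iloc[0], row.iloc[1],
            c=DONOR_COLORS.get(donor, "gray"),
            marker="D" if fecal else "o",
            s=36 if fecal else 12,
            edgecolors="none" if fecal else None,
            alpha=1.0 if fecal else 0.6,
        )
    ax.set_xlabel("NMDS axis 1")
    ax.set_ylabel("NMDS axis 2")
    ax.set_title(f"stress = {result.stress:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def stability_plot(curves, path) -> None:
    """Per-vessel mean-similarity curves with detected inflection days."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        donor = curve.vessel[:-1] if curve.vessel[:-1] in DONOR_COLORS else None
        ax.plot(curve.days, curve.mean_similarity, lw=1,
                color=DONOR_COLORS.get(donor, "gray"), alpha=0.7)
        if curve.inflection is not None:
            i = list(curve.days).index(curve.inflection)
            ax.plot(curve.inflection, curve.mean_similarity[i], "kv", ms=5)
    ax.set_xlabel("day in culture")
    ax.set_ylabel("mean similarity to other days")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
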