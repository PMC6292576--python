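"""Per-embryo summary reports (static multi-panel PDF)."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .experiment_io import PhenomeDataset

logger = logging.getLogger(__name__)

PANELS = ("area", "movement", "total_energy", "band_energy", "cardiac_frequency")


def generate_summary_report(
    dataset: PhenomeDataset, out_path: str | Path
) -> dict | None:
    """Write a five-panel developmental report for one embryo.

    Panels: area (min/mean/max), per-recording movement, total spectral
    energy, band-energy heatmap, cardiac frequency — all against hours.
    Returns the plotted arrays keyed by panel (for verification against
    the dataset); returns None and logs when the dataset is empty.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ds = dataset.data
    if "time" not in ds.coords or ds.sizes.get("time", 0) == 0:
        logger.warning("embryo %s: empty dataset, report skipped", dataset.embryo_id)
        return None
    t = np.asarray(ds["time"].values, dtype=float)
    plotted: dict[str, np.ndarray] = {}

    fig, axes = plt.subplots(5, 1, figsize=(7, 12), sharex=True)
    ax = axes[0]
    for col, style in (("area_min", ":"), ("area_mean", "-"), ("area_max", ":")):
        if col in ds:
            y = np.asarray(ds[col].values, dtype=float)
            ax.plot(t, y, style, label=col)
            plotted[col] = y
    plotted["area"] = plotted.get("area_mean", np.full_like(t, np.nan))
    ax.set_ylabel(f"area ({ds['area_mean'].attrs.get('units', '')})"
                  if "area_mean" in ds else "area")
    ax.legend(fontsize=7)

    ax = axes[1]
    if "movement" in ds:
        y = np.asarray(ds["movement"].values, dtype=float)
        ax.plot(t, y, "-o", ms=2)
        plotted["movement"] = y
    ax.set_ylabel("movement")

    ax = axes[2]
    if "total_energy" in ds:
        y = np.asarray(ds["total_energy"].values, dtype=float)
        ax.plot(t, y, "-o", ms=2)
        plotted["total_energy"] = y
    ax.set_ylabel("total energy")

    ax = axes[3]
    band_cols = [c for c in ds.data_vars if str(c).startswith("energy_")]
    if band_cols:
        bands = np.stack(
            [np.asarray(ds[c].values, dtype=float) for c in band_cols]
        )
        ax.imshow(
            bands,
            aspect="auto",
            origin="lower",
            extent=[t[0], t[-1], 0, len(band_cols)],
            cmap="viridis",
        )
        plotted["band_energy"] = bands
    ax.set_ylabel("band index")

    ax = axes[4]
    if "cardiac_frequency" in ds:
        y = np.asarray(ds["cardiac_frequency"].values, dtype=float)
        ax.plot(t, y, "o", ms=3)
        plotted["cardiac_frequency"] = y
    ax.set_ylabel("heart rate (Hz)")
    ax.set_xlabel("time (h)")

    fig.suptitle(f"embryo {dataset.embryo_id}")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path)
    plt.close(fig)
    return plotted
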