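"""Optional matplotlib figures: dimension-vs-temperature scatter and
per-class amplitude bars with class means ± SD."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .channel_model import MeasurementDataset
from .stats import CLASSES, class_summary

_UNITS = {"length": "Å", "surface": "Å²", "volume": "Å³"}


def plot_scatter(
    dataset: MeasurementDataset, dimension: str, enzyme: str, subunit: str, path: str | Path
) -> None:
    """Scatter of one dimension against T_opt for one enzyme/subunit."""
    frame = dataset.frame
    sel = frame[(frame["enzyme"] == enzyme) & (frame["subunit"] == subunit)]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(sel["t_opt"], sel[dimension], s=12, alpha=0.7)
    ax.set_xlabel("optimum growth temperature (°C)")
    ax.set_ylabel(f"{dimension} ({_UNITS[dimension]})")
    ax.set_title(f"{enzyme} {subunit}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_amplitude_bars(
    dataset: MeasurementDataset, dimension: str, enzyme: str, subunit: str, path: str | Path
) -> None:
    """Per-class amplitude bars with the class mean ± SD overlaid."""
    frame = dataset.frame
    sel = frame[(frame["enzyme"] == enzyme) & (frame["subunit"] == subunit)]
    summaries = []
    for c in CLASSES:
        vals = sel.loc[sel["t_class"] == c, dimension].to_numpy()
        summaries.append(class_summary(vals, c) if vals.size else None)
    fig, ax = plt.subplots(figsize=(4, 3))
    xs = range(len(CLASSES))
    amps = [s.amplitude if s else 0.0 for s in summaries]
    ax.bar(xs, amps, color="0.7", label="amplitude (max − min)")
    means = [s.mean if s else float("nan") for s in summaries]
    sds = [s.sd if s and s.sd_defined else 0.0 for s in summaries]
    ax.errorbar(xs, means, yerr=sds, fmt="rs", capsize=3, label="class mean ± SD")
    ax.set_xticks(list(xs), CLASSES)
    ax.set_xlabel("growth temperature class (°C)")
    ax.set_ylabel(f"{dimension} ({_UNITS[dimension]})")
    ax.set_title(f"{enzyme} {subunit}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
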