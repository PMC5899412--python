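"""Diagnostic plots standing in for interactive fit inspection.

One figure per fitted edge: the regulator profile, the smoothed target with
its error-margin ribbon, the raw measurements and the fitted model
trajectory. These are the pictures a curator looks at before deciding to
override a classification.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .fitting import FitSettings, Label, error_margin
from .io import ExpressionSet
from .model import RegulationParams, integrate_model
from .smoothing import resample, smooth_profile


def plot_edges(
    dataset: ExpressionSet,
    table: pd.DataFrame,
    settings: FitSettings,
    out_dir: Path,
    max_plots: int = 200,
) -> int:
    """Write one PNG per fitted edge; returns the number written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dense, margin, classification, _ = settings.resolve(dataset)
    fitted = table[table["label"].isin([str(Label.GOOD_FIT), str(Label.NO_FIT)])]
    n = 0
    for _, row in fitted.head(max_plots).iterrows():
        reg, tgt = row["regulator"], row["target"]
        reg_prof = smooth_profile(dataset.row(reg), dataset.grid, settings.df, gene_id=reg)
        tgt_prof = smooth_profile(dataset.row(tgt), dataset.grid, settings.df, gene_id=tgt)
        reg_dense = resample(reg_prof, dense)
        tgt_dense = resample(tgt_prof, dense)
        band = error_margin(tgt_dense, margin)
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.fill_between(
            dense.times, tgt_dense - band, tgt_dense + band,
            alpha=0.25, color="tab:red", label="error margin",
        )
        ax.plot(dense.times, tgt_dense, color="tab:red", label=f"target {tgt}")
        ax.plot(dense.times, reg_dense, color="tab:blue", label=f"regulator {reg}")
        ax.plot(
            dataset.grid.times, dataset.row(tgt), "o", ms=4,
            color="tab:red", alpha=0.6, label="measured",
        )
        if np.isfinite(row["k1"]) and isinstance(row["w"], str) and row["w"]:
            params = RegulationParams(
                row["k1"], row["k2"], row["b"],
                np.array([float(x) for x in row["w"].split(";")]),
            )
            pred = integrate_model(params, reg_dense[None, :], float(tgt_dense[0]), dense)
            ax.plot(dense.times, pred, color="tab:green", label="fitted model")
        ax.set_xlabel("time")
        ax.set_ylabel("expression")
        ax.set_title(f"{reg} -> {tgt}: {row['label']} (quality {row['fit_quality']:.2f})")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out_dir / f"{reg}__{tgt}.png", dpi=100)
        plt.close(fig)
        n += 1
    return n
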