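"""Centile-chart plotting for normative model results."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .normative import RegionNormativeResult

__all__ = ["plot_centiles"]


def plot_centiles(
    result: RegionNormativeResult, roi_table: pd.DataFrame, path: str | Path
) -> None:
    """Age vs uptake chart: seven centile lines plus train/test points."""
    fig, ax = plt.subplots(figsize=(6, 4.2))
    for q, curve in sorted(result.centile_curves.items()):
        lw = 1.8 if abs(q - 0.5) < 1e-9 else 0.9
        ax.plot(result.centile_ages, curve, color="0.35", lw=lw)
        ax.annotate(
            f"{q * 100:g}", (result.centile_ages[-1], curve[-1]),
            fontsize=7, color="0.35", xytext=(2, 0), textcoords="offset points",
        )
    idx = roi_table.set_index("subject_id")
    tr = idx.loc[result.train_ids]
    te = idx.loc[result.test_ids]
    ax.scatter(tr["age"], tr[result.region], s=14, facecolors="none",
               edgecolors="tab:blue", label="train")
    ax.scatter(te["age"], te[result.region], s=12, color="tab:red", label="test")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("normalized uptake")
    ax.set_title(f"{result.region}  (test EV = {result.ev_test:.2f})")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
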