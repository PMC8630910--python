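"""Figure helpers (headless matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Ellipse


def _confidence_ellipse(ax, x, y, color, n_std_chi2: float = 0.95):
    """95% normal-theory confidence ellipse for one individual's cells."""
    if len(x) < 3:
        return
    cov = np.cov(x, y)
    mean = (np.mean(x), np.mean(y))
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 0, None)
    # chi-square quantile for 2 df at the requested coverage
    from scipy.stats import chi2

    r = chi2.ppf(n_std_chi2, 2)
    width, height = 2 * np.sqrt(vals * r)
    angle = np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1]))
    ax.add_patch(
        Ellipse(mean, width, height, angle=angle, facecolor="none",
                edgecolor=color, lw=1.2, alpha=0.8)
    )


def pc_scatter(scores: pd.DataFrame, title: str, path) -> None:
    """PC1/PC2 scatter of cells, colored and ellipsed by individual."""
    fig, ax = plt.subplots(figsize=(6, 5))
    inds = sorted(scores["individual_id"].unique())
    cmap = plt.get_cmap("tab20")
    for i, ind in enumerate(inds):
        sub = scores[scores["individual_id"] == ind]
        color = cmap(i % 20)
        ax.scatter(sub["PC1"], sub["PC2"], s=8, color=color, alpha=0.6, label=str(ind))
        _confidence_ellipse(ax, sub["PC1"].to_numpy(), sub["PC2"].to_numpy(), color)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
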