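"""Median-centered clustered heatmaps and the pipeline's static figures.

Every figure writes a sidecar TSV containing exactly the numbers plotted, so
plots are reproducible and scriptable without image diffing.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = ["clustered_heatmap", "km_plot", "pie_plot"]


def _corr_condensed(values: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance between rows."""
    d = 1.0 - np.corrcoef(values)
    d = np.clip((d + d.T) / 2, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


def clustered_heatmap(values: pd.DataFrame, distance: str = "pearson",
                      linkage_method: str = "average",
                      out_path: str | Path | None = None,
                      center: bool = True):
    """Hierarchically cluster a genes x samples submatrix and render a heatmap.

    Rows are median-centered across samples before clustering (each output
    row has median 0).  Distance is 1 - Pearson correlation by default
    (``distance="euclidean"`` available); linkage is average by default.
    Constant rows (undefined correlation distance) are dropped with a
    warning.  Returns (centered values, row leaf order, column leaf order,
    row linkage matrix) so the plot is fully reproducible.
    """
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need >= 2 rows and >= 2 columns")
    mat = values.copy().astype(float)
    if center:
        mat = mat.sub(mat.median(axis=1), axis=0)
    if distance == "pearson":
        keep = mat.std(axis=1) > 0
        if (~keep).any():
            warnings.warn(
                f"dropped {int((~keep).sum())} constant row(s): correlation "
                "distance undefined", stacklevel=2)
        mat = mat[keep]
        if mat.shape[0] < 2:
            raise ValueError("fewer than 2 non-constant rows")
        row_d = _corr_condensed(mat.to_numpy())
        col_d = _corr_condensed(mat.to_numpy().T) if mat.shape[1] > 2 else \
            _corr_condensed(np.vstack([mat.to_numpy().T, mat.to_numpy().T]))[:1]
        if mat.shape[1] == 2:
            col_d = np.array([0.0])
    elif distance == "euclidean":
        from scipy.spatial.distance import pdist
        row_d = pdist(mat.to_numpy())
        col_d = pdist(mat.to_numpy().T)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    row_link = hierarchy.linkage(row_d, method=linkage_method)
    col_link = hierarchy.linkage(col_d, method=linkage_method)
    row_order = hierarchy.leaves_list(row_link)
    col_order = hierarchy.leaves_list(col_link)
    ordered = mat.iloc[row_order, col_order]

    if out_path is not None:
        out_path = Path(out_path)
        fig, ax = plt.subplots(figsize=(max(4, ordered.shape[1] * 0.15),
                                        max(3, ordered.shape[0] * 0.2)))
        vmax = float(np.nanmax(np.abs(ordered.to_numpy()))) or 1.0
        im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r",
                       vmin=-vmax, vmax=vmax)
        ax.set_yticks(range(len(ordered.index)))
        ax.set_yticklabels(ordered.index, fontsize=6)
        ax.set_xticks([])
        fig.colorbar(im, ax=ax, label="median-centered log2 ratio")
        fig.tight_layout()
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
        ordered.to_csv(out_path.with_suffix(".tsv"), sep="\t")
    return ordered, row_order, col_order, row_link


def km_plot(call, out_path: str | Path, title: str = "") -> None:
    """Plot the two Kaplan-Meier curves of a PrognosticCall with a sidecar TSV."""
    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(5, 4))
    frames = []
    for name, curve in call.km_curves.items():
        ax.step(curve["time"], curve["survival"], where="post", label=name)
        c = curve.copy()
        c.insert(0, "group", name)
        frames.append(c)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    ax.set_title(title or
                 f"log-rank chi2={call.logrank_chi2:.2f}, p={call.logrank_p:.3g}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    pd.concat(frames).to_csv(out_path.with_suffix(".tsv"), sep="\t", index=False)


def pie_plot(distribution: pd.DataFrame, out_path: str | Path,
             title: str = "") -> None:
    """Pie of the feature-type distribution (counts/percent sidecar TSV)."""
    out_path = Path(out_path)
    nonzero = distribution[distribution["count"] > 0]
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    if len(nonzero):
        ax.pie(nonzero["count"],
               labels=[f"{i} ({row.percent:.0f}%)" for i, row in nonzero.iterrows()],
               startangle=90)
    ax.set_title(title or "feature-type distribution")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    distribution.to_csv(out_path.with_suffix(".tsv"), sep="\t")
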