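"""Minimal heatmap export for saved pile-up matrices."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import LogNorm

from .contact_io import read_pileup_text
from .scoring import central_enrichment

__all__ = ["render_heatmap"]


def render_heatmap(
    pileup_txt,
    out_image,
    corner_normalize_first: bool = False,
    corner_normalize: bool = False,
    vmax: float | None = None,
) -> float:
    """Render a pile-up text file as a log-scaled heatmap.

    Missing pixels are drawn in a distinct (grey) color; the central 3x3
    enrichment is annotated in the top-left corner. Returns the annotated
    score so callers can cross-check it.
    """
    mat, meta = read_pileup_text(pileup_txt)
    if corner_normalize or corner_normalize_first:
        mat = _corner(mat)
    score = central_enrichment(mat) if min(mat.shape) >= 3 else float("nan")
    fig, ax = plt.subplots(figsize=(4, 4))
    cmap = plt.get_cmap("coolwarm").copy()
    cmap.set_bad("0.7")
    finite = mat[np.isfinite(mat) & (mat > 0)]
    if finite.size:
        vmin = finite.min()
        vm = vmax if vmax is not None else finite.max()
        norm = LogNorm(vmin=vmin, vmax=max(vm, vmin * (1 + 1e-9)))
    else:
        norm = None
    im = ax.imshow(np.ma.masked_invalid(mat), cmap=cmap, norm=norm)
    ax.text(
        0.03,
        0.97,
        f"{score:.3g}",
        transform=ax.transAxes,
        va="top",
        ha="left",
        fontsize=11,
        color="black",
        bbox=dict(facecolor="white", alpha=0.8, edgecolor="none"),
    )
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(out_image, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return score


def _corner(mat: np.ndarray) -> np.ndarray:
    both = np.concatenate([mat[:1, :1].ravel(), mat[-1:, -1:].ravel()])
    scale = float(np.nanmean(both))
    if not np.isfinite(scale) or scale <= 0:
        raise ValueError("cannot corner-normalize: corner mean missing or <= 0")
    return mat / scale
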