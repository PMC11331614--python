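"""Explainability: actionable tiles, attention heatmaps, and PCA bin maps.

An *actionable tile* is a tile the trained model both attends to and whose
per-class instance head calls in-class: instance probability strictly above
0.5, then the top 15 tiles by attention for that class on that slide,
regardless of the slide's final classification. Pooled actionable-tile
embeddings are projected onto their first two principal components and the
plane is discretized into a 30×30 histogram; bins are then colored by
majority HER2 group, by fold consistency (class present in ≥ 50% of a
model's folds), or by cross-model agreement (≥ 2 / 3 / 4 models using the
same bin for the same class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .cohort_labels import HER2_GROUPS
from .mil_model import MILOutput

N_BINS_DEFAULT = 30
MAX_ACTIONABLE_PER_CLASS = 15


@dataclass
class ActionableTile:
    slide_id: str
    coord: tuple
    her2_group: str  # the branch class, not the slide's final call
    attention: float
    instance_prob: float
    embedding: np.ndarray


def select_actionable(output: MILOutput, slide_id: str, coords, class_index: int,
                      group_label: str, embeddings=None,
                      prob_threshold: float = 0.5,
                      max_tiles: int = MAX_ACTIONABLE_PER_CLASS) -> list:
    """Actionable tiles of one class branch on one slide.

    Strict filter ``instance_prob > prob_threshold`` then the ≤ ``max_tiles``
    highest-attention tiles (ties broken by tile index).
    """
    probs = np.asarray(output.instance_probs[class_index])
    attn = np.asarray(output.attention[class_index])
    coords = np.asarray(coords)
    qualify = np.flatnonzero(probs > prob_threshold)
    order = qualify[np.argsort(-attn[qualify], kind="stable")][:max_tiles]
    emb = embeddings if embeddings is not None else [None] * len(attn)
    return [
        ActionableTile(
            slide_id=slide_id,
            coord=tuple(int(v) for v in coords[i]),
            her2_group=group_label,
            attention=float(attn[i]),
            instance_prob=float(probs[i]),
            embedding=None if emb[i] is None else np.asarray(emb[i]),
        )
        for i in order
    ]


def attention_heatmap(coords, attention_row, slide_dims, tile_px: int = 256,
                      scale: int = 1) -> np.ndarray:
    """Paint min-max-normalized attention onto tile footprints.

    ``slide_dims`` is (width, height) in level-0 pixels; the output array has
    shape (height//scale, width//scale), values in [0, 1], overlapping
    footprints averaged, uncovered pixels 0. A single tile normalizes to 1.
    """
    coords = np.asarray(coords)
    a = np.asarray(attention_row, dtype=np.float64)
    if coords.shape[0] != a.size:
        raise ValueError("attention row does not align with tile coordinates")
    lo, hi = a.min(), a.max()
    norm = np.ones_like(a) if hi == lo else (a - lo) / (hi - lo)
    w, h = int(slide_dims[0]) // scale, int(slide_dims[1]) // scale
    acc = np.zeros((h, w))
    cnt = np.zeros((h, w))
    t = max(tile_px // scale, 1)
    for (x, y), v in zip(coords // scale, norm):
        x, y = int(x), int(y)
        acc[y : y + t, x : x + t] += v
        cnt[y : y + t, x : x + t] += 1
    out = np.zeros((h, w))
    np.divide(acc, cnt, out=out, where=cnt > 0)
    return out


@dataclass
class BinMap:
    """30×30 occupancy histogram over the shared (PC1, PC2) plane."""

    bounds: tuple  # (x_min, x_max, y_min, y_max)
    n_bins: int
    counts: dict  # (model_id, fold, her2_group) -> (n_bins, n_bins) int array
    pca: PCA = field(repr=False, default=None)

    @property
    def total(self) -> int:
        return int(sum(int(c.sum()) for c in self.counts.values()))

    def models(self):
        return sorted({k[0] for k in self.counts})

    def folds(self, model_id):
        return sorted({k[1] for k in self.counts if k[0] == model_id})

    def group_grid(self, model_id=None, fold=None, group=None) -> np.ndarray:
        """Summed count grid over any subset of (model, fold, group)."""
        g = np.zeros((self.n_bins, self.n_bins), dtype=int)
        for (m, f, c), grid in self.counts.items():
            if (model_id is None or m == model_id) and (fold is None or f == fold) \
                    and (group is None or c == group):
                g += grid
        return g


def project_and_bin(tiles_df: pd.DataFrame, embeddings: np.ndarray,
                    n_bins: int = N_BINS_DEFAULT) -> BinMap:
    """Fit PCA on the pooled actionable-tile embeddings and bin the plane.

    ``tiles_df`` needs columns ``model_id, fold, her2_group`` aligned with
    the embedding rows. Equal-width bins over the pooled min/max ranges;
    points on the max edge fall in the last bin. PCA is fitted once on the
    pool so bins are comparable across models and folds.
    """
    X = np.asarray(embeddings, dtype=np.float64)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 tiles to fit the 2-D projection")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate PCA: all embeddings identical")
    pca = PCA(n_components=2, random_state=0)
    P = pca.fit_transform(X)
    x_min, x_max = P[:, 0].min(), P[:, 0].max()
    y_min, y_max = P[:, 1].min(), P[:, 1].max()
    ix = _bin_index(P[:, 0], x_min, x_max, n_bins)
    iy = _bin_index(P[:, 1], y_min, y_max, n_bins)
    counts: dict = {}
    keys = list(zip(tiles_df["model_id"], tiles_df["fold"], tiles_df["her2_group"]))
    for (key, bx, by) in zip(keys, ix, iy):
        counts.setdefault(key, np.zeros((n_bins, n_bins), dtype=int))[by, bx] += 1
    return BinMap(bounds=(x_min, x_max, y_min, y_max), n_bins=n_bins, counts=counts, pca=pca)


def _bin_index(v, lo, hi, n_bins):
    if hi == lo:
        return np.zeros(len(v), dtype=int)
    idx = np.floor((v - lo) / (hi - lo) * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def color_bins(binmap: BinMap, rule: str, model_id=None, fold=None,
               group=None, n_folds: int = 10, agreement_levels=(2, 3, 4)):
    """Color the bin grid by one of the three panel rules.

    * ``majority_class`` (per model & fold): each occupied bin takes its most
      frequent HER2 group; ties broken by the fixed order neg < low < high.
      Returns an object grid of group labels (None where empty).
    * ``fold_consistency`` (per model & group): boolean grid, True where
      ≥ 50% of the folds (inclusive) contribute ≥ 1 tile of the group.
    * ``model_agreement`` (per group): dict level -> boolean grid, True where
      at least ``level`` distinct models use the bin (in the
      fold-consistency sense) for that group.
    """
    nb = binmap.n_bins
    if rule == "majority_class":
        stack = np.stack([binmap.group_grid(model_id, fold, g) for g in HER2_GROUPS])
        out = np.full((nb, nb), None, dtype=object)
        occupied = stack.sum(axis=0) > 0
        best = np.argmax(stack, axis=0)  # argmax takes the first (neg<low<high) on ties
        for g_idx, g in enumerate(HER2_GROUPS):
            out[occupied & (best == g_idx)] = g
        return out
    if rule == "fold_consistency":
        if model_id is None or group is None:
            raise ValueError("fold_consistency needs model_id and group")
        return _fold_consistent(binmap, model_id, group, n_folds)
    if rule == "model_agreement":
        if group is None:
            raise ValueError("model_agreement needs group")
        usage = sum(
            _fold_consistent(binmap, m, group, n_folds).astype(int) for m in binmap.models()
        )
        return {level: usage >= level for level in agreement_levels}
    raise ValueError(f"unknown coloring rule {rule!r}")


def _fold_consistent(binmap: BinMap, model_id, group, n_folds: int) -> np.ndarray:
    folds_with = np.zeros((binmap.n_bins, binmap.n_bins), dtype=int)
    for f in binmap.folds(model_id):
        folds_with += (binmap.group_grid(model_id, f, group) > 0).astype(int)
    return folds_with >= 0.5 * n_folds


def save_heatmap_png(heatmap: np.ndarray, path, cmap: str = "inferno") -> None:
    """Render an attention heatmap (values in [0, 1]) to a PNG panel."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6 * heatmap.shape[0] / max(heatmap.shape[1], 1)))
    im = ax.imshow(heatmap, cmap=cmap, vmin=0.0, vmax=1.0)
    fig.colorbar(im, ax=ax, fraction=0.046)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)


GROUP_COLORS = {"neg": "#2166ac", "low": "#f4a582", "high": "#b2182b"}


def save_binmap_png(grid, path, title: str = "") -> None:
    """Render a colored bin grid (class labels, booleans, or counts) to PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import to_rgb

    g = np.asarray(grid)
    img = np.ones(g.shape + (3,))
    if g.dtype == object:
        for grp, col in GROUP_COLORS.items():
            img[g == grp] = to_rgb(col)
    else:
        occupied = g.astype(float) > 0
        img[occupied] = to_rgb("#b2182b")
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(img, origin="lower")
    ax.set_xlabel("PC1 bin")
    ax.set_ylabel("PC2 bin")
    if title:
        ax.set_title(title)
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)


def actionable_table(tiles) -> pd.DataFrame:
    """Flatten ActionableTile objects to the CSV-facing table."""
    return pd.DataFrame(
        {
            "slide_id": [t.slide_id for t in tiles],
            "x": [t.coord[0] for t in tiles],
            "y": [t.coord[1] for t in tiles],
            "class": [t.her2_group for t in tiles],
            "attention": [t.attention for t in tiles],
            "instance_prob": [t.instance_prob for t in tiles],
        }
    )
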