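"""Tumor / non-tumor / background tile triage and slide-level exclusion.

Only tissue-bearing tiles inform HER2 prediction, and the attention model is
easiest to interpret when fed tumor regions only. Two filtering strategies
are supported: NOBG (drop background tiles only) and TUMO (keep tumor tiles
only), plus an ALL passthrough. Slides with fewer than ``min_tumor_tiles``
tumor tiles (strictly fewer; default 1000) are excluded from analysis.

The region classifier is pluggable: any object with ``classes`` and a
``predict_proba(patches) -> (n, 3)`` method qualifies, so a full CNN can be
swapped in for real slides. The bundled default is a multinomial logistic
model on per-channel color and optical-density summaries, which separates the
three region types of H&E tiles (white background, eosin-dominant stroma,
hematoxylin-dense tumor) by their stain statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .stain_norm import rgb_to_od

REGION_CLASSES = ("tumor", "non_tumor", "background")


@dataclass(frozen=True)
class FilterConfig:
    strategy: str = "TUMO"  # NOBG | TUMO | ALL
    min_tumor_tiles: int = 1000

    def __post_init__(self):
        if self.strategy not in ("NOBG", "TUMO", "ALL"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.min_tumor_tiles < 0:
            raise ValueError("min_tumor_tiles must be >= 0")


_KEPT = {"TUMO": {"tumor"}, "NOBG": {"tumor", "non_tumor"}, "ALL": set(REGION_CLASSES)}


def patch_features(patches) -> np.ndarray:
    """Color/stain summary features for a batch of RGB patches.

    Per channel: mean and standard deviation of intensity and of optical
    density, plus overall saturation proxies. 14 features per patch.
    """
    X = np.asarray(patches, dtype=np.float64)
    if X.ndim == 3:
        X = X[None]
    n = X.shape[0]
    flat = X.reshape(n, -1, 3)
    od = rgb_to_od(flat)
    mean_rgb = flat.mean(axis=1)
    std_rgb = flat.std(axis=1)
    mean_od = od.mean(axis=1)
    std_od = od.std(axis=1)
    chroma = flat.max(axis=2).mean(axis=1) - flat.min(axis=2).mean(axis=1)
    total_od = od.sum(axis=2).mean(axis=1)
    return np.column_stack([mean_rgb, std_rgb, mean_od, std_od, chroma, total_od])


class ColorStatPatchClassifier:
    """3-class logistic region classifier on color/OD summary features."""

    def __init__(self, seed: int = 0):
        self.classes = REGION_CLASSES
        self._model = LogisticRegression(max_iter=2000, random_state=seed)

    def fit(self, patches, labels):
        y = np.asarray([REGION_CLASSES.index(l) for l in labels])
        self._model.fit(patch_features(patches), y)
        return self

    def predict_proba(self, patches) -> np.ndarray:
        p = self._model.predict_proba(patch_features(patches))
        out = np.zeros((p.shape[0], 3))
        out[:, np.asarray(self._model.classes_, dtype=int)] = p
        return out

    def predict(self, patches):
        return [REGION_CLASSES[i] for i in np.argmax(self.predict_proba(patches), axis=1)]


def train_patch_classifier(patches, labels, seed: int = 0) -> ColorStatPatchClassifier:
    """Fit the region classifier; all three classes must be present."""
    present = set(labels)
    missing = set(REGION_CLASSES) - present
    if missing:
        raise ValueError(f"training patches missing classes: {sorted(missing)}")
    return ColorStatPatchClassifier(seed=seed).fit(patches, labels)


def label_tiles(classifier, slide_id, coords, patches) -> pd.DataFrame:
    """Classify tiles; region = argmax probability."""
    proba = classifier.predict_proba(patches)
    idx = np.argmax(proba, axis=1)
    coords = np.asarray(coords)
    return pd.DataFrame(
        {
            "slide_id": slide_id,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "region_class": [REGION_CLASSES[i] for i in idx],
            "p_tumor": proba[:, 0],
            "p_nontumor": proba[:, 1],
            "p_background": proba[:, 2],
        }
    )


def apply_filter(tile_labels: pd.DataFrame, config: FilterConfig) -> pd.DataFrame:
    """Keep the tiles admitted by the strategy (TUMO ⊆ NOBG ⊆ ALL)."""
    kept = _KEPT[config.strategy]
    return tile_labels.loc[tile_labels["region_class"].isin(kept)].reset_index(drop=True)


def exclude_sparse_slides(tumor_tile_counts: dict, min_tumor_tiles: int = 1000) -> list:
    """Slides retained iff their tumor-tile count ≥ threshold (strict exclusion below)."""
    return sorted(s for s, c in tumor_tile_counts.items() if c >= min_tumor_tiles)
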