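"""Per-slide bags of tile embeddings and their persistent HDF5 store.

A slide enters the MIL classifier as a *bag*: an (n_tiles × d) float32 matrix
of tile embeddings plus the level-0 tile coordinates. Encoders are pluggable
(any object with ``dim`` and ``encode(tiles) -> (n, d)``); the bundled
default is a deterministic seeded random projection of per-channel color
histograms, adequate for exercising the pipeline without pretrained weights.
Bags are materialized once into an HDF5 container and the MIL stage trains
from the store, decoupling feature extraction from classifier training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd


@dataclass
class FeatureBag:
    slide_id: str
    features: np.ndarray  # (n_tiles, d) float32
    coords: np.ndarray  # (n_tiles, 2) int32
    encoder_id: str = "unknown"

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float32)
        self.coords = np.asarray(self.coords, dtype=np.int32)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError("features must be a non-empty (n_tiles, d) matrix")
        if self.coords.shape != (self.features.shape[0], 2):
            raise ValueError("coords must align with features rows")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")

    @property
    def n_tiles(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]


class HistogramProjectionEncoder:
    """Seeded random projection of 3×``bins``-bin channel histograms to d dims.

    Deterministic: identical tiles yield identical embeddings. Serves as the
    pipeline's default encoder where a pathology foundation model would sit.
    """

    def __init__(self, dim: int = 1024, bins: int = 16, seed: int = 0):
        self.dim = dim
        self.bins = bins
        self.encoder_id = f"hist{bins}-proj{dim}-seed{seed}"
        rng = np.random.default_rng(seed)
        self._proj = rng.standard_normal((3 * bins, dim)) / np.sqrt(3 * bins)

    def encode(self, tiles) -> np.ndarray:
        X = np.asarray(tiles, dtype=np.float64)
        if X.ndim == 3:
            X = X[None]
        n = X.shape[0]
        flat = X.reshape(n, -1, 3)
        hists = np.empty((n, 3 * self.bins))
        edges = np.linspace(0, 256, self.bins + 1)
        for c in range(3):
            for i in range(n):
                h, _ = np.histogram(flat[i, :, c], bins=edges)
                hists[i, c * self.bins : (c + 1) * self.bins] = h / flat.shape[1]
        return (hists @ self._proj).astype(np.float32)


def encode_tiles(tiles, coords, slide_id: str, encoder) -> FeatureBag:
    """Encode a slide's kept tiles into a FeatureBag; validates dimensions and finiteness."""
    feats = np.asarray(encoder.encode(tiles))
    if feats.ndim != 2 or feats.shape[1] != encoder.dim:
        raise ValueError(
            f"encoder {getattr(encoder, 'encoder_id', '?')} returned shape {feats.shape}, "
            f"expected (n, {encoder.dim})"
        )
    if not np.all(np.isfinite(feats)):
        raise ValueError("encoder produced non-finite values")
    return FeatureBag(
        slide_id=slide_id,
        features=feats,
        coords=np.asarray(coords),
        encoder_id=getattr(encoder, "encoder_id", "unknown"),
    )


class BagStoreError(KeyError):
    pass


class BagStore:
    """HDF5 container: one group per slide with ``features`` and ``coords`` datasets."""

    def __init__(self, path):
        self.path = str(path)

    def write_bag(self, bag: FeatureBag) -> None:
        with h5py.File(self.path, "a") as f:
            if bag.slide_id in f:
                del f[bag.slide_id]
            g = f.create_group(bag.slide_id)
            g.create_dataset("features", data=bag.features, dtype="float32")
            g.create_dataset("coords", data=bag.coords, dtype="int32")
            g.attrs["encoder_id"] = bag.encoder_id

    def read_bag(self, slide_id: str) -> FeatureBag:
        try:
            with h5py.File(self.path, "r") as f:
                if slide_id not in f:
                    raise BagStoreError(f"slide {slide_id!r} not in store {self.path}")
                g = f[slide_id]
                return FeatureBag(
                    slide_id=slide_id,
                    features=g["features"][...],
                    coords=g["coords"][...],
                    encoder_id=g.attrs.get("encoder_id", "unknown"),
                )
        except (OSError, KeyError) as e:
            if isinstance(e, BagStoreError):
                raise
            raise BagStoreError(f"cannot read slide {slide_id!r} from {self.path}: {e}") from e

    def list_slides(self) -> list:
        try:
            with h5py.File(self.path, "r") as f:
                return sorted(f.keys())
        except OSError as e:
            raise BagStoreError(f"cannot open store {self.path}: {e}") from e

    def write_manifest(self, path) -> None:
        rows = []
        with h5py.File(self.path, "r") as f:
            for sid in sorted(f.keys()):
                g = f[sid]
                rows.append((sid, g["features"].shape[0], g["features"].shape[1],
                             g.attrs.get("encoder_id", "unknown")))
        pd.DataFrame(rows, columns=["slide_id", "n_tiles", "dim", "encoder_id"]).to_csv(
            path, index=False
        )
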