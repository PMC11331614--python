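"""Macenko stain normalization of H&E tiles to a reference color profile.

Pixels are mapped to optical density, OD = −log10((I + 1)/256), where the
Beer–Lambert law makes stain mixing linear: OD ≈ M·c with M the 3×2 matrix of
unit hematoxylin/eosin absorption directions and c the per-pixel stain
concentrations. The Macenko estimator projects tissue pixels onto the top-2
singular plane of their OD vectors and takes robust extreme angles as the two
stain directions. Normalization re-expresses a tile's concentrations in a
reference profile: solve non-negative concentrations against the source
matrix, rescale by the ratio of robust concentration maxima, and re-render
with the reference matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np


class BackgroundTileError(ValueError):
    """Raised when a tile has too few tissue (high-OD) pixels to estimate stains."""


@dataclass(frozen=True)
class StainProfile:
    """Stain geometry of one image: unit H/E OD directions and robust maxima."""

    stain_matrix: np.ndarray  # 3x2, unit columns, hematoxylin first
    max_concentrations: np.ndarray  # 2 positive scalars

    def __post_init__(self):
        m = np.asarray(self.stain_matrix, dtype=np.float64)
        if m.shape != (3, 2):
            raise ValueError("stain_matrix must be 3x2")
        object.__setattr__(self, "stain_matrix", m)
        object.__setattr__(
            self, "max_concentrations", np.asarray(self.max_concentrations, dtype=np.float64)
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "stain_matrix": self.stain_matrix.tolist(),
                "max_concentrations": self.max_concentrations.tolist(),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "StainProfile":
        d = json.loads(s)
        return cls(np.array(d["stain_matrix"]), np.array(d["max_concentrations"]))


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """Optical density per channel; the +1 offset avoids log(0) at I = 255... 0."""
    return -np.log10((np.asarray(rgb, dtype=np.float64) + 1.0) / 256.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    i = 256.0 * np.power(10.0, -od) - 1.0
    return np.clip(np.rint(i), 0, 255).astype(np.uint8)


def nnls_concentrations(stain_matrix: np.ndarray, od_pixels: np.ndarray) -> np.ndarray:
    """Exact vectorized non-negative least squares for the 3×2 stain system.

    Solves min ||M c − b||² s.t. c ≥ 0 for every OD pixel b by enumerating the
    four sign supports {both free, c0=0, c1=0, both 0} and picking the feasible
    candidate with the smallest residual. Returns concentrations (2, n).
    """
    M = np.asarray(stain_matrix, dtype=np.float64)
    B = np.asarray(od_pixels, dtype=np.float64)  # (n, 3)
    n = B.shape[0]
    cands = np.zeros((3, 2, n))
    # both coefficients free
    cands[0] = np.linalg.lstsq(M, B.T, rcond=None)[0]
    # single-column projections, clipped at zero
    for j in (0, 1):
        cands[1 + j, j] = np.clip(B @ M[:, j] / (M[:, j] @ M[:, j]), 0.0, None)
    feasible = np.all(cands >= -1e-12, axis=1)  # (3, n); single-column rows always feasible
    resid = np.einsum("kin,kin->kn", np.einsum("ij,kjn->kin", M, cands) - B.T[None],
                      np.einsum("ij,kjn->kin", M, cands) - B.T[None])
    resid = np.where(feasible, resid, np.inf)
    # the all-zero candidate is implicitly covered: residual ||b||^2 only wins when
    # both single-column projections clip to 0, which then equal it exactly
    best = np.argmin(resid, axis=0)
    return np.clip(cands[best, :, np.arange(n)].T, 0.0, None)


def estimate_stain_profile(
    rgb_image: np.ndarray,
    od_threshold: float = 0.15,
    angle_percentiles: tuple = (1.0, 99.0),
    min_tissue_pixels: int = 100,
) -> StainProfile:
    """Estimate a Macenko stain profile from an RGB image.

    Pixels whose maximum-channel OD falls below ``od_threshold`` are treated
    as background and excluded; the two stain directions are the
    ``angle_percentiles`` extremes of the angular distribution in the top-2
    OD singular plane. The hematoxylin column (larger red-channel OD) is
    listed first. Robust maxima are 99th-percentile concentrations.
    """
    od = rgb_to_od(rgb_image).reshape(-1, 3)
    tissue = od[od.max(axis=1) >= od_threshold]
    if tissue.shape[0] < min_tissue_pixels:
        raise BackgroundTileError(
            f"background-only tile: {tissue.shape[0]} tissue pixels < {min_tissue_pixels}"
        )
    _, _, vt = np.linalg.svd(tissue, full_matrices=False)
    basis = vt[:2].T  # 3x2 plane basis
    # orient basis vectors so tissue projections are predominantly positive
    for j in range(2):
        if (tissue @ basis[:, j]).sum() < 0:
            basis[:, j] = -basis[:, j]
    proj = tissue @ basis
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, angle_percentiles)
    v_lo = basis @ np.array([np.cos(lo), np.sin(lo)])
    v_hi = basis @ np.array([np.cos(hi), np.sin(hi)])
    # hematoxylin absorbs red light more strongly than eosin
    h, e = (v_lo, v_hi) if v_lo[0] >= v_hi[0] else (v_hi, v_lo)
    m = np.column_stack([h, e])
    m = np.clip(m, 0.0, None)
    m /= np.linalg.norm(m, axis=0, keepdims=True)
    conc = nnls_concentrations(m, tissue)
    max_c = np.percentile(conc, 99.0, axis=1)
    return StainProfile(m, np.maximum(max_c, 1e-8))


def normalize_tile(
    rgb_tile: np.ndarray, source_profile: StainProfile, reference_profile: StainProfile
) -> np.ndarray:
    """Re-render a tile's stain concentrations in the reference profile.

    Background pixels carry near-zero concentrations and pass through
    near-white. Output is uint8 with the input's shape.
    """
    shape = rgb_tile.shape
    od = rgb_to_od(rgb_tile).reshape(-1, 3)
    conc = nnls_concentrations(source_profile.stain_matrix, od)
    scale = reference_profile.max_concentrations / source_profile.max_concentrations
    conc = conc * scale[:, None]
    od_new = (reference_profile.stain_matrix @ conc).T
    return od_to_rgb(od_new).reshape(shape)


def estimate_slide_profile(tiles, max_tiles: int = 50, pixels_per_tile: int = 2000,
                           seed: int = 0, **kwargs) -> StainProfile:
    """One stain profile per slide, from a random sample of its (tumor) tiles.

    Estimating once per slide and applying the profile to all of its tiles
    stabilizes the percentile-based estimates on tiles with little tissue.
    """
    rng = np.random.default_rng(seed)
    tiles = list(tiles)
    if len(tiles) > max_tiles:
        idx = rng.choice(len(tiles), size=max_tiles, replace=False)
        tiles = [tiles[i] for i in sorted(idx)]
    pools = []
    for t in tiles:
        flat = np.asarray(t).reshape(-1, 3)
        if flat.shape[0] > pixels_per_tile:
            flat = flat[rng.choice(flat.shape[0], size=pixels_per_tile, replace=False)]
        pools.append(flat)
    pooled = np.concatenate(pools, axis=0)
    side = int(np.floor(np.sqrt(pooled.shape[0])))
    return estimate_stain_profile(pooled[: side * side].reshape(side, side, 3), **kwargs)


def stain_angle_error(estimated: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Per-column angle (radians) between estimated and true stain directions."""
    est = estimated / np.linalg.norm(estimated, axis=0)
    tru = truth / np.linalg.norm(truth, axis=0)
    cos = np.clip(np.abs((est * tru).sum(axis=0)), -1.0, 1.0)
    return np.arccos(cos)
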