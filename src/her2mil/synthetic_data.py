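"""Synthetic cohorts with the statistical structure the MIL analysis assumes.

A slide's latent HER2 group (neg / low / high) determines both its assay
readout and the composition of its bag of tile embeddings:

* background tiles are drawn from K Gaussian clusters shared by all classes
  (shared morphology: stroma, fat, vessels, ...);
* low/high slides additionally carry *witness* tiles from a class-specific
  Gaussian shifted by δ from the background — the tile-level evidence the
  attention mechanism is supposed to find. The per-slide witness fraction is
  Beta-distributed around a class prevalence, mimicking tumor heterogeneity.

Observed labels follow the clinical assay path: latent high reads IHC 3+
with probability 0.7 and otherwise 2+/ISH-pos; latent low reads 1+ with
probability 0.6 and otherwise 2+/ISH-neg; latent neg reads 0. Interobserver
disagreement on faint membrane staining is modeled as a 0↔1+ swap of the
observed IHC score with probability ε; 2+/3+ calls stay clean, which is
exactly the mechanism that degrades neg-vs-low contrasts while leaving
neg-vs-high untouched.

The generator can also emit tiny RGB patches (near-white background,
eosin-pink non-tumor, hematoxylin-purple tumor) rendered through Beer–Lambert
mixing from a recorded stain matrix, as fixtures for the imaging stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_labels import manifest_from_records, SlideRecord
from .feature_bags import FeatureBag

LATENT_CLASSES = ("neg", "low", "high")

#: Unit H/E absorption directions used to render synthetic tiles (Beer–Lambert).
TRUE_STAIN_MATRIX = np.array(
    [[0.650, 0.072], [0.704, 0.990], [0.286, 0.105]]
)
TRUE_STAIN_MATRIX /= np.linalg.norm(TRUE_STAIN_MATRIX, axis=0, keepdims=True)


@dataclass(frozen=True)
class SynthConfig:
    n_slides_per_class_per_cohort: int = 10
    cohorts: tuple = ("SYNTH_A", "SYNTH_B")
    tiles_per_slide: tuple = (50, 200)
    embed_dim: int = 32
    n_background_clusters: int = 10
    witness_separation: float = 5.0  # mean shift δ, in units of cluster σ below
    witness_prevalence_low: float = 0.10
    witness_prevalence_high: float = 0.20
    prevalence_concentration: float = 20.0
    cluster_sigma: float = 1.0
    p_ihc3_given_high: float = 0.7
    p_ihc1_given_low: float = 0.6
    label_noise: float = 0.0  # ε: probability of swapping observed IHC 0 <-> 1+
    patch_px: int = 64
    seed: int = 0

    def __post_init__(self):
        for p in (self.witness_prevalence_low, self.witness_prevalence_high,
                  self.label_noise, self.p_ihc3_given_high, self.p_ihc1_given_low):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.witness_separation <= 0:
            raise ValueError("witness_separation must be positive")


@dataclass
class SyntheticCohort:
    manifest: pd.DataFrame  # slide_id, patient_id, cohort, ihc, ish, her2_group + latent_class
    bags: dict  # slide_id -> FeatureBag
    witness_masks: dict  # slide_id -> bool array aligned with bag rows
    witness_means: dict  # latent class -> d-vector (zero vector for neg)
    config: SynthConfig


def _observed_assay(latent: str, cfg: SynthConfig, rng) -> tuple:
    if latent == "neg":
        ihc, ish = "0", "absent"
    elif latent == "low":
        ihc, ish = ("1+", "absent") if rng.random() < cfg.p_ihc1_given_low else ("2+", "neg")
    else:
        ihc, ish = ("3+", "absent") if rng.random() < cfg.p_ihc3_given_high else ("2+", "pos")
    # interobserver 0 <-> 1+ swap
    if ihc in ("0", "1+") and rng.random() < cfg.label_noise:
        ihc = "1+" if ihc == "0" else "0"
        ish = "absent"
    return ihc, ish


def generate_cohort(config: SynthConfig) -> SyntheticCohort:
    """Generate a seeded synthetic cohort of slide records and feature bags."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    d = cfg.embed_dim
    centers = rng.normal(0.0, 1.0, size=(cfg.n_background_clusters, d))
    # orthogonal witness directions, scaled to δ·σ
    dirs = np.linalg.qr(rng.normal(size=(d, 2)))[0].T
    shift = cfg.witness_separation * cfg.cluster_sigma
    witness_means = {
        "neg": np.zeros(d),
        "low": dirs[0] * shift,
        "high": dirs[1] * shift,
    }
    prevalence = {"neg": 0.0, "low": cfg.witness_prevalence_low,
                  "high": cfg.witness_prevalence_high}

    records, bags, masks = [], {}, {}
    i = 0
    for latent in LATENT_CLASSES:
        for cohort in cfg.cohorts:
            for _ in range(cfg.n_slides_per_class_per_cohort):
                sid = f"S{i:04d}"
                pid = f"P{i:04d}"
                i += 1
                n_tiles = int(rng.integers(cfg.tiles_per_slide[0], cfg.tiles_per_slide[1] + 1))
                p_c = prevalence[latent]
                if p_c > 0:
                    kappa = cfg.prevalence_concentration
                    frac = rng.beta(p_c * kappa, (1 - p_c) * kappa)
                else:
                    frac = 0.0
                witness = rng.random(n_tiles) < frac
                assign = rng.integers(cfg.n_background_clusters, size=n_tiles)
                feats = centers[assign] + rng.normal(0.0, cfg.cluster_sigma, size=(n_tiles, d))
                feats[witness] = witness_means[latent] + rng.normal(
                    0.0, cfg.cluster_sigma, size=(int(witness.sum()), d)
                )
                ihc, ish = _observed_assay(latent, cfg, rng)
                records.append(SlideRecord(sid, pid, cohort, ihc, ish))
                coords = np.column_stack(
                    [np.arange(n_tiles) * 128, np.zeros(n_tiles, dtype=int)]
                )
                bags[sid] = FeatureBag(sid, feats, coords, encoder_id="synthetic")
                masks[sid] = witness

    manifest = manifest_from_records(records)
    manifest["latent_class"] = np.repeat(
        LATENT_CLASSES, len(cfg.cohorts) * cfg.n_slides_per_class_per_cohort
    )
    return SyntheticCohort(
        manifest=manifest, bags=bags, witness_masks=masks,
        witness_means=witness_means, config=cfg,
    )


def generate_tile_images(config: SynthConfig, n_per_class: int = 20):
    """Render labeled RGB patches for the imaging stages.

    Returns ``(patches, labels, stain_matrix)``: background is near-white
    (mean intensity > 230), non-tumor is eosin-dominant pink, tumor is
    hematoxylin-dominant purple; tissue classes are Beer–Lambert mixes of
    the recorded stain matrix, so the stain estimator's recovery is checkable.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1)
    px = cfg.patch_px
    patches, labels = [], []
    conc_ranges = {
        "tumor": ((0.8, 1.5), (0.15, 0.45)),  # (hematoxylin, eosin)
        "non_tumor": ((0.03, 0.15), (0.55, 1.1)),
    }
    for label in ("tumor", "non_tumor", "background"):
        for _ in range(n_per_class):
            if label == "background":
                img = 250.0 + rng.normal(0.0, 2.0, size=(px, px, 3))
            else:
                (h_lo, h_hi), (e_lo, e_hi) = conc_ranges[label]
                c = np.stack(
                    [rng.uniform(h_lo, h_hi, size=(px, px)),
                     rng.uniform(e_lo, e_hi, size=(px, px))],
                    axis=-1,
                )
                od = c @ TRUE_STAIN_MATRIX.T
                img = 256.0 * np.power(10.0, -od) - 1.0
            patches.append(np.clip(np.rint(img), 0, 255).astype(np.uint8))
            labels.append(label)
    return patches, labels, TRUE_STAIN_MATRIX.copy()
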