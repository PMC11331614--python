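"""Actionable tiles, attention heatmaps, and PCA bin maps."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from her2mil.mil_model import MILOutput
from her2mil.xai_actionable import (
    BinMap,
    attention_heatmap,
    color_bins,
    project_and_bin,
    select_actionable,
)


def _output(instance_probs, attention):
    inst = np.asarray(instance_probs, dtype=float)[None, :]
    attn = np.asarray(attention, dtype=float)[None, :]
    n = inst.shape[1]
    return MILOutput(
        attention=attn, slide_vectors=np.zeros((1, 2)), logits=np.zeros(1),
        probs=np.ones(1), instance_logits=np.zeros((1, n, 2)), instance_probs=inst,
    )


def _coords(n):
    return [(i * 128, 0) for i in range(n)]


def test_all_qualifying_tiles_returned_when_below_cap(rng):
    out = _output([0.9] * 10, rng.uniform(size=10))
    tiles = select_actionable(out, "s", _coords(10), 0, "high")
    assert len(tiles) == 10


def test_cap_takes_fifteen_highest_attention(rng):
    attn = np.arange(20) / 20.0
    out = _output([0.9] * 20, attn)
    tiles = select_actionable(out, "s", _coords(20), 0, "high")
    assert len(tiles) == 15
    picked = sorted(t.coord[0] // 128 for t in tiles)
    assert picked == list(range(5, 20))  # oracle: sort + slice


def test_probability_exactly_half_is_excluded():
    out = _output([0.5, 0.500001, 0.7], [0.3, 0.3, 0.4])
    tiles = select_actionable(out, "s", _coords(3), 0, "low")
    assert {t.coord[0] // 128 for t in tiles} == {1, 2}
    assert all(t.instance_prob > 0.5 for t in tiles)


def test_selection_bounded_per_class(rng):
    for c in range(3):
        out = MILOutput(
            attention=rng.dirichlet(np.ones(40), size=3),
            slide_vectors=np.zeros((3, 2)), logits=np.zeros(3), probs=np.ones(3) / 3,
            instance_logits=np.zeros((3, 40, 2)),
            instance_probs=rng.uniform(size=(3, 40)),
        )
        tiles = select_actionable(out, "s", _coords(40), c, "low")
        assert len(tiles) <= 15


def test_heatmap_singleton_tile_paints_one():
    hm = attention_heatmap([(0, 0)], [0.42], slide_dims=(512, 512), tile_px=256)
    assert hm[:256, :256].min() == 1.0
    assert hm[300:, 300:].max() == 0.0


def test_heatmap_two_disjoint_tiles_min_max_normalized():
    hm = attention_heatmap([(0, 0), (256, 0)], [0.2, 0.8], slide_dims=(512, 256))
    assert np.all(hm[:, :256] == 0.0)
    assert np.all(hm[:, 256:] == 1.0)


def test_heatmap_overlap_region_is_average():
    hm = attention_heatmap([(0, 0), (128, 0)], [0.2, 0.8], slide_dims=(384, 256))
    assert np.all(hm[:, :128] == 0.0)
    assert np.all(hm[:, 128:256] == 0.5)  # 50%-overlap strip: mean of 0 and 1
    assert np.all(hm[:, 256:] == 1.0)


def test_heatmap_bounds_order_invariance_and_length_check(rng):
    coords = [(0, 0), (128, 0), (256, 0)]
    a = rng.uniform(size=3)
    h1 = attention_heatmap(coords, a, (512, 256), scale=4)
    h2 = attention_heatmap(coords[::-1], a[::-1], (512, 256), scale=4)
    assert np.array_equal(h1, h2)
    assert h1.min() >= 0.0 and h1.max() <= 1.0
    with pytest.raises(ValueError):
        attention_heatmap(coords, [0.1, 0.2], (512, 256))


def _tiles_df(n, model="M6", fold=0, group="low"):
    return pd.DataFrame({"model_id": model, "fold": fold, "her2_group": [group] * n})


def test_bin_counts_conserve_points(rng):
    X = rng.normal(size=(200, 16))
    bm = project_and_bin(_tiles_df(200), X)
    assert bm.total == 200
    doubled = project_and_bin(pd.concat([_tiles_df(200)] * 2, ignore_index=True),
                              np.vstack([X, X]))
    for key in bm.counts:
        assert np.array_equal(doubled.counts[key], 2 * bm.counts[key])


def test_two_dim_input_projection_preserves_distances_and_bins_corners():
    X = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 2.0], [10.0, 2.0]])
    bm = project_and_bin(_tiles_df(4), X)
    P = bm.pca.transform(X)
    assert np.allclose(pdist(P), pdist(X))  # pure rotation + centering
    cols = ((P[:, 0] - bm.bounds[0]) / (bm.bounds[1] - bm.bounds[0]) * 30).astype(int)
    cols = np.clip(cols, 0, 29)
    # the x=0 pair shares one edge column, the x=10 pair the opposite one
    assert cols[0] == cols[2] and cols[1] == cols[3]
    assert {cols[0], cols[1]} == {0, 29}


def test_degenerate_inputs_rejected(rng):
    with pytest.raises(ValueError):
        project_and_bin(_tiles_df(2), rng.normal(size=(2, 4)))
    with pytest.raises(ValueError, match="degenerate"):
        project_and_bin(_tiles_df(5), np.ones((5, 4)))


def _binmap_from_counts(counts, n_bins=30):
    return BinMap(bounds=(0, 1, 0, 1), n_bins=n_bins, counts=counts)


def test_majority_class_coloring_and_tie_break():
    low = np.zeros((30, 30), dtype=int); low[3, 4] = 3; low[7, 7] = 2
    high = np.zeros((30, 30), dtype=int); high[3, 4] = 1; high[7, 7] = 2
    bm = _binmap_from_counts({("M6", 0, "low"): low, ("M6", 0, "high"): high})
    grid = color_bins(bm, "majority_class", model_id="M6", fold=0)
    assert grid[3, 4] == "low"  # 3 vs 1
    assert grid[7, 7] == "low"  # tie broken by fixed order neg < low < high
    assert grid[0, 0] is None


def test_fold_consistency_requires_half_the_folds():
    counts = {}
    for f in range(10):
        g = np.zeros((30, 30), dtype=int)
        if f < 5:
            g[2, 2] = 1  # present in exactly 5/10 folds -> colored (inclusive)
        if f < 4:
            g[9, 9] = 1  # 4/10 -> not colored
        counts[("M6", f, "high")] = g
    bm = _binmap_from_counts(counts)
    grid = color_bins(bm, "fold_consistency", model_id="M6", group="high", n_folds=10)
    assert grid[2, 2] and not grid[9, 9]


def test_model_agreement_levels():
    counts = {}
    for model in ("M1", "M2", "M3"):
        for f in range(10):
            g = np.zeros((30, 30), dtype=int)
            if model in ("M1", "M2"):
                g[5, 5] = 1  # used consistently by exactly 2 models
            g[6, 6] = 1  # used by all 3
            counts[(model, f, "high")] = g
    bm = _binmap_from_counts(counts)
    out = color_bins(bm, "model_agreement", group="high", n_folds=10)
    assert out[2][5, 5] and not out[3][5, 5]
    assert out[3][6, 6] and not out[4][6, 6]


def test_unknown_rule_rejected():
    bm = _binmap_from_counts({("M6", 0, "low"): np.zeros((30, 30), dtype=int)})
    with pytest.raises(ValueError):
        color_bins(bm, "rainbow")


def test_count_conservation_under_subsetting(rng):
    df = pd.DataFrame({
        "model_id": rng.choice(["M1", "M2"], size=100),
        "fold": rng.integers(0, 3, size=100),
        "her2_group": rng.choice(["neg", "low", "high"], size=100),
    })
    bm = project_and_bin(df, rng.normal(size=(100, 8)))
    assert bm.total == 100
    assert sum(bm.group_grid(model_id=m).sum() for m in ("M1", "M2")) == 100
    assert sum(bm.group_grid(group=g).sum() for g in ("neg", "low", "high")) == 100


def test_png_panels_are_written(tmp_path, rng):
    from her2mil.xai_actionable import save_binmap_png, save_heatmap_png

    hm = attention_heatmap([(0, 0), (256, 0)], [0.2, 0.8], (512, 256), scale=4)
    save_heatmap_png(hm, tmp_path / "heat.png")
    grid = np.full((30, 30), None, dtype=object)
    grid[3, 3] = "low"
    save_binmap_png(grid, tmp_path / "bins.png", title="majority")
    assert (tmp_path / "heat.png").stat().st_size > 0
    assert (tmp_path / "bins.png").stat().st_size > 0
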