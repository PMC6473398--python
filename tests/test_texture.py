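"""GLCM/GLRLM construction, feature formulas, and the cohort extractor."""

import itertools
import math

import numpy as np
import pytest

from conftest import glcm_bruteforce, glrlm_bruteforce, random_quantized
from dosiomics.core import DoseGrid, FeatureTable, RoiMask
from dosiomics.texture import (
    DIRECTIONS_13,
    GLCM_FEATURES,
    GLRLM_FEATURES,
    QuantizedGrid,
    TextureConfig,
    dosiomics_columns,
    extract_dosiomics,
    extract_patient_dosiomics,
    glcm_3d,
    glcm_features,
    glrlm_3d,
    glrlm_features,
    quantize,
    zscore_normalize,
)


def _qgrid(levels, ng=None):
    levels = np.asarray(levels, dtype=np.int32)
    ng = ng or int(levels.max())
    return QuantizedGrid(levels, ng, np.arange(ng + 1, dtype=float))


# ------------------------------------------------- independent feature oracles

def glcm_features_naive(p):
    """Textbook double-loop evaluation of the 27 co-occurrence features."""
    ng = p.shape[0]
    mu_x = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
    mu_y = sum((j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]
    sx = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng)))
    sy = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng)))
    pd = [sum(p[i, j] for i in range(ng) for j in range(ng) if abs(i - j) == k)
          for k in range(ng)]
    ps = [sum(p[i, j] for i in range(ng) for j in range(ng) if i + j + 2 == k)
          for k in range(2, 2 * ng + 1)]

    def ent(vals):
        return -sum(v * math.log2(v) for v in vals if v > 0)

    hx, hy = ent(px), ent(py)
    hxy = ent([p[i, j] for i in range(ng) for j in range(ng)])
    hxy1 = -sum(p[i, j] * math.log2(px[i] * py[j])
                for i in range(ng) for j in range(ng)
                if p[i, j] > 0 and px[i] * py[j] > 0)
    hxy2 = -sum(px[i] * py[j] * math.log2(px[i] * py[j])
                for i in range(ng) for j in range(ng) if px[i] * py[j] > 0)
    da = sum(k * pd[k] for k in range(ng))
    sa = sum((k + 2) * ps[k] for k in range(len(ps)))
    out = {
        "Autocorrelation": sum((i + 1) * (j + 1) * p[i, j]
                               for i in range(ng) for j in range(ng)),
        "JointAverage": mu_x,
        "ClusterProminence": sum((i + j + 2 - mu_x - mu_y) ** 4 * p[i, j]
                                 for i in range(ng) for j in range(ng)),
        "ClusterShade": sum((i + j + 2 - mu_x - mu_y) ** 3 * p[i, j]
                            for i in range(ng) for j in range(ng)),
        "ClusterTendency": sum((i + j + 2 - mu_x - mu_y) ** 2 * p[i, j]
                               for i in range(ng) for j in range(ng)),
        "Contrast": sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng)),
        "Correlation": (sum((i + 1 - mu_x) * (j + 1 - mu_y) * p[i, j]
                            for i in range(ng) for j in range(ng)) / (sx * sy)
                        if sx > 0 and sy > 0 else 1.0),
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(pd),
        "DifferenceVariance": sum((k - da) ** 2 * pd[k] for k in range(ng)),
        "Dissimilarity": sum(abs(i - j) * p[i, j] for i in range(ng) for j in range(ng)),
        "JointEnergy": sum(p[i, j] ** 2 for i in range(ng) for j in range(ng)),
        "JointEntropy": hxy,
        "Homogeneity1": sum(p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)),
        "Homogeneity2": sum(p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)),
        "Imc1": (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0,
        "Imc2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))),
        "Idm": sum(p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)),
        "Idmn": sum(p[i, j] / (1 + (i - j) ** 2 / ng**2) for i in range(ng) for j in range(ng)),
        "Id": sum(p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)),
        "Idn": sum(p[i, j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)),
        "InverseVariance": sum(p[i, j] / (i - j) ** 2
                               for i in range(ng) for j in range(ng) if i != j),
        "MaximumProbability": max(p[i, j] for i in range(ng) for j in range(ng)),
        "SumAverage": sa,
        "SumEntropy": ent(ps),
        "SumSquares": sum((i + 1 - mu_x) ** 2 * p[i, j]
                          for i in range(ng) for j in range(ng)),
        "SumVariance": sum((k + 2 - sa) ** 2 * ps[k] for k in range(len(ps))),
    }
    return out


def glrlm_features_naive(c, n_voxels):
    """Textbook double-loop evaluation of the 16 run-length features."""
    ng, rmax = c.shape
    nr = c.sum()
    p = c / nr
    mu_i = sum((i + 1) * p[i, j] for i in range(ng) for j in range(rmax))
    mu_j = sum((j + 1) * p[i, j] for i in range(ng) for j in range(rmax))
    ri = [sum(c[i, j] for j in range(rmax)) for i in range(ng)]
    rj = [sum(c[i, j] for i in range(ng)) for j in range(rmax)]
    return {
        "ShortRunEmphasis": sum(c[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(rmax)) / nr,
        "LongRunEmphasis": sum(c[i, j] * (j + 1) ** 2 for i in range(ng) for j in range(rmax)) / nr,
        "GrayLevelNonUniformity": sum(v**2 for v in ri) / nr,
        "GrayLevelNonUniformityNormalized": sum(v**2 for v in ri) / nr**2,
        "RunLengthNonUniformity": sum(v**2 for v in rj) / nr,
        "RunLengthNonUniformityNormalized": sum(v**2 for v in rj) / nr**2,
        "RunPercentage": nr / n_voxels,
        "GrayLevelVariance": sum((i + 1 - mu_i) ** 2 * p[i, j]
                                 for i in range(ng) for j in range(rmax)),
        "RunVariance": sum((j + 1 - mu_j) ** 2 * p[i, j]
                           for i in range(ng) for j in range(rmax)),
        "RunEntropy": -sum(p[i, j] * math.log2(p[i, j])
                           for i in range(ng) for j in range(rmax) if p[i, j] > 0),
        "LowGrayLevelRunEmphasis": sum(c[i, j] / (i + 1) ** 2
                                       for i in range(ng) for j in range(rmax)) / nr,
        "HighGrayLevelRunEmphasis": sum(c[i, j] * (i + 1) ** 2
                                        for i in range(ng) for j in range(rmax)) / nr,
        "ShortRunLowGrayLevelEmphasis": sum(c[i, j] / ((i + 1) ** 2 * (j + 1) ** 2)
                                            for i in range(ng) for j in range(rmax)) / nr,
        "ShortRunHighGrayLevelEmphasis": sum(c[i, j] * (i + 1) ** 2 / (j + 1) ** 2
                                             for i in range(ng) for j in range(rmax)) / nr,
        "LongRunLowGrayLevelEmphasis": sum(c[i, j] * (j + 1) ** 2 / (i + 1) ** 2
                                           for i in range(ng) for j in range(rmax)) / nr,
        "LongRunHighGrayLevelEmphasis": sum(c[i, j] * (i + 1) ** 2 * (j + 1) ** 2
                                            for i in range(ng) for j in range(rmax)) / nr,
    }


class TestQuantize:
    def test_integer_dose_identity_binning(self):
        values = np.arange(64, dtype=float).reshape(4, 4, 4)
        dose = DoseGrid(values)
        mask = RoiMask(np.ones((4, 4, 4), dtype=bool))
        q = quantize(dose, mask, n_levels=64)
        assert np.array_equal(q.levels, values.astype(int) + 1)

    def test_constant_dose_degenerates_to_one_level(self, uniform_grid):
        dose, mask = uniform_grid
        q = quantize(dose, mask, n_levels=64)
        assert q.n_levels == 1
        assert np.all(q.levels[mask.values] == 1)

    def test_matches_edge_comparison_oracle(self, random_grid):
        dose, mask = random_grid
        for ng in (2, 8, 64):
            q = quantize(dose, mask, n_levels=ng)
            d = dose.values[mask.values]
            expected = np.minimum(
                np.digitize(d, q.bin_edges[1:-1], right=False) + 1, ng
            )
            assert np.array_equal(q.levels[mask.values], expected)
            assert q.levels[mask.values].min() >= 1
            assert q.levels[mask.values].max() == ng
            assert np.all(q.levels[~mask.values] == 0)

    def test_bin_width_mode(self, random_grid):
        dose, mask = random_grid
        q = quantize(dose, mask, bin_width=5.0)
        d = dose.values[mask.values]
        assert q.n_levels == int(np.ceil((d.max() - d.min()) / 5.0))

    def test_max_dose_maps_to_top_level(self, random_grid):
        dose, mask = random_grid
        q = quantize(dose, mask, n_levels=16)
        top_voxel = np.unravel_index(
            np.argmax(np.where(mask.values, dose.values, -1)), dose.shape
        )
        assert q.levels[top_voxel] == 16


class TestGlcm:
    def test_two_voxel_line(self):
        q = _qgrid([[[1, 2]]])
        out = glcm_3d(q, directions=((0, 0, 1),), symmetric=True)
        p = out.matrices[0]
        assert p[0, 1] == 0.5 and p[1, 0] == 0.5

    def test_constant_grid_all_mass_at_origin(self):
        q = _qgrid(np.ones((3, 3, 3), dtype=int))
        out = glcm_3d(q)
        for m, ok in zip(out.matrices, out.valid):
            assert ok and m[0, 0] == 1.0

    def test_matches_bruteforce_all_directions(self, rng):
        for symmetric in (True, False):
            for _ in range(4):
                shape = tuple(rng.integers(2, 5, size=3))
                levels = random_quantized(rng, shape, ng=4)
                q = _qgrid(levels, ng=4)
                out = glcm_3d(q, symmetric=symmetric)
                for m, ok, direction in zip(out.matrices, out.valid, out.directions):
                    ref = glcm_bruteforce(levels, 4, direction, symmetric=symmetric)
                    if ref.sum() == 0:
                        assert not ok
                    else:
                        assert ok
                        assert np.allclose(m, ref / ref.sum())

    def test_probabilities_sum_to_one_and_symmetry(self, rng):
        levels = random_quantized(rng, (5, 5, 5), ng=6)
        out = glcm_3d(_qgrid(levels, ng=6), symmetric=True)
        for m, ok in zip(out.matrices, out.valid):
            if ok:
                assert m.sum() == pytest.approx(1.0)
                assert np.array_equal(m, m.T)

    def test_distance_two(self, rng):
        levels = random_quantized(rng, (4, 4, 4), ng=3)
        out = glcm_3d(_qgrid(levels, ng=3), distance=2)
        for m, ok, direction in zip(out.matrices, out.valid, out.directions):
            ref = glcm_bruteforce(levels, 3, direction, distance=2)
            if ref.sum() > 0:
                assert np.allclose(m, ref / ref.sum())


class TestGlrlm:
    def test_line_runs(self):
        q = _qgrid([[[1], [1], [2], [2]]])  # 1x4x1 grid, direction (0,1,0)
        out = glrlm_3d(q, directions=((0, 1, 0),))
        c = out.matrices[0]
        assert c[0, 1] == 1 and c[1, 1] == 1 and c.sum() == 2

    def test_constant_line_single_run(self):
        n = 9
        q = _qgrid(np.ones((1, 1, n), dtype=int))
        out = glrlm_3d(q, directions=((0, 0, 1),))
        assert out.matrices[0][0, n - 1] == 1
        assert out.matrices[0].sum() == 1

    def test_conservation_and_scanline_oracle(self, rng):
        for _ in range(5):
            shape = tuple(rng.integers(2, 6, size=3))
            levels = random_quantized(rng, shape, ng=4)
            q = _qgrid(levels, ng=4)
            out = glrlm_3d(q)
            n_in = int((levels > 0).sum())
            j = None
            for c, direction in zip(out.matrices, out.directions):
                jj = np.arange(1, c.shape[1] + 1)
                assert (c * jj).sum() == n_in  # every voxel in exactly one run
                ref = glrlm_bruteforce(levels, 4, direction)
                rmax = max(c.shape[1], ref.shape[1])
                cp = np.zeros((4, rmax)); cp[:, :c.shape[1]] = c
                rp = np.zeros((4, rmax)); rp[:, :ref.shape[1]] = ref
                assert np.array_equal(cp, rp)


class TestGlcmFeatures:
    def test_constant_grid_contrast_zero(self):
        q = _qgrid(np.ones((3, 3, 3), dtype=int))
        feats = glcm_features(glcm_3d(q))
        assert feats["Contrast"] == 0.0
        assert feats["Correlation"] == 1.0  # degenerate convention
        assert feats["MaximumProbability"] == 1.0

    def test_two_level_pair_contrast_one(self):
        q = _qgrid([[[1, 2]]])
        feats = glcm_features(glcm_3d(q, directions=((0, 0, 1),)))
        assert feats["Contrast"] == pytest.approx(1.0)
        assert feats["Dissimilarity"] == pytest.approx(1.0)
        assert feats["JointEnergy"] == pytest.approx(0.5)

    def test_all_27_match_naive_reference(self, rng):
        for _ in range(3):
            levels = random_quantized(rng, (4, 5, 4), ng=5)
            out = glcm_3d(_qgrid(levels, ng=5))
            feats = glcm_features(out)
            per_dir = [glcm_features_naive(m)
                       for m, ok in zip(out.matrices, out.valid) if ok]
            for name in GLCM_FEATURES:
                expected = np.mean([d[name] for d in per_dir])
                assert feats[name] == pytest.approx(expected, rel=1e-10, abs=1e-12), name


class TestGlrlmFeatures:
    def test_all_level_one_lglre(self, rng):
        levels = (random_quantized(rng, (4, 4, 4), ng=3) > 0).astype(np.int32)
        feats = glrlm_features(glrlm_3d(_qgrid(levels, ng=1)))
        assert feats["LowGrayLevelRunEmphasis"] == pytest.approx(1.0)
        assert feats["HighGrayLevelRunEmphasis"] == pytest.approx(1.0)

    def test_single_run_long_run_emphasis(self):
        q = _qgrid(np.ones((1, 1, 4), dtype=int))
        feats = glrlm_features(glrlm_3d(q, directions=((0, 0, 1),)))
        assert feats["LongRunEmphasis"] == pytest.approx(16.0)
        assert feats["ShortRunEmphasis"] == pytest.approx(1.0 / 16.0)

    def test_all_16_match_naive_reference(self, rng):
        levels = random_quantized(rng, (4, 4, 5), ng=4)
        out = glrlm_3d(_qgrid(levels, ng=4))
        feats = glrlm_features(out)
        per_dir = [glrlm_features_naive(m, out.n_voxels)
                   for m in out.matrices if m.sum() > 0]
        for name in GLRLM_FEATURES:
            expected = np.mean([d[name] for d in per_dir])
            assert feats[name] == pytest.approx(expected, rel=1e-10), name


class TestRotationInvariance:
    def test_90_degree_rotation_preserves_features(self, rng):
        # the 13-direction set is closed under 90-degree rotations up to
        # sign, so direction-averaged features cannot change
        dose_values = rng.uniform(0, 60, size=(6, 6, 6))
        mask_values = rng.uniform(size=(6, 6, 6)) < 0.8
        mask_values[0, 0, 0] = True
        dose = DoseGrid(dose_values)
        mask = RoiMask(mask_values)
        rot_dose = DoseGrid(np.rot90(dose_values, k=1, axes=(1, 2)).copy())
        rot_mask = RoiMask(np.rot90(mask_values, k=1, axes=(1, 2)).copy())
        cfg = TextureConfig(n_levels=8)
        q1 = quantize(dose, mask, n_levels=8)
        q2 = quantize(rot_dose, rot_mask, n_levels=8)
        f1 = glcm_features(glcm_3d(q1))
        f2 = glcm_features(glcm_3d(q2))
        for name in GLCM_FEATURES:
            assert f1[name] == pytest.approx(f2[name], rel=1e-9), name
        r1 = glrlm_features(glrlm_3d(q1))
        r2 = glrlm_features(glrlm_3d(q2))
        for name in GLRLM_FEATURES:
            assert r1[name] == pytest.approx(r2[name], rel=1e-9), name


def _phantom(shape=(6, 10, 12), seed=7):
    rng = np.random.default_rng(seed)
    left = np.zeros(shape, dtype=bool)
    right = np.zeros(shape, dtype=bool)
    left[1:5, 2:8, 1:5] = True
    right[1:5, 2:8, 7:11] = True
    dose = rng.uniform(0, 60, size=shape)
    return dose, left, right


class TestExtract:
    def test_129_columns_and_determinism(self):
        from dosiomics.dvh import lung_set

        dose_values, left, right = _phantom()
        dose = DoseGrid(dose_values)
        masks = dict(zip(("ipsilateral", "contralateral", "total"),
                         lung_set(RoiMask(left, role="left"),
                                  RoiMask(right, role="right"), "left")))
        table = extract_dosiomics([("A", dose, masks), ("B", dose, masks)])
        assert table.features.shape == (2, 129)
        assert list(table.columns) == dosiomics_columns()
        assert np.array_equal(table.features.loc["A"].to_numpy(),
                              table.features.loc["B"].to_numpy())
        assert not table.features.isna().any().any()

    def test_mirror_symmetry(self):
        from dosiomics.dvh import lung_set

        dose_values, left, right = _phantom()
        dose = DoseGrid(dose_values)
        masks_a = dict(zip(("ipsilateral", "contralateral", "total"),
                           lung_set(RoiMask(left, role="left"),
                                    RoiMask(right, role="right"), "left")))
        # mirrored patient: flip x, tumor side right
        mdose = DoseGrid(dose_values[:, :, ::-1].copy())
        mleft = RoiMask(right[:, :, ::-1].copy(), role="left")
        mright = RoiMask(left[:, :, ::-1].copy(), role="right")
        masks_b = dict(zip(("ipsilateral", "contralateral", "total"),
                           lung_set(mleft, mright, "right")))
        a = extract_patient_dosiomics(dose, masks_a)
        b = extract_patient_dosiomics(mdose, masks_b)
        for name, value in a.items():
            assert value == pytest.approx(b[name], rel=1e-9), name

    def test_uniform_phantom_contrast_and_run_percentage(self):
        from dosiomics.dvh import lung_set

        _, left, right = _phantom()
        dose = DoseGrid(np.full(left.shape, 30.0))
        masks = dict(zip(("ipsilateral", "contralateral", "total"),
                         lung_set(RoiMask(left, role="left"),
                                  RoiMask(right, role="right"), "left")))
        row = extract_patient_dosiomics(dose, masks)
        assert row["glcm_Contrast_ipsi"] == 0.0
        # single gray level: runs per direction = number of scan lines
        q = quantize(dose, masks["ipsilateral"], n_levels=64)
        out = glrlm_3d(q)
        expected_rp = np.mean(
            [m.sum() / out.n_voxels for m in out.matrices if m.sum() > 0]
        )
        assert row["glrlm_RunPercentage_ipsi"] == pytest.approx(expected_rp)

    def test_failure_reports_patient_id(self):
        dose = DoseGrid(np.full((4, 4, 4), 10.0))
        empty = {role: RoiMask(np.zeros((4, 4, 4), dtype=bool), role=role)
                 for role in ("ipsilateral", "contralateral", "total")}
        with pytest.raises(Exception, match="P7"):
            extract_dosiomics([("P7", dose, empty)])


class TestZscore:
    def test_basic_column(self):
        import pandas as pd

        t = FeatureTable(pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.0, 1.0, 5.0]}))
        z = zscore_normalize(t)
        assert np.allclose(z.features["a"], [-1.0, 0.0, 1.0])  # sample sd = 1
        assert z.features.mean().abs().max() < 1e-12
        assert np.allclose(z.features.var(ddof=1), 1.0)
        assert z.normalized

    def test_renormalization_is_stable(self, rng):
        import pandas as pd

        t = FeatureTable(pd.DataFrame(rng.normal(size=(20, 4)),
                                      columns=list("abcd")))
        z1 = zscore_normalize(t)
        z2 = zscore_normalize(z1)
        assert np.allclose(z1.features.to_numpy(), z2.features.to_numpy(), atol=1e-12)

    def test_zero_variance_column_named(self):
        import pandas as pd

        t = FeatureTable(pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0]}))
        with pytest.raises(ValueError, match="flat"):
            zscore_normalize(t)
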