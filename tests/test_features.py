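"""Clump detection, shape measures, and the 296-feature schema."""

import math
from collections import deque

import numpy as np
import pytest

from bfmorph import features, synth
from bfmorph.features import FeatureConfig


class TestBinarizeDark:
    def test_constant_crop_empty_mask_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = features.binarize_dark(np.full((10, 10), 7.0), 0.5)
        assert not mask.any()

    def test_high_tau_excludes_only_maximum(self):
        crop = np.array([[0.0, 1.0], [2.0, 3.0]])
        mask = features.binarize_dark(crop, 1 - 1e-9)
        assert mask.sum() == 3 and not mask[1, 1]

    def test_planted_disk_recovered(self):
        rng = np.random.default_rng(1)
        crop = rng.normal(1000, 2, (64, 64))
        rr, cc = np.mgrid[:64, :64]
        disk = (rr - 32) ** 2 + (cc - 32) ** 2 <= 10**2
        crop[disk] -= 60
        mask = features.binarize_dark(crop, 0.5)
        assert np.array_equal(mask, disk)

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            features.binarize_dark(np.zeros((4, 4)), 0.0)


def _flood_fill_components(mask, connectivity=8):
    """Brute-force oracle: BFS components + exposed-edge perimeters."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    if connectivity == 8:
        nbrs = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1) if (a, b) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    comps = []
    H, W = mask.shape
    for r in range(H):
        for c in range(W):
            if mask[r, c] and not seen[r, c]:
                q = deque([(r, c)])
                seen[r, c] = True
                pix = []
                while q:
                    i, j = q.popleft()
                    pix.append((i, j))
                    for a, b in nbrs:
                        ii, jj = i + a, j + b
                        if 0 <= ii < H and 0 <= jj < W and mask[ii, jj] and not seen[ii, jj]:
                            seen[ii, jj] = True
                            q.append((ii, jj))
                per = 0
                pset = set(pix)
                for i, j in pix:
                    for a, b in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        if (i + a, j + b) not in pset:
                            per += 1
                comps.append((frozenset(pix), len(pix), per))
    return comps


class TestLabelClumps:
    def test_two_squares_hand_example(self):
        mask = np.zeros((10, 10), bool)
        mask[1:4, 1:4] = True
        mask[6:9, 6:9] = True
        clumps = features.label_clumps(mask, FeatureConfig(min_clump_area=1))
        assert len(clumps) == 2
        assert [c.area for c in clumps] == [9, 9]
        assert [c.perimeter for c in clumps] == [12, 12]
        assert clumps[0].centroid == (2.0, 2.0)

    def test_diagonal_touch_is_one_clump_under_8_connectivity(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True
        cfg8 = FeatureConfig(min_clump_area=1)
        assert len(features.label_clumps(mask, cfg8)) == 1
        cfg4 = FeatureConfig(connectivity=4, min_clump_area=1)
        assert len(features.label_clumps(mask, cfg4)) == 2

    def test_min_area_filter(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        assert features.label_clumps(mask, FeatureConfig(min_clump_area=2)) == []

    def test_matches_flood_fill_oracle_random_masks(self):
        rng = np.random.default_rng(5)
        cfg = FeatureConfig(min_clump_area=1)
        for _ in range(25):
            mask = rng.random((32, 32)) < 0.35
            got = {
                (frozenset(map(tuple, c.pixels)), c.area, c.perimeter)
                for c in features.label_clumps(mask, cfg)
            }
            want = set(_flood_fill_components(mask))
            assert got == want


class TestShapeMeasures:
    def test_noncircularity_closed_forms(self):
        r = 5.0
        assert features.noncircularity(math.pi * r**2, 2 * math.pi * r) == 0.0
        assert features.noncircularity(9, 12) == pytest.approx(1 - 36 * math.pi / 144)
        bar = features.noncircularity(9, 20)
        assert bar == pytest.approx(1 - 36 * math.pi / 400)
        assert bar > features.noncircularity(9, 12)

    def test_noncircularity_rejects_degenerate(self):
        with pytest.raises(ValueError):
            features.noncircularity(0, 10)
        with pytest.raises(ValueError):
            features.noncircularity(5, 0)

    def test_clump_measurements_conventions(self):
        assert features.clump_measurements([]) == (0, 0.0, 0.0)
        mask = np.zeros((6, 6), bool)
        mask[1:4, 1:4] = True
        clumps = features.label_clumps(mask, FeatureConfig(min_clump_area=1))
        n, area, nc = features.clump_measurements(clumps)
        assert (n, area) == (1, 9.0)
        assert nc == pytest.approx(1 - 36 * math.pi / 144)

    def test_binarized_shape_measures(self):
        assert features.binarized_shape_measures(np.zeros((4, 4), bool)) == (0, 0, 0.0)
        mask = np.zeros((6, 6), bool)
        mask[1:4, 1:4] = True
        area, per, thin = features.binarized_shape_measures(mask)
        assert (area, per) == (9, 12)
        assert thin == pytest.approx(36 * math.pi / 144)

    def test_disk_thinner_than_equal_area_bar(self):
        rr, cc = np.mgrid[:40, :40]
        disk = (rr - 20) ** 2 + (cc - 20) ** 2 <= 81
        bar = np.zeros((40, 40), bool)
        bar[1, 1 : 1 + int(disk.sum())] = True
        t_disk = features.binarized_shape_measures(disk)[2]
        t_bar = features.binarized_shape_measures(bar)[2]
        assert t_disk > t_bar

    def test_mean_noncircularity_monotone_in_axis_ratio(self):
        means = []
        for q in (1.0, 2.0, 3.0, 4.0):
            ncs = []
            for s in range(20):
                rng = np.random.default_rng(s)
                rr, cc, _ = synth._rasterize_ellipse(
                    (40.0, 40.0), 200.0, q, rng.uniform(0, math.pi), (80, 80)
                )
                m = np.zeros((80, 80), bool)
                m[rr, cc] = True
                a, p, _ = features.binarized_shape_measures(m)
                ncs.append(features.noncircularity(a, p))
            means.append(np.mean(ncs))
        assert all(b > a for a, b in zip(means, means[1:]))


class TestIntensityStatistics:
    def test_constant_crop_conventions(self):
        s = features.intensity_statistics(np.full((5, 5), 3.0))
        assert s["sd"] == 0 and s["skewness"] == 0 and s["kurtosis"] == 0
        assert s["min"] == s["max"] == s["mean"] == 3.0

    def test_hand_computed_example(self):
        s = features.intensity_statistics(np.array([[0.0, 0.0], [0.0, 100.0]]))
        assert s["mean"] == 25.0
        assert s["d50"] == 0.0

    def test_matches_brute_force_on_random_crops(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            v = rng.normal(50, 9, (12, 17))
            s = features.intensity_statistics(v)
            flat = sorted(v.ravel())
            n = len(flat)
            mean = sum(flat) / n
            sd = math.sqrt(sum((x - mean) ** 2 for x in flat) / n)
            sk = sum(((x - mean) / sd) ** 3 for x in flat) / n
            ku = sum(((x - mean) / sd) ** 4 for x in flat) / n - 3
            assert s["mean"] == pytest.approx(mean)
            assert s["sd"] == pytest.approx(sd)
            assert s["skewness"] == pytest.approx(sk)
            assert s["kurtosis"] == pytest.approx(ku)
            assert s["min"] == flat[0] and s["max"] == flat[-1]


class TestExtractFeatures:
    def test_vector_length_and_determinism(self, single_cell_pair, feature_config):
        pair, _ = single_cell_pair
        v1 = features.extract_features(pair.bf, feature_config)
        v2 = features.extract_features(pair.bf, feature_config)
        assert v1.values.shape == (296,)
        assert np.array_equal(v1.values, v2.values)
        assert np.all(np.isfinite(v1.values))

    def test_constant_crop_zero_clump_features(self, feature_config):
        with pytest.warns(UserWarning):
            v = features.extract_features(np.full((30, 30), 5.0), feature_config)
        idx = [
            i for i, nm in enumerate(feature_config.feature_schema)
            if nm.endswith("clump_count")
        ]
        assert np.all(v.values[idx] == 0)

    def test_named_threshold_summaries_present(self, feature_config):
        schema = feature_config.feature_schema
        for nm in (
            "taumean_clump_count",
            "taumean_clump_mean_area",
            "taumean_clump_mean_noncircularity",
        ):
            assert nm in schema

    def test_schema_stable_and_serializable(self, feature_config):
        import json

        again = FeatureConfig()
        assert again.feature_schema == feature_config.feature_schema
        assert again.schema_hash == feature_config.schema_hash
        records = json.loads(json.dumps(feature_config.schema_records()))
        assert [r["name"] for r in records] == list(feature_config.feature_schema)

    def test_adding_a_clump_never_decreases_count(self, feature_config):
        rng = np.random.default_rng(3)
        crop = rng.normal(1000, 2, (80, 80))
        rr, cc = np.mgrid[:80, :80]
        tau5 = feature_config.feature_schema.index("tau5_clump_count")
        counts = []
        for k, ctr in enumerate([(20, 20), (60, 60), (40, 15)]):
            disk = (rr - ctr[0]) ** 2 + (cc - ctr[1]) ** 2 <= 16
            crop[disk] -= 60
            counts.append(features.extract_features(crop, feature_config).values[tau5])
        assert counts == sorted(counts)


class TestApplyFilter:
    def test_constant_invariance(self):
        crop = np.full((12, 12), 40.0)
        for kind in ("blur", "edge_enhance", "sharpen"):
            out = features.apply_filter(crop, kind)
            assert np.allclose(out, crop)

    def test_sharpen_does_not_soften_step_edge(self):
        crop = np.zeros((16, 16))
        crop[:, 8:] = 100.0
        base = np.abs(np.diff(crop, axis=1)).max()
        sharp = features.apply_filter(crop, "sharpen")
        assert np.abs(np.diff(sharp, axis=1)).max() >= base

    def test_blur_softens_step_edge(self):
        crop = np.zeros((16, 16))
        crop[:, 8:] = 100.0
        blurred = features.apply_filter(crop, "blur")
        assert np.abs(np.diff(blurred, axis=1)).max() < 100.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="emboss"):
            features.apply_filter(np.zeros((4, 4)), "emboss")
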