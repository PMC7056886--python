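"""Scene composition: augmentations, edge-ignore labelling, dataset builds."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swardseg import fixtures, sig
from swardseg.types import (
    BACKGROUND,
    CLOVER,
    EXCLUDED,
    GRASS,
    IGNORE,
    IGNORE_EDGE,
    OBJECT,
    ContaminationError,
    PlantSample,
)


def _sample(size=9):
    rgb = np.full((size, size, 3), 120, dtype=np.uint8)
    mask = np.full((size, size), EXCLUDED, dtype=np.uint8)
    mask[2:-2, 2:-2] = OBJECT
    return PlantSample(rgb=rgb, mask=mask, species=CLOVER)


class TestAugment:
    def test_identity_when_jitters_off(self):
        cfg = sig.SigConfig(flip_probability=0.0, scale_jitter=0.0,
                            gamma_jitter=0.0, saturation_jitter=0.0)
        s = _sample()
        out = sig.augment_sample(s, cfg, np.random.default_rng(0))
        assert np.array_equal(out.rgb, s.rgb)
        assert np.array_equal(out.mask, s.mask)

    def test_hflip_is_involution(self):
        cfg = sig.SigConfig(flip_probability=1.0, scale_jitter=0.0,
                            gamma_jitter=0.0, saturation_jitter=0.0)
        s = _sample()
        s.rgb[2, 3] = (1, 2, 3)  # break symmetry
        once = sig.augment_sample(s, cfg, np.random.default_rng(0))
        # p=1 applies both flips; applying both again restores the original
        twice = sig.augment_sample(once, cfg, np.random.default_rng(0))
        assert np.array_equal(twice.rgb, s.rgb)
        assert np.array_equal(twice.mask, s.mask)

    def test_scale_factor_distribution(self):
        """Monte-Carlo check of the +-25% scale range."""
        cfg = sig.SigConfig()
        s = _sample(5)
        rng = np.random.default_rng(42)
        scales = np.array([
            sig.augment_sample(s, cfg, rng, return_params=True)[1]["scale"]
            for _ in range(10_000)
        ])
        assert scales.min() >= 0.75 and scales.max() <= 1.25
        se = scales.std() / np.sqrt(len(scales))
        assert abs(scales.mean() - 1.0) < 3 * se

    def test_degenerate_scale_raises(self):
        cfg = sig.SigConfig(flip_probability=0.0, scale_jitter=0.9)
        tiny = PlantSample(
            rgb=np.zeros((1, 1, 3), np.uint8),
            mask=np.full((1, 1), OBJECT, np.uint8),
            species=CLOVER,
        )
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            for _ in range(200):
                sig.augment_sample(tiny, cfg, rng)


class TestEdgeIgnore:
    def test_width_zero_is_identity(self):
        m = _sample().mask
        assert np.array_equal(sig.mark_edge_ignore(m, 0), m)

    def test_all_object_5x5(self):
        m = np.full((5, 5), OBJECT, np.uint8)
        out = sig.mark_edge_ignore(m, 1)
        assert np.sum(out == IGNORE_EDGE) == 16
        assert np.sum(out == OBJECT) == 9
        assert np.all(out[1:-1, 1:-1] == OBJECT)

    def test_single_pixel_becomes_edge(self):
        m = np.full((3, 3), EXCLUDED, np.uint8)
        m[1, 1] = OBJECT
        out = sig.mark_edge_ignore(m, 1)
        assert out[1, 1] == IGNORE_EDGE
        assert not np.any(out == OBJECT)

    @given(st.integers(0, 3), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_chebyshev_brute_force(self, width, seed):
        rng = np.random.default_rng(seed)
        m = rng.choice([OBJECT, EXCLUDED], size=(8, 8), p=[0.6, 0.4]).astype(np.uint8)
        out = sig.mark_edge_ignore(m, width)
        h, w = m.shape
        for y in range(h):
            for x in range(w):
                if m[y, x] != OBJECT:
                    assert out[y, x] == m[y, x]
                    continue
                near_non_object = False
                for dy in range(-width, width + 1):
                    for dx in range(-width, width + 1):
                        yy, xx = y + dy, x + dx
                        if not (0 <= yy < h and 0 <= xx < w) or m[yy, xx] != OBJECT:
                            near_non_object = True
                expected = IGNORE_EDGE if (width > 0 and near_non_object) else OBJECT
                assert out[y, x] == expected


class TestCompose:
    def test_single_species_occlusion_bound(self, fixture_config):
        lib = fixtures.make_sample_library((1, 0, 1), fixture_config, seed=0)
        cfg = sig.SigConfig(n_samples_range=(2, 2), shadow_probability=0.0,
                            scale_jitter=0.0, species_weights=(1.0, 0.0))
        _, labels, _ = sig.compose_image(lib.backgrounds[0], lib, cfg,
                                         np.random.default_rng(1))
        non_bg = labels[labels != BACKGROUND]
        assert set(np.unique(non_bg).tolist()) <= {CLOVER, IGNORE}
        n_object = np.sum(lib.clover[0].mask == OBJECT)
        assert np.sum(labels == CLOVER) <= 2 * n_object

    def test_determinism(self, library, sig_config):
        bg = library.backgrounds[0]
        a = sig.compose_image(bg, library, sig_config, np.random.default_rng(9))
        b = sig.compose_image(bg, library, sig_config, np.random.default_rng(9))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_shadow_fraction_near_half(self, library, sig_config):
        rng = np.random.default_rng(3)
        flags = [
            sig.compose_image(library.backgrounds[0], library, sig_config, rng)[2]["shadow"]
            for _ in range(500)
        ]
        assert 0.4 <= np.mean(flags) <= 0.6

    def test_shadows_never_change_labels(self, library):
        on = sig.SigConfig(n_samples_range=(3, 6), shadow_probability=1.0)
        off = sig.SigConfig(n_samples_range=(3, 6), shadow_probability=0.0)
        bg = library.backgrounds[0]
        _, lab_on, _ = sig.compose_image(bg, library, on, np.random.default_rng(4))
        _, lab_off, _ = sig.compose_image(bg, library, off, np.random.default_rng(4))
        assert np.array_equal(lab_on, lab_off)

    def test_label_conservation_brute_force(self, fixture_config):
        """Each pixel's label re-derives from the topmost covering sample."""
        fix = fixtures.FixtureConfig(image_size=(32, 32), sample_size=16)
        lib = fixtures.make_sample_library((2, 2, 1), fix, seed=5)
        cfg = sig.SigConfig(n_samples_range=(2, 6), record_placements=True)
        _, labels, prov = sig.compose_image(lib.backgrounds[0], lib, cfg,
                                            np.random.default_rng(6))
        expected = np.full((32, 32), BACKGROUND, np.uint8)
        for p in prov["placements"]:  # painter's order
            m, top, left = p["mask"], p["top"], p["left"]
            for y in range(m.shape[0]):
                for x in range(m.shape[1]):
                    yy, xx = top + y, left + x
                    if not (0 <= yy < 32 and 0 <= xx < 32):
                        continue
                    if m[y, x] == OBJECT:
                        expected[yy, xx] = p["species"]
                    elif m[y, x] == IGNORE_EDGE:
                        expected[yy, xx] = IGNORE
        assert np.array_equal(labels, expected)

    def test_empty_library_raises(self, fixture_config):
        lib = fixtures.make_sample_library((0, 0, 1), fixture_config, seed=0)
        with pytest.raises(ValueError):
            sig.compose_image(lib.backgrounds[0], lib, sig.SigConfig(),
                              np.random.default_rng(0))


class TestFlipExpand:
    def test_four_variants_first_identity(self, library, sig_config):
        rgb, lab, _ = sig.compose_image(library.backgrounds[0], library,
                                        sig_config, np.random.default_rng(2))
        out = sig.flip_expand(rgb, lab)
        assert len(out) == 4
        assert np.array_equal(out[0][0], rgb) and np.array_equal(out[0][1], lab)

    def test_involution_and_count_conservation(self, library, sig_config):
        rgb, lab, _ = sig.compose_image(library.backgrounds[0], library,
                                        sig_config, np.random.default_rng(2))
        n_clover = np.sum(lab == CLOVER)
        for frgb, flab in sig.flip_expand(rgb, lab):
            assert np.sum(flab == CLOVER) == n_clover
            # applying the same flip again must restore the original
            again = [v for v in sig.flip_expand(frgb, flab)]
            assert any(np.array_equal(a[0], rgb) and np.array_equal(a[1], lab)
                       for a in again)


class TestBuildDataset:
    def test_totals(self, library, sig_config):
        rgb = library.backgrounds[0]
        lab = np.full(rgb.shape[:2], BACKGROUND, np.uint8)
        spec = sig.DatasetSpec(n_synthetic=5, n_partial=3)
        ds = sig.build_dataset(spec, library, [(rgb, lab)] * 3, sig_config,
                               np.random.default_rng(0))
        assert len(ds) == 5 + 3 * 4 == spec.total
        assert ds.manifest["total"] == 17

    def test_empty_spec(self, library, sig_config):
        ds = sig.build_dataset(sig.DatasetSpec(0, 0), library, [], sig_config,
                               np.random.default_rng(0))
        assert len(ds) == 0 and ds.manifest["total"] == 0

    def test_contamination_guard(self, fixture_config, sig_config):
        test_lib = fixtures.make_sample_library((2, 2, 1), fixture_config,
                                                seed=1, role="test")
        with pytest.raises(ContaminationError):
            sig.build_dataset(sig.DatasetSpec(1, 0), test_lib, [], sig_config,
                              np.random.default_rng(0), expected_role="train")


class TestStratifiedKFold:
    def test_fold_sizes(self):
        groups = {"a": list(range(10)), "b": list(range(10)), "c": list(range(5))}
        folds = sig.stratified_kfold(groups, 5, np.random.default_rng(0))
        sizes = [sum(len(v) for v in f.values()) for f in folds]
        assert sizes == [5, 5, 5, 5, 5]

    def test_k1_is_whole(self):
        groups = {"a": [1, 2, 3]}
        folds = sig.stratified_kfold(groups, 1, np.random.default_rng(0))
        assert sorted(folds[0]["a"]) == [1, 2, 3]

    def test_partition_property(self):
        groups = {"a": list(range(13)), "b": list(range(100, 107))}
        folds = sig.stratified_kfold(groups, 3, np.random.default_rng(1))
        for name, items in groups.items():
            parts = [set(f[name]) for f in folds]
            assert set().union(*parts) == set(items)
            for i in range(len(parts)):
                for j in range(i + 1, len(parts)):
                    assert not parts[i] & parts[j]

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            sig.stratified_kfold({"a": [1, 2]}, 3, np.random.default_rng(0))
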