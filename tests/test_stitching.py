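"""Overlap estimation, strip extraction, rasterisation, round-trips."""
import numpy as np
import pytest
from scipy import ndimage

from swardseg import fixtures, postprocess, stitching
from swardseg.types import CLOVER, GRASS, FrameSequence, UnstitchablePairError


@pytest.fixture(scope="module")
def texture():
    fix = fixtures.FixtureConfig(image_size=(600, 160))
    return fixtures.make_background(fix, np.random.default_rng(12))


@pytest.fixture(scope="module")
def sim(texture):
    cfg = stitching.PassConfig(frame_height_px=128)
    return stitching.simulate_pass(texture, cfg, np.random.default_rng(3))


class TestEstimateOverlap:
    def test_constructed_shift_exact(self, texture):
        a = texture[0:128]
        b = texture[40:168]
        assert stitching.estimate_overlap(a, b) == 128 - 40

    def test_identical_frames_give_max_overlap(self, texture):
        a = texture[0:128]
        assert stitching.estimate_overlap(a, a) == 128

    def test_noise_frames_rejected(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 255, (64, 64, 3)).astype(np.uint8)
        b = rng.integers(0, 255, (64, 64, 3)).astype(np.uint8)
        with pytest.raises(UnstitchablePairError):
            stitching.estimate_overlap(a, b)

    def test_matches_exhaustive_search_on_sim(self, sim):
        """The estimator recovers every simulated inter-frame shift."""
        frames = sim.sequence.frames
        shifts = np.diff(sim.offsets_px)
        for i, true_shift in enumerate(shifts):
            overlap = stitching.estimate_overlap(frames[i], frames[i + 1])
            assert overlap == 128 - true_shift


class TestExtractStrips:
    def test_44_rows_22_strips(self):
        frame = np.zeros((128, 8, 3), np.uint8)
        rows = stitching.extract_strips(frame, 44, 22)
        # 2-row bands; centre convention floor((h-1)/2) picks the first row
        assert list(rows) == list(range(0, 44, 2))

    def test_22_rows_each_own_strip(self):
        rows = stitching.extract_strips(np.zeros((64, 4, 3)), 22, 22)
        assert list(rows) == list(range(22))

    def test_shallow_overlap_clamps(self):
        rows = stitching.extract_strips(np.zeros((64, 4, 3)), 10, 22)
        assert list(rows) == list(range(10))


class TestRasterGrid:
    def test_single_sample_per_cell_identity(self):
        g = stitching.RasterGrid(cell_size=1.0, origin=(0.0, 0.0), shape=(2, 2), n_channels=1)
        g.add(np.array([0.5, 1.5]), np.array([0.5, 0.5]), np.array([[10.0], [20.0]]))
        out = g.finalise()
        assert out[0, 0, 0] == 10 and out[1, 0, 0] == 20
        assert np.isnan(out[0, 1, 0])

    def test_two_samples_average(self):
        g = stitching.RasterGrid(cell_size=1.0, origin=(0.0, 0.0), shape=(1, 1), n_channels=1)
        g.add(np.array([0.2, 0.8]), np.array([0.5, 0.5]), np.array([[10.0], [20.0]]))
        assert g.finalise()[0, 0, 0] == 15.0


class TestRoundTrip:
    def test_constant_texture_stitches_constant(self):
        tex = np.full((400, 64, 3), 137, dtype=np.uint8)
        cfg = stitching.PassConfig(frame_height_px=96)
        sim = stitching.simulate_pass(tex, cfg, np.random.default_rng(1))
        # constant frames defeat correlation; supply ground-truth overlaps
        config = stitching.StitchConfig()
        seq = sim.sequence
        params = []
        base = 0.0
        for i in range(1, len(seq)):
            base += float(seq.encoder_travel[i])
            shift = int(sim.offsets_px[i] - sim.offsets_px[i - 1])
            overlap = 96 - shift
            rows = stitching.extract_strips(seq.frames[i], overlap, config.n_strips)
            params.append(stitching.PairParams(
                frame_index=i, overlap=overlap, shift_px=shift,
                strip_rows=rows, base_mm=base, scale=float(seq.scale[i])))
        grid = stitching.rasterize(seq, params, config)
        out = grid.finalise()
        filled = ~grid.empty_mask
        assert np.all(np.abs(out[filled] - 137.0) < 1e-9)

    def test_rgb_reconstruction_error(self, sim):
        grid, params = stitching.stitch_sequence(sim.sequence)
        out = grid.finalise()
        truth = _downsample_texture(sim, grid)
        filled = ~grid.empty_mask & ~np.isnan(truth[..., 0])
        mae = np.nanmean(np.abs(out[filled] - truth[filled]))
        assert mae < 0.05 * 255

    def test_mask_votes_match_brute_force(self, sim):
        rng = np.random.default_rng(7)
        label_tex = _label_texture(sim.texture.shape[:2], rng)
        masks = [label_tex[o : o + 128] for o in sim.offsets_px]
        _, params = stitching.stitch_sequence(sim.sequence)
        classes, grid = stitching.stitch_mask(masks, sim.sequence, params, n_classes=3)
        # brute-force vote tally with identical placement arithmetic
        votes = np.zeros(grid.shape + (3,))
        for p in params:
            m = masks[p.frame_index]
            travel = float(sim.sequence.encoder_travel[p.frame_index])
            y_mm, x_mm = stitching.place_strips(
                p.strip_rows, m.shape[1], p.base_mm, travel, p.shift_px, p.scale)
            for row, y in zip(p.strip_rows, y_mm):
                iy = int(np.floor((y - grid.origin[0]) / grid.cell_size))
                ix = np.floor((x_mm - grid.origin[1]) / grid.cell_size).astype(int)
                for col, cx in enumerate(ix):
                    if 0 <= iy < grid.shape[0] and 0 <= cx < grid.shape[1]:
                        votes[iy, cx, m[row, col]] += 1
        filled = votes.sum(axis=-1) > 0
        assert np.array_equal(classes[filled], votes[filled].argmax(axis=-1))
        assert np.all(classes[~filled] == 255)

    def test_relabelling_permutation_invariance(self, sim):
        rng = np.random.default_rng(8)
        label_tex = _label_texture(sim.texture.shape[:2], rng)
        masks = [label_tex[o : o + 128] for o in sim.offsets_px]
        _, params = stitching.stitch_sequence(sim.sequence)
        base, grid = stitching.stitch_mask(masks, sim.sequence, params, n_classes=3)
        perm = np.array([2, 0, 1])
        permuted_masks = [perm[m] for m in masks]
        out, _ = stitching.stitch_mask(permuted_masks, sim.sequence, params, n_classes=3)
        votes = grid.finalise()
        top2 = np.sort(np.nan_to_num(votes), axis=-1)[..., -2:]
        untied = (~grid.empty_mask) & (top2[..., 1] > top2[..., 0])
        assert untied.sum() > 0.9 * (~grid.empty_mask).sum()
        assert np.array_equal(out[untied], perm[base[untied]])

    def test_end_to_end_clover_fraction(self, sim):
        rng = np.random.default_rng(9)
        label_tex = _label_texture(sim.texture.shape[:2], rng)
        masks = [label_tex[o : o + 128] for o in sim.offsets_px]
        _, params = stitching.stitch_sequence(sim.sequence)
        classes, grid = stitching.stitch_mask(masks, sim.sequence, params, n_classes=3)
        stitched = postprocess.clover_fraction(
            np.where(classes == 255, 2, classes), region=~grid.empty_mask)
        lo, hi = sim.offsets_px[0], sim.offsets_px[-1] + 128
        covered = label_tex[lo:hi]
        truth = np.sum(covered == CLOVER) / np.sum((covered == CLOVER) | (covered == GRASS))
        assert abs(stitched - truth) < 0.02


def _label_texture(shape, rng):
    """Occlusion-free clover/grass blob map covering the whole texture."""
    field = ndimage.gaussian_filter(rng.normal(size=shape), 12.0)
    return np.where(field > 0, CLOVER, GRASS).astype(np.uint8)


def _downsample_texture(sim, grid):
    """Exact cell means of the ground-truth texture, oracle for the raster."""
    tex = sim.texture.astype(np.float64)
    scale = float(sim.sequence.scale[0])
    rows = np.arange(tex.shape[0]) / scale
    cols = (np.arange(tex.shape[1]) + 0.5) / scale
    iy = np.floor((rows - grid.origin[0]) / grid.cell_size).astype(int)
    ix = np.floor((cols - grid.origin[1]) / grid.cell_size).astype(int)
    sums = np.zeros(grid.shape + (3,))
    counts = np.zeros(grid.shape)
    ok_y = (iy >= 0) & (iy < grid.shape[0])
    ok_x = (ix >= 0) & (ix < grid.shape[1])
    for r in np.nonzero(ok_y)[0]:
        for c in np.nonzero(ok_x)[0]:
            sums[iy[r], ix[c]] += tex[r, c]
            counts[iy[r], ix[c]] += 1
    out = np.full(grid.shape + (3,), np.nan)
    filled = counts > 0
    out[filled] = sums[filled] / counts[filled, None]
    return out
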