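"""Equalization, CLAHE, gradients, surface labeling and coloring."""

import numpy as np
import pytest

from periscan import crop, enhance, synth
from periscan.enhance import Label, SurfaceParams


def _brute_equalize(gray):
    """Per-pixel oracle: out = floor(255 * cdf(g)) evaluated longhand."""
    g = gray.astype(int)
    out = np.empty_like(g)
    n = g.size
    for lvl in np.unique(g):
        cdf = (g <= lvl).sum() / n
        out[g == lvl] = int(np.floor(255.0 * cdf))
    return out.astype(np.uint8)


class TestEqualize:
    def test_constant_image_maps_to_255(self):
        # the sole occupied level has cdf 1, and the plain scaled-cdf
        # convention keeps it: every pixel becomes 255
        out = enhance.equalize_histogram(np.full((10, 10), 37, dtype=np.uint8))
        assert (out == 255).all()

    def test_two_level_image(self):
        img = np.array([[10, 10], [200, 200]], dtype=np.uint8)
        out = enhance.equalize_histogram(img)
        assert set(out[img == 10]) == {127}   # floor(255 * 0.5)
        assert set(out[img == 200]) == {255}  # floor(255 * 1.0)

    def test_uniform_ramp_closed_form(self):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        out = enhance.equalize_histogram(img)
        expected = np.floor(255.0 * (np.arange(256) + 1) / 256).astype(np.uint8)
        assert np.array_equal(out.ravel(), expected)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(23, 17)).astype(np.uint8)
        assert np.array_equal(enhance.equalize_histogram(img), _brute_equalize(img))

    def test_monotone_in_input_level(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, size=(40, 40)).astype(np.uint8)
        out = enhance.equalize_histogram(img)
        flat_in, flat_out = img.ravel(), out.ravel()
        order = np.argsort(flat_in, kind="stable")
        assert (np.diff(flat_out[order].astype(int)) >= 0).all()

    def test_near_uniform_output_cdf(self):
        """With >= 256 distinct-valued pixels the output cdf is within
        1/L of uniform at every level."""
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        out = enhance.equalize_histogram(img)
        cdf = np.cumsum(np.bincount(out.ravel(), minlength=256)) / out.size
        uniform = (np.arange(256) + 1) / 256
        assert np.abs(cdf - uniform).max() <= 1 / 256 + 1e-12


class TestAdaptiveEqualize:
    def test_constant_image_stays_constant(self):
        img = np.full((32, 32), 90, dtype=np.uint8)
        out = enhance.adaptive_equalize(img, tiles=(4, 4), clip_limit=0.5)
        assert len(np.unique(out)) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_single_tile_equals_global(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(30, 28)).astype(np.uint8)
        ahe = enhance.adaptive_equalize(img, tiles=(1, 1), clip_limit=1.0)
        he = enhance.equalize_histogram(img)
        assert np.abs(ahe.astype(int) - he.astype(int)).max() <= 1

    def test_checkerboard_keeps_local_contrast(self):
        tile = np.kron(np.indices((8, 8)).sum(axis=0) % 2, np.ones((4, 4)))
        img = (tile * 255).astype(np.uint8)
        out = enhance.adaptive_equalize(img, tiles=(4, 4), clip_limit=0.01)
        for i in range(4):
            for j in range(4):
                sub = out[i * 8:(i + 1) * 8, j * 8:(j + 1) * 8]
                assert sub.min() < 64 and sub.max() > 192

    def test_tiny_tiles_rejected(self):
        with pytest.raises(ValueError):
            enhance.adaptive_equalize(np.zeros((8, 8), dtype=np.uint8),
                                      tiles=(8, 8))


class TestDifferenceAndGradient:
    def test_difference_identity_and_arithmetic(self):
        a = np.full((5, 5), 200, dtype=np.uint8)
        b = np.full((5, 5), 50, dtype=np.uint8)
        assert (enhance.enhancement_difference(a, a) == 0).all()
        assert (enhance.enhancement_difference(a, b) == 150).all()
        assert (enhance.enhancement_difference(b, a) == 150).all()  # absolute

    def test_difference_random_oracle(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 256, (12, 9)).astype(np.uint8)
        b = rng.integers(0, 256, (12, 9)).astype(np.uint8)
        expected = np.array([[abs(int(x) - int(y)) for x, y in zip(ra, rb)]
                             for ra, rb in zip(a, b)])
        assert np.array_equal(enhance.enhancement_difference(a, b), expected)

    def test_difference_shape_mismatch(self):
        with pytest.raises(ValueError):
            enhance.enhancement_difference(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_gradient_constant_zero(self):
        assert (enhance.gradient_magnitude(np.full((6, 6), 7.0)) == 0).all()

    def test_gradient_step_edge_local(self):
        img = np.zeros((8, 8))
        img[:, 4:] = 255.0
        g = enhance.gradient_magnitude(img)
        nz_cols = np.unique(np.nonzero(g)[1])
        assert set(nz_cols) == {3, 4}

    def test_gradient_unit_ramp(self):
        img = np.tile(np.arange(10, dtype=float), (6, 1))
        g = enhance.gradient_magnitude(img)
        assert np.allclose(g[1:-1, 1:-1], 1.0)


class TestClassifySurface:
    def test_flat_bright_image_all_implant(self):
        img = np.full((20, 20), 200.0)
        grad = np.zeros_like(img)
        labels = enhance.classify_surface(
            img, grad, SurfaceParams(range_threshold=10, z_threshold=128,
                                     gate_value=30))
        assert (labels == Label.IMPLANT).all()

    def test_gate_wins_over_everything(self):
        img = np.full((10, 10), 10.0)
        grad = np.zeros_like(img)
        grad[5, 5] = 500.0  # huge local range
        labels = enhance.classify_surface(
            img, grad, SurfaceParams(range_threshold=10, z_threshold=128,
                                     gate_value=30))
        assert (labels == Label.BACKGROUND).all()

    def test_synthetic_half_matches_generator_regions(self):
        """Non-edge pixels agree with the generator's region truth on
        at least 95% of the half."""
        im = synth.generate_radiograph(synth.SynthSpec(seed=13))
        box = im.boxes[0]
        c = crop.crop_implant(im.pixels, box, margin=20)
        grad = enhance.gradient_magnitude(c.pixels)
        labels = enhance.classify_surface(
            c.pixels, grad, SurfaceParams(range_threshold=60.0,
                                          z_threshold=150.0, gate_value=30.0))
        y1, x1 = int(box.y), int(max(0, box.x - 20))
        shaft = im.truth["shaft"][0][y1:y1 + labels.shape[0], x1:x1 + labels.shape[1]]
        flat = labels != Label.EDGE
        expected = np.where(shaft, Label.IMPLANT, Label.GUM)
        agree = (labels[flat] == expected[flat]).mean()
        assert agree >= 0.95


class TestColorize:
    def test_all_implant_green_plus_red_row(self):
        labels = np.full((10, 8), Label.IMPLANT, dtype=np.uint8)
        base = np.zeros((10, 8), dtype=np.uint8)
        out = enhance.colorize(base, labels, reference_row=3)
        assert (out.pixels[3] == (255, 0, 0)).all()
        others = np.delete(out.pixels, 3, axis=0)
        assert (others == (0, 255, 0)).all()

    def test_palette_is_exact(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 4, size=(30, 20)).astype(np.uint8)
        base = rng.integers(0, 256, size=(30, 20)).astype(np.uint8)
        out = enhance.colorize(base, labels, reference_row=0)
        body = out.pixels[1:]
        lab = labels[1:]
        palette = {(0, 255, 0), (255, 165, 0), (0, 0, 0)}
        for rgb, code in zip(body.reshape(-1, 3), lab.ravel()):
            t = tuple(int(v) for v in rgb)
            if code == Label.EDGE:
                assert t[0] == t[1] == t[2]  # edges keep their gray
            else:
                assert t in palette

    def test_row_zero_boundary(self):
        labels = np.full((5, 5), Label.BACKGROUND, dtype=np.uint8)
        out = enhance.colorize(np.zeros((5, 5), dtype=np.uint8), labels, 0)
        assert (out.pixels[0] == (255, 0, 0)).all()
        assert (out.pixels[1:] == 0).all()

    def test_bad_row_rejected(self):
        labels = np.zeros((5, 5), dtype=np.uint8)
        with pytest.raises(ValueError):
            enhance.colorize(np.zeros((5, 5), dtype=np.uint8), labels, 9)


class TestPreprocessHalf:
    def _halves(self, seed, sides):
        im = synth.generate_radiograph(
            synth.SynthSpec(seed=seed, defect_sides=(sides,),
                            defect_darkening=80))
        c = crop.crop_implant(im.pixels, im.boxes[0], margin=20)
        line = crop.fit_midline(crop.binarize_implant(c))
        return crop.split_halves(c, line)

    def test_deterministic(self):
        left, _ = self._halves(21, (True, False))
        a = enhance.preprocess_half(left, platform_row=0)
        b = enhance.preprocess_half(left, platform_row=0)
        assert np.array_equal(a.pixels, b.pixels)
        assert np.array_equal(a.label_map, b.label_map)

    def test_damaged_half_darker_coronal_region(self):
        """The wedge suppresses orange (gum) coverage next to the
        coronal threads relative to the same geometry rendered healthy."""
        damaged_l, _ = self._halves(21, (True, False))
        healthy_l, _ = self._halves(21, (False, False))
        params = SurfaceParams(range_threshold=60.0, z_threshold=150.0,
                               gate_value=55.0)
        top = damaged_l.pixels.shape[0] // 2
        e_dam = enhance.preprocess_half(damaged_l, params=params)
        e_hea = enhance.preprocess_half(healthy_l, params=params)
        orange_dam = (e_dam.label_map[:top] == Label.GUM).mean()
        orange_hea = (e_hea.label_map[:top] == Label.GUM).mean()
        assert orange_hea - orange_dam > 0.10

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            enhance.preprocess_half(np.zeros((1, 1), dtype=np.uint8))
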