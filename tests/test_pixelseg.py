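"""Nearest-colour pixel classification and exclusion masking."""

import numpy as np
import pytest

from mucofract.field import RGBField
from mucofract.pixelseg import (
    CLASS_NAMES,
    EXCLUDED_LABEL,
    ClassPalette,
    apply_exclusion,
    segment_field,
)
from mucofract.synthgen import generate_ihc_field


def _exact_colour_image(palette, proportions, side=40):
    """Image whose pixels equal palette colours in given class proportions."""
    cols = palette.as_array().astype(np.uint8)
    n = side * side
    counts = [int(round(p / 100 * n)) for p in proportions]
    counts[-1] = n - sum(counts[:-1])
    flat = np.concatenate([np.tile(c, (k, 1)) for c, k in zip(cols, counts)])
    return flat.reshape(side, side, 3)


class TestSegmentField:
    def test_exact_palette_colours_give_exact_percentages(self, default_palette):
        img = _exact_colour_image(default_palette, [10, 30, 40, 20])
        cm = segment_field(img, default_palette)
        for name, expected in zip(CLASS_NAMES, [10, 30, 40, 20]):
            assert cm.area_percent[name] == pytest.approx(expected, abs=1e-9)
        assert sum(cm.area_percent.values()) == pytest.approx(100.0, abs=1e-6)

    def test_noisy_synthetic_field_recovered_within_two_points(self, small_ihc_field, default_palette):
        f = small_ihc_field  # rendered with sigma = 8 colour noise
        cm = segment_field(f.image, default_palette, exclusion_mask=f.exclusion_mask)
        for name in CLASS_NAMES:
            truth = 100 * f.truth.class_area_fractions[name]
            assert abs(cm.area_percent[name] - truth) < 2.0

    def test_all_pixels_excluded_is_an_error(self, default_palette):
        img = np.zeros((8, 8, 3), np.uint8)
        with pytest.raises(ValueError, match="empty field after exclusion"):
            segment_field(img, default_palette, exclusion_mask=np.ones((8, 8), bool))

    def test_mask_dimension_mismatch_rejected(self, default_palette):
        img = np.zeros((8, 8, 3), np.uint8)
        with pytest.raises(ValueError, match="mask shape"):
            segment_field(img, default_palette, exclusion_mask=np.zeros((4, 4), bool))

    def test_duplicate_palette_colours_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            ClassPalette(
                positive_nucleus=(10, 10, 10),
                negative_nucleus=(10, 10, 10),
                cytoplasm=(200, 0, 0),
                background=(255, 255, 255),
            )

    def test_swapping_reference_colours_swaps_percentages(self, default_palette):
        """Permutation equivariance of the class -> colour anchoring."""
        img = _exact_colour_image(default_palette, [10, 30, 40, 20])
        swapped = ClassPalette(
            positive_nucleus=default_palette.negative_nucleus,
            negative_nucleus=default_palette.positive_nucleus,
            cytoplasm=default_palette.cytoplasm,
            background=default_palette.background,
        )
        a = segment_field(img, default_palette).area_percent
        b = segment_field(img, swapped).area_percent
        assert b["positive_nucleus"] == pytest.approx(a["negative_nucleus"], abs=1e-9)
        assert b["negative_nucleus"] == pytest.approx(a["positive_nucleus"], abs=1e-9)
        assert b["cytoplasm"] == pytest.approx(a["cytoplasm"], abs=1e-9)

    def test_downsampling_leaves_percentages_unchanged(self, default_palette):
        base = _exact_colour_image(default_palette, [10, 30, 40, 20], side=40)
        big = np.kron(base, np.ones((2, 2, 1))).astype(np.uint8)  # 2x2 blocks
        a = segment_field(big, default_palette).area_percent
        b = segment_field(big[::2, ::2], default_palette).area_percent
        for name in CLASS_NAMES:
            assert abs(a[name] - b[name]) <= 0.5

    def test_classification_is_deterministic(self, small_ihc_field, default_palette):
        f = small_ihc_field
        a = segment_field(f.image, default_palette)
        b = segment_field(f.image, default_palette)
        assert np.array_equal(a.labels, b.labels)

    def test_rgb_colour_space_switch(self, default_palette):
        img = _exact_colour_image(default_palette, [25, 25, 25, 25])
        cm = segment_field(img, default_palette, color_space="rgb")
        assert cm.area_percent["cytoplasm"] == pytest.approx(25.0, abs=1e-9)
        with pytest.raises(ValueError, match="color_space"):
            segment_field(img, default_palette, color_space="hsv")


class TestApplyExclusion:
    def test_all_zero_mask_keeps_everything(self, small_ihc_field, default_palette):
        f = RGBField(small_ihc_field.image.pixels)
        out = apply_exclusion(f, np.zeros(f.shape, np.uint8))
        cm = segment_field(out, default_palette)
        assert cm.n_pixels_excluded == 0
        assert np.array_equal(out.pixels, f.pixels)

    def test_quarter_mask_counting_identity(self, default_palette):
        img = np.full((40, 40, 3), 255, np.uint8)
        mask = np.zeros((40, 40), bool)
        mask[:20, :20] = True  # exactly 25%
        f = apply_exclusion(RGBField(img), mask)
        cm = segment_field(f, default_palette)
        assert cm.n_pixels_excluded == cm.n_pixels_total // 4
        assert (cm.labels == EXCLUDED_LABEL).sum() == cm.n_pixels_excluded

    def test_non_binary_mask_rejected(self):
        img = RGBField(np.zeros((8, 8, 3), np.uint8))
        with pytest.raises(ValueError, match="binary"):
            apply_exclusion(img, np.arange(64).reshape(8, 8))

    def test_lamina_propria_nuclei_never_reach_the_counts(self, default_palette):
        """Distractor nuclei inside the exclusion mask leave the census."""
        f = generate_ihc_field(
            n_positive=0, n_negative=0, n_lamina_nuclei=10,
            noise_sigma=0, canvas=(300, 300), seed=2,
        )
        neg_idx = CLASS_NAMES.index("negative_nucleus")
        assert (f.labels[f.exclusion_mask] == neg_idx).any()  # distractors rendered
        cm = segment_field(f.image, default_palette, exclusion_mask=f.exclusion_mask)
        assert cm.area_percent["negative_nucleus"] == 0.0
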