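"""The generators must be exact about their ground truth and reproducible."""

import numpy as np
import pytest

from ecmarch import synthetic_data as sd
from ecmarch.morphometry import measure_cell
from ecmarch.orientation_analysis import mean_orientation


class TestFiberImage:
    def test_single_horizontal_bar_mask_and_porosity(self):
        spec = sd.FiberImageSpec(
            image_size=(100, 120), n_fibers=1, diameter_mean=5, diameter_sd=0,
            orientation_mu=0, orientation_kappa=1e9, blur_sigma=0, noise_sd=0, seed=1,
        )
        _, truth = sd.generate_fiber_image(spec)
        mask = truth.true_mask.pixels
        # a horizontal bar: 5 full rows of fiber
        rows_with_fiber = np.flatnonzero(mask.any(axis=1))
        assert len(rows_with_fiber) == 5
        assert mask[rows_with_fiber].all()
        assert truth.true_porosity == pytest.approx(1 - (5 * 120) / (100 * 120))

    def test_true_porosity_is_exact_pixel_fraction(self):
        _, truth = sd.generate_fiber_image(sd.FiberImageSpec(seed=9))
        assert truth.true_porosity == 1 - truth.true_mask.pixels.mean()

    def test_isotropic_angles_have_small_resultant_length(self):
        # Monte-Carlo bound: doubled-angle mean resultant length of 200
        # uniform fiber angles stays below 0.15
        spec = sd.FiberImageSpec(n_fibers=200, orientation_kappa=0, seed=11)
        _, truth = sd.generate_fiber_image(spec)
        doubled = np.radians([2 * f.angle for f in truth.fibers])
        r = np.hypot(np.cos(doubled).mean(), np.sin(doubled).mean())
        assert r < 0.15

    def test_concentrated_angles_recover_mu(self):
        spec = sd.FiberImageSpec(
            n_fibers=500, orientation_mu=20, orientation_kappa=50, seed=11
        )
        _, truth = sd.generate_fiber_image(spec)
        mu = mean_orientation([f.angle for f in truth.fibers])
        assert abs(mu - 20) < 3

    def test_all_angles_in_range(self):
        _, truth = sd.generate_fiber_image(sd.FiberImageSpec(n_fibers=100, seed=2))
        assert all(-90 <= f.angle < 90 for f in truth.fibers)

    def test_determinism(self):
        spec = sd.FiberImageSpec(seed=42)
        img1, tr1 = sd.generate_fiber_image(spec)
        img2, tr2 = sd.generate_fiber_image(sd.FiberImageSpec(seed=42))
        np.testing.assert_array_equal(img1.pixels, img2.pixels)
        np.testing.assert_array_equal(tr1.true_mask.pixels, tr2.true_mask.pixels)

    def test_image_in_unit_range(self):
        img, _ = sd.generate_fiber_image(sd.FiberImageSpec(noise_sd=0.3, seed=0))
        assert img.pixels.min() >= 0 and img.pixels.max() <= 1

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"n_fibers": 0}, "n_fibers"),
            ({"diameter_mean": -1}, "diameter_mean"),
            ({"image_size": (32, 32)}, "image_size"),
            ({"orientation_kappa": -1}, "orientation_kappa"),
            ({"fiber_intensity": 0.5, "background_intensity": 0.5}, "fiber_intensity"),
        ],
    )
    def test_validation_names_the_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            sd.FiberImageSpec(**kwargs)


class TestCellOutlines:
    def test_circle_area_close_to_analytic(self):
        cells = sd.generate_cell_outlines(1, elongation_mean=1.0, radius_mean=10, seed=0)
        rec = measure_cell(cells[0].outline)
        assert rec.area == pytest.approx(np.pi * 100, rel=1e-3)

    def test_count_and_reproducibility(self):
        a = sd.generate_cell_outlines(3, elongation_mean=1.5, seed=7)
        b = sd.generate_cell_outlines(3, elongation_mean=1.5, seed=7)
        assert len(a) == 3
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.outline.vertices, cb.outline.vertices)

    def test_recorded_elongation_exact(self):
        cells = sd.generate_cell_outlines(2, elongation_mean=2.0, seed=1)
        for c in cells:
            assert c.true_aspect_ratio == pytest.approx(2.0)

    def test_rejects_elongation_below_one(self):
        with pytest.raises(ValueError, match="elongation"):
            sd.generate_cell_outlines(2, elongation_mean=0.5, seed=0)


class TestRheologySweepGen:
    def test_maxwell_identity_at_unit_frequency(self):
        spec = sd.MaxwellSpec(
            modulus_scale=100, relaxation_time=1.0, noise_sd=0,
            frequency_grid=(0.5, 1.0, 2.0),
        )
        sweep = sd.generate_rheology_sweep(spec)
        i = list(spec.frequency_grid).index(1.0)
        assert sweep.storage_modulus[i] == pytest.approx(50.0)
        assert sweep.loss_modulus[i] == pytest.approx(50.0)

    def test_loss_dominates_at_low_frequency(self):
        spec = sd.MaxwellSpec(relaxation_time=1.0, noise_sd=0, frequency_grid=(0.1, 1.0, 10.0))
        sweep = sd.generate_rheology_sweep(spec)
        assert sweep.loss_modulus[0] / sweep.storage_modulus[0] == pytest.approx(10.0)

    def test_moduli_strictly_positive(self):
        sweep = sd.generate_rheology_sweep(sd.MaxwellSpec(noise_sd=0.05, seed=1))
        assert (sweep.storage_modulus > 0).all() and (sweep.loss_modulus > 0).all()

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError, match="frequency_grid"):
            sd.MaxwellSpec(frequency_grid=(1.0, 1.0, 2.0))


class TestExpressionTableGen:
    def test_planted_folds_beyond_effect(self):
        spec = sd.ExpressionSimSpec(n_genes=500, n_up=10, n_down=5, effect_fold=3.0, seed=0)
        table = sd.generate_expression_table(spec)
        up = table[table["planted"] == "up"]
        down = table[table["planted"] == "down"]
        assert len(up) == 10 and (up["fold_change"] >= 3.0).all()
        assert len(down) == 5 and (down["fold_change"] <= 1 / 3.0).all()
        assert (up["biotype"] == "protein_coding").all()
        assert (down["biotype"] == "protein_coding").all()

    def test_pure_protein_coding_table(self):
        spec = sd.ExpressionSimSpec(
            n_genes=100,
            biotype_proportions={"protein_coding": 1.0},
            n_up=5, n_down=5, seed=1,
        )
        table = sd.generate_expression_table(spec)
        assert (table["biotype"] == "protein_coding").all()

    def test_determinism(self):
        spec = sd.ExpressionSimSpec(seed=3)
        a = sd.generate_expression_table(spec)
        b = sd.generate_expression_table(sd.ExpressionSimSpec(seed=3))
        assert a.equals(b)

    def test_planted_counts_cannot_exceed_coding_pool(self):
        with pytest.raises(ValueError, match="protein-coding pool"):
            sd.ExpressionSimSpec(n_genes=100, n_up=60, n_down=60)

    def test_biotype_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="biotype_proportions"):
            sd.ExpressionSimSpec(biotype_proportions={"protein_coding": 0.5})


class TestCytokineArrayGen:
    def test_true_level_matches_formula(self):
        table = sd.generate_cytokine_array(20, background=2.0, reference=20.0, seed=0)
        mean_spots = (table["spot_1"] + table["spot_2"]) / 2
        expected = ((mean_spots - 2.0) / 20.0).clip(lower=0)
        np.testing.assert_allclose(table["true_level"], expected)

    def test_determinism(self):
        a = sd.generate_cytokine_array(10, seed=5)
        b = sd.generate_cytokine_array(10, seed=5)
        assert a.equals(b)

    def test_reference_must_be_positive(self):
        with pytest.raises(ValueError, match="reference"):
            sd.generate_cytokine_array(5, reference=0.0)
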