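"""Quantification: background, blur, mask assignment, morphometrics."""

import dataclasses

import numpy as np
import pytest

import lipidflux as lf
from lipidflux.scene import FieldImage, OrganelleMaskSet



def make_image(pixels, **kw):
    kw.setdefault("probe_id", "p")
    kw.setdefault("chase_time", 4.0)
    return FieldImage(pixels=np.asarray(pixels, dtype=float), **kw)


def flat_masks(shape, values):
    """Spatially uniform probability masks (plus an all-true cell mask)."""
    masks = {
        c: np.full(shape, v, dtype=np.float32)
        for c, v in zip(lf.COMPARTMENTS, values)
    }
    return OrganelleMaskSet(masks=masks, cell_mask=np.ones(shape, dtype=bool))


class TestBackground:
    def test_pure_background_goes_to_zero(self):
        img = make_image(np.full((64, 64), 7.0))
        cell = np.zeros((64, 64), dtype=bool)
        cell[16:48, 16:48] = True
        out = lf.background_correct(img, cell)
        assert not out.pixels.any()
        assert out.provenance["background"] == 7.0

    def test_signal_integral_preserved_after_correction(self):
        img = np.full((64, 64), 3.0)
        cell = np.zeros((64, 64), dtype=bool)
        cell[20:40, 20:40] = True
        img[22:30, 22:30] += 10.0
        out = lf.background_correct(make_image(img), cell)
        assert out.pixels.sum() == pytest.approx(10.0 * 64)

    def test_full_cell_mask_requires_constant(self):
        img = make_image(np.full((64, 64), 3.0))
        full = np.ones((64, 64), dtype=bool)
        with pytest.raises(ValueError):
            lf.background_correct(img, full)
        cfg = lf.QuantConfig(background_constant=1.0)
        with pytest.warns(RuntimeWarning):
            out = lf.background_correct(img, full, cfg)
        assert np.allclose(out.pixels, 2.0)

    def test_no_uv_field_corrects_to_near_zero(self):
        cfg = lf.SceneConfig(seed=9)
        m = lf.generate_organelle_masks(cfg)
        img = lf.render_field(m, [1.0, 0, 0, 0], cfg, 4.0, condition="no-UV")
        out = lf.background_correct(img, m.cell_mask)
        # clipped noise only: mean well below one noise SD
        noise_sd = np.sqrt(cfg.background_level + cfg.gaussian_sd**2)
        assert out.pixels[m.cell_mask].mean() < noise_sd


class TestBlur:
    def test_sigma_zero_is_identity(self, rng):
        img = make_image(rng.random((32, 32)))
        assert lf.blur(img, 0.0) is img

    def test_negative_sigma_rejected(self, rng):
        with pytest.raises(ValueError):
            lf.blur(make_image(rng.random((8, 8))), -1.0)

    def test_delta_matches_sampled_gaussian_kernel(self):
        sigma = 4.0
        img = np.zeros((129, 129))
        img[64, 64] = 1.0
        out = lf.blur(make_image(img), sigma).pixels
        # oracle: separable discrete Gaussian, truncated like the filter
        r = int(4.0 * sigma + 0.5)
        x = np.arange(-r, r + 1)
        k1 = np.exp(-(x**2) / (2 * sigma**2))
        k1 /= k1.sum()
        want = np.zeros_like(img)
        want[64 - r : 64 + r + 1, 64 - r : 64 + r + 1] = np.outer(k1, k1)
        assert np.abs(out - want).max() < 1e-6

    def test_constant_image_unchanged(self):
        img = make_image(np.full((40, 40), 2.5))
        assert np.abs(lf.blur(img, 4.0).pixels - 2.5).max() < 1e-9

    def test_interior_mass_conserved(self):
        img = np.zeros((128, 128))
        img[40:80, 40:80] = 3.0
        out = lf.blur(make_image(img), 4.0).pixels
        assert out.sum() == pytest.approx(img.sum(), rel=1e-6)


class TestMeanIntensity:
    def test_constant_value_over_mask(self):
        img = make_image(np.full((32, 32), 5.0))
        mask = np.zeros((32, 32), dtype=bool)
        mask[4:10, 4:10] = True
        assert lf.mean_cell_intensity(img, mask) == 5.0
        with pytest.raises(ValueError):
            lf.mean_cell_intensity(img, np.zeros((32, 32), dtype=bool))

    def test_doubled_signal_doubles_intensity(self, noiseless_config):
        cfg = dataclasses.replace(noiseless_config, background_level=0.0)
        cfg2 = dataclasses.replace(cfg, total_signal=2 * cfg.total_signal)
        m = lf.generate_organelle_masks(cfg)
        f = [0.5, 0.1, 0.1, 0.3]
        i1 = lf.render_field(m, f, cfg, 10.0)
        i2 = lf.render_field(m, f, cfg2, 10.0)
        r = lf.mean_cell_intensity(i2, m.cell_mask) / lf.mean_cell_intensity(
            i1, m.cell_mask
        )
        assert r == pytest.approx(2.0, rel=1e-9)

    def test_no_uv_much_dimmer_than_uv(self):
        cfg = lf.SceneConfig(seed=14)
        m = lf.generate_organelle_masks(cfg)
        qc = lf.QuantConfig()
        vals = {}
        for cond in ("UV", "no-UV"):
            img = lf.render_field(m, [1.0, 0, 0, 0], cfg, 4.0, condition=cond)
            corr = lf.blur(lf.background_correct(img, m.cell_mask, qc), qc.blur_sigma)
            vals[cond] = lf.mean_cell_intensity(corr, m.cell_mask)
        assert vals["no-UV"] <= 0.05 * vals["UV"]


class TestAssignment:
    def test_disjoint_masks_keep_signal_separate(self):
        shape = (32, 32)
        masks = {c: np.zeros(shape, dtype=np.float32) for c in lf.COMPARTMENTS}
        masks["Endo"][10:20, 10:20] = 1.0
        masks["PM"][0:5, :] = 1.0
        ms = OrganelleMaskSet(masks=masks, cell_mask=np.ones(shape, dtype=bool))
        img = np.zeros(shape)
        img[12:18, 12:18] = 4.0
        sums = lf.assign_signal(make_image(img), ms)
        assert sums["Endo"] == pytest.approx(img.sum())
        assert sums["PM"] == sums["ER"] == sums["Golgi"] == 0.0

    def test_proportional_split_follows_probabilities(self):
        ms = flat_masks((16, 16), (0.75, 0.25, 0.0, 0.0))
        img = make_image(np.full((16, 16), 1.0))
        sums = lf.assign_signal(img, ms)
        assert sums["PM"] / sums["Endo"] == pytest.approx(3.0)

    def test_argmax_gives_winner_everything(self):
        ms = flat_masks((16, 16), (0.75, 0.25, 0.0, 0.0))
        img = make_image(np.full((16, 16), 1.0))
        sums = lf.assign_signal(img, ms, lf.QuantConfig(overlap_policy="argmax"))
        assert sums["PM"] == pytest.approx(256.0)
        assert sums["Endo"] == 0.0

    def test_assignment_conserves_total_exactly(self, rng):
        shape = (48, 48)
        masks = {
            c: rng.random(shape).astype(np.float32) * (rng.random(shape) > 0.4)
            for c in lf.COMPARTMENTS
        }
        ms = OrganelleMaskSet(masks=masks, cell_mask=np.ones(shape, dtype=bool))
        img = make_image(rng.random(shape) * 10)
        sums = lf.assign_signal(img, ms)
        assert sum(sums.values()) == pytest.approx(img.pixels.sum(), rel=1e-12)

    def test_scaling_image_scales_sums_not_fractions(self, rng):
        ms = flat_masks((16, 16), (0.3, 0.3, 0.2, 0.2))
        img = rng.random((16, 16))
        s1 = lf.assign_signal(make_image(img), ms)
        s3 = lf.assign_signal(make_image(3 * img), ms)
        for c in lf.COMPARTMENTS:
            assert s3[c] == pytest.approx(3 * s1[c])
        assert np.allclose(lf.relative_fractions(s1), lf.relative_fractions(s3))

    def test_empty_masks_and_shape_mismatch_rejected(self, rng):
        ms = flat_masks((16, 16), (0.0, 0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            lf.assign_signal(make_image(np.ones((16, 16))), ms)
        ms2 = flat_masks((16, 16), (0.5, 0.1, 0.1, 0.1))
        with pytest.raises(ValueError):
            lf.assign_signal(make_image(np.ones((8, 8))), ms2)


class TestFractions:
    def test_uniform_sums_normalise_to_quarters(self):
        f = lf.relative_fractions(dict(PM=10, Endo=10, Golgi=10, ER=10))
        assert np.allclose(f, 0.25)

    def test_single_compartment_takes_all(self):
        f = lf.relative_fractions(dict(PM=3.7, Endo=0, Golgi=0, ER=0))
        assert np.allclose(f, [1, 0, 0, 0])

    def test_all_zero_is_an_error(self):
        with pytest.raises(ValueError):
            lf.relative_fractions(dict(PM=0, Endo=0, Golgi=0, ER=0))


class TestEndosomeMorphometrics:
    def test_counts_disjoint_discs(self):
        cfg = lf.SceneConfig(n_cells=1, endosome_count=4, seed=3)
        m = lf.generate_organelle_masks(cfg)
        morph = lf.endosome_morphometrics(m.masks["Endo"])
        assert morph.object_count == m.n_objects["Endo"] == 4
        assert all(s > 0 for s in morph.sizes)

    def test_empty_mask_counts_zero(self):
        morph = lf.endosome_morphometrics(np.zeros((32, 32)))
        assert morph.object_count == 0 and morph.sizes == []

    def test_overlapping_discs_merge_into_one(self):
        mask = np.zeros((40, 40))
        yy, xx = np.ogrid[:40, :40]
        mask[(yy - 20) ** 2 + (xx - 16) ** 2 <= 36] = 1.0
        mask[(yy - 20) ** 2 + (xx - 24) ** 2 <= 36] = 1.0
        assert lf.endosome_morphometrics(mask).object_count == 1


class TestTimecourse:
    def test_noiseless_roundtrip_within_two_percent(self, noiseless_dataset):
        tab = lf.quantify_timecourse(noiseless_dataset)
        mean = tab.groupby("time_min")[list(lf.COMPARTMENTS)].mean().to_numpy()
        err = np.abs(mean - noiseless_dataset.truth_series.fractions)
        assert err.max() <= 0.02

    def test_every_field_fraction_sums_to_one(self, noiseless_dataset):
        tab = lf.quantify_timecourse(noiseless_dataset)
        sums = tab[list(lf.COMPARTMENTS)].sum(axis=1)
        assert np.abs(sums - 1).max() < 1e-9

    def test_order_invariance(self, noiseless_dataset):
        tab1 = lf.quantify_timecourse(noiseless_dataset)
        shuffled = list(noiseless_dataset.fields)[::-1]
        tab2 = lf.quantify_timecourse(shuffled)
        assert tab1.equals(tab2)
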