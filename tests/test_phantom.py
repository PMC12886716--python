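"""Phantom generation, stain/AF rendering and dataset round trips."""

import numpy as np
import pytest

from virtmihc.phantom import BACKGROUND, EPITHELIAL_CYTOPLASM, STROMA, \
    VESSEL_LUMEN, ChromogenRecipe, PhantomConfigError, PhantomSpec, \
    concentration_maps, default_recipe, generate_phantom, \
    make_misaligned_pair, make_sample, phantom_cohort, read_dataset, \
    render_af, render_stain, smooth_random_field, write_dataset
from virtmihc.evaluation import StainVectors, color_deconvolve
from virtmihc.losses import smth

from oracles import shift_oracle

FLAT_SPEC = PhantomSpec(n_nuclei=0, n_vessels=0, n_epithelial_blobs=0,
                        background_fraction=0.0, density_amplitude=0.0)


class TestGeneratePhantom:
    def test_empty_scene_is_pure_stroma(self):
        ph = generate_phantom(256, 256, PhantomSpec(
            n_nuclei=0, n_vessels=0, n_epithelial_blobs=0,
            density_amplitude=0.0), seed=1)
        assert set(np.unique(ph.class_map)) <= {BACKGROUND, STROMA}
        assert not ph.nuclei_labels.any()
        assert not ph.endothelial_nuclei_mask.any()

    def test_requested_nucleus_count_is_max_instance_id(self):
        ph = generate_phantom(256, 256, PhantomSpec(
            n_nuclei=20, n_vessels=0, n_epithelial_blobs=0), seed=7)
        assert ph.nuclei_labels.max() == 20
        assert ph.ground_truth["n_nuclei"] == 20

    def test_same_seed_is_bit_identical(self):
        a = generate_phantom(64, 64, PhantomSpec(), seed=7)
        b = generate_phantom(64, 64, PhantomSpec(), seed=7)
        assert np.array_equal(a.class_map, b.class_map)
        assert np.array_equal(a.nuclei_labels, b.nuclei_labels)
        assert np.array_equal(a.density, b.density)

    def test_too_small_tile_rejected(self):
        with pytest.raises(PhantomConfigError):
            generate_phantom(32, 32, PhantomSpec(), seed=0)

    def test_overcrowded_spec_reports_configuration_error(self):
        with pytest.raises(PhantomConfigError):
            generate_phantom(64, 64, PhantomSpec(n_nuclei=500), seed=0)

    def test_invariants(self, small_phantom):
        ph = small_phantom
        # endothelial nuclei are nuclei instances...
        assert not (ph.endothelial_nuclei_mask & (ph.nuclei_labels == 0)).any()
        # ...lying within a fixed distance of a vessel-lumen boundary
        from scipy import ndimage
        lumen = ph.class_map == VESSEL_LUMEN
        assert lumen.any()
        dist = ndimage.distance_transform_edt(~lumen)
        assert dist[ph.endothelial_nuclei_mask].max() <= 6.0
        # epithelial mask = cytoplasm plus nuclei inside epithelial regions
        assert (ph.epithelial_mask
                & (ph.class_map == EPITHELIAL_CYTOPLASM)).sum() \
            == (ph.class_map == EPITHELIAL_CYTOPLASM).sum()
        extra = ph.epithelial_mask & (ph.class_map != EPITHELIAL_CYTOPLASM)
        assert not (extra & (ph.nuclei_labels == 0)).any()


class TestChromogenRecipe:
    def test_negative_concentration_rejected(self):
        h = ("hematoxylin", tuple(np.array([0.65, 0.704, 0.286])
                                  / np.linalg.norm([0.65, 0.704, 0.286])))
        with pytest.raises(ValueError, match="negative"):
            ChromogenRecipe("h-and-e", (h,), {"nuclei": {"hematoxylin": -1}})

    def test_erg_dab_restricted_to_endothelium(self):
        recipe = default_recipe("erg")
        dab_targets = [c for c, r in recipe.concentration_rules.items()
                       if r.get("dab", 0) > 0]
        assert dab_targets == ["endothelial_nuclei"]
        with pytest.raises(ValueError, match="endothelial"):
            ChromogenRecipe("erg", recipe.stain_vectors,
                            {"stroma": {"dab": 0.5}})

    def test_non_unit_vectors_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            ChromogenRecipe("h-and-e", (("hematoxylin", (1.0, 1.0, 0.0)),),
                            {})


class TestRenderStain:
    def test_zero_concentration_renders_white(self):
        ph = generate_phantom(64, 64, FLAT_SPEC, seed=3)
        recipe = ChromogenRecipe(
            "h-and-e", default_recipe("h-and-e").stain_vectors, {})
        assert np.array_equal(render_stain(ph, recipe), np.ones((64, 64, 3)))

    def test_single_dab_pixel_closed_form(self, small_phantom):
        recipe = default_recipe("erg")
        rgb = render_stain(small_phantom, recipe)
        names = dict(recipe.stain_vectors)
        v_dab = np.array(names["dab"])
        v_h = np.array(names["hematoxylin"])
        c_dab = recipe.concentration_rules["endothelial_nuclei"]["dab"]
        c_h = recipe.concentration_rules["nuclei"]["hematoxylin"]
        endo = small_phantom.endothelial_nuclei_mask
        d = small_phantom.density
        expected = np.exp(-(c_dab * v_dab + c_h * v_h)[None]
                          * d[endo][:, None])
        assert np.allclose(rgb[endo], expected, atol=1e-12)

    def test_erg_dab_positive_pixels_equal_endothelial_mask(
            self, small_phantom):
        rgb = render_stain(small_phantom, default_recipe("erg"))
        conc = color_deconvolve(rgb, StainVectors.h_dab())
        dab = conc[..., 1]
        assert np.array_equal(dab > 0.01, small_phantom.endothelial_nuclei_mask)

    def test_deconvolution_round_trip(self, small_phantom):
        recipe = default_recipe("panck")
        rgb = render_stain(small_phantom, recipe)
        conc_true = concentration_maps(small_phantom, recipe)
        vectors = StainVectors.h_dab()
        conc = color_deconvolve(rgb, vectors)
        assert np.abs(conc[..., 0] - conc_true[..., 0]).max() < 1e-6
        assert np.abs(conc[..., 1] - conc_true[..., 1]).max() < 1e-6


class TestRenderAF:
    def test_noise_free_single_compartment_is_piecewise_constant(self):
        ph = generate_phantom(64, 64, FLAT_SPEC, seed=3)
        mixing = {"stroma": (0.1, 0.5, 0.3, 0.2)}
        af = render_af(ph, mixing=mixing, noise_sd=0.0)
        stroma = ph.class_map == STROMA
        for ch, val in enumerate(mixing["stroma"]):
            assert np.allclose(af[ch][stroma], val, atol=1e-6)

    def test_dapi_brighter_in_nuclei_than_stroma(self, small_phantom):
        af = render_af(small_phantom, noise_sd=0.0)
        nuc = small_phantom.nuclei_labels > 0
        stroma = (small_phantom.class_map == STROMA) & ~nuc
        assert af[0][nuc].mean() > af[0][stroma].mean()

    def test_seeds_differ_only_in_noise(self, small_phantom):
        clean = render_af(small_phantom, noise_sd=0.0)
        a = render_af(small_phantom, noise_sd=0.05, seed=1)
        b = render_af(small_phantom, noise_sd=0.05, seed=2)
        assert not np.array_equal(a, b)
        # interior pixels (unclipped) recover the clean image after
        # subtracting each realization's noise
        assert np.abs(a - clean).max() < 0.4
        assert np.abs(b - clean).max() < 0.4

    def test_invalid_mixing_rejected(self, small_phantom):
        with pytest.raises(ValueError):
            render_af(small_phantom, mixing={"stroma": (2.0, 0, 0, 0)})


class TestMisalignment:
    def test_zero_amplitude_is_identity(self, small_phantom):
        s = make_sample(small_phantom, "h-and-e", noise_sd=0.0)
        mis = make_misaligned_pair(s, amplitude=0.0, seed=4)
        assert np.array_equal(mis.target, s.target)
        assert not mis.true_displacement.any()

    def test_integer_translation_matches_shift_oracle(self, small_phantom):
        s = make_sample(small_phantom, "h-and-e", noise_sd=0.0)
        field = np.zeros((2, 64, 64), dtype=np.float32)
        field[1] = 3.0
        from virtmihc.model import warp
        warped = warp(s.target, field)
        assert np.allclose(warped, shift_oracle(s.target, 0, 3), atol=1e-6)

    def test_generated_field_is_smooth_and_bounded(self, small_phantom):
        s = make_sample(small_phantom, "h-and-e", noise_sd=0.0)
        mis = make_misaligned_pair(s, amplitude=4.0, seed=9)
        f = mis.true_displacement
        mag = np.sqrt(f[0] ** 2 + f[1] ** 2)
        assert mag.max() == pytest.approx(4.0, abs=1e-5)
        # discrete gradients stay below 1 so the warp is invertible
        assert np.abs(np.diff(f, axis=1)).max() < 1.0
        assert np.abs(np.diff(f, axis=2)).max() < 1.0
        assert smth(f) < 0.1

    def test_excessive_amplitude_rejected(self, small_phantom):
        s = make_sample(small_phantom, "h-and-e")
        with pytest.raises(ValueError, match="10%"):
            make_misaligned_pair(s, amplitude=10.0, seed=0)


class TestDatasetIO:
    def test_round_trip_pixel_identical(self, tmp_path):
        cohort = phantom_cohort(2, 64, 64, seed=5)
        samples = [s for stain in cohort.values() for s in stain][:5]
        manifest = write_dataset(samples, tmp_path)
        loaded = read_dataset(manifest)
        assert len(loaded) == 5
        for orig, back in zip(samples, loaded):
            assert np.array_equal(orig.af, back.af)
            assert np.array_equal(orig.target, back.target)
            assert np.array_equal(orig.endothelial_nuclei_mask,
                                  back.endothelial_nuclei_mask)
            assert orig.stain_class == back.stain_class

    def test_manifest_row_count_and_stain_histogram(self, tmp_path):
        cohort = phantom_cohort(3, 64, 64, seed=6)
        samples = [s for stain in cohort.values() for s in stain]
        manifest = write_dataset(samples, tmp_path)
        from virtmihc.io import load_manifest
        rows = load_manifest(manifest).rows
        assert len(rows) == len(samples)
        assert rows["stain"].value_counts().to_dict() == {
            "h-and-e": 3, "erg": 3, "panck": 3}


def test_cohort_is_co_registered_across_stains():
    cohort = phantom_cohort(2, 64, 64, seed=8)
    for i in range(2):
        af0 = cohort["h-and-e"][i].af
        for stain in ("erg", "panck"):
            assert np.array_equal(cohort[stain][i].af, af0)
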