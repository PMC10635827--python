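"""Generator correctness: ground truth, determinism, and noise structure."""

import numpy as np
import pandas as pd
import pytest

from steatoscope import lipidomics, synthetic, tracing
from steatoscope.synthetic import (
    FattyAcid,
    ImageScenario,
    LabelingScenario,
    ScreenScenario,
    TagScenario,
)


class TestOrganoidImage:
    def test_zero_droplets_gives_zero_coverage(self):
        sc = ImageScenario(n_droplets=0, target_coverage_fraction=0.0, seed=1)
        img = synthetic.make_organoid_image(sc)
        assert img.coverage == 0.0
        assert not img.droplet_mask.any()

    def test_single_droplet_area_ratio(self):
        # one 10 px droplet in a 100 px organoid: coverage ~ (10/100)^2
        sc = ImageScenario(
            image_size_px=(256, 256),
            organoid_radius_px=100,
            n_droplets=1,
            droplet_radius_px_range=(10, 10),
            target_coverage_fraction=0.01,
            noise_sd=0.0,
            seed=1,
        )
        img = synthetic.make_organoid_image(sc)
        assert img.coverage == pytest.approx(0.01, abs=1e-3)

    def test_default_scenario_hits_target_coverage(self, default_image):
        assert abs(default_image.coverage - 0.30) <= 0.01

    def test_ground_truth_coverage_is_exact_pixel_ratio(self, default_image):
        img = default_image
        assert img.coverage == img.droplet_mask.sum() / img.organoid_mask.sum()

    def test_bit_reproducible_given_seed(self):
        sc = ImageScenario(seed=11)
        a = synthetic.make_organoid_image(sc)
        b = synthetic.make_organoid_image(sc)
        assert np.array_equal(a.nuclei, b.nuclei)
        assert np.array_equal(a.lipid, b.lipid)
        assert np.array_equal(a.droplet_mask, b.droplet_mask)

    def test_infeasible_coverage_raises(self):
        sc = ImageScenario(n_droplets=2, target_coverage_fraction=0.5)
        with pytest.raises(ValueError, match="infeasible coverage"):
            synthetic.make_organoid_image(sc)

    def test_droplets_confined_to_organoid(self, default_image):
        assert not (default_image.droplet_mask & ~default_image.organoid_mask).any()

    def test_images_are_16bit(self, default_image):
        assert default_image.nuclei.dtype == np.uint16
        assert default_image.lipid.dtype == np.uint16


class TestIsotopologueDataset:
    def test_no_dnl_no_natural_abundance_all_mass_at_m0(self):
        sc = LabelingScenario(
            true_dnl_fraction_per_day=0.0,
            natural_13c_abundance=0.0,
            elongation_fraction=0.0,
            noise_cv=0.0,
            n_replicates=1,
            seed=0,
        )
        table, _ = synthetic.make_isotopologue_dataset(sc)
        for fa in table.fatty_acids:
            vec = table.vector(fa, 1)
            assert vec[0] == pytest.approx(1.0)
            assert vec[1:].sum() == pytest.approx(0.0, abs=1e-12)

    def test_fully_labeled_c16_all_mass_at_m16(self):
        fas = (FattyAcid("C16:0", 16, 8, False, 1.0),)
        sc = LabelingScenario(
            fatty_acids=fas,
            true_dnl_fraction_per_day=0.2,
            days=5,
            precursor_enrichment=1.0,
            natural_13c_abundance=0.0,
            elongation_fraction=0.0,
            noise_cv=0.0,
            n_replicates=1,
        )
        table, _ = synthetic.make_isotopologue_dataset(sc)
        vec = table.vector("C16:0", 1)
        assert vec[16] == pytest.approx(1.0)

    def test_labeled_tail_matches_binomial_oracle(self):
        # f=0.6, enrichment 0.8 on C16:0: mass at shifts >= 4 is
        # 0.6 * P(k >= 2), k ~ Binomial(8, 0.8), everything else noise-free
        fas = (FattyAcid("C16:0", 16, 8, False, 1.0),)
        sc = LabelingScenario(
            fatty_acids=fas,
            true_dnl_fraction_per_day=0.12,
            days=5,
            precursor_enrichment=0.8,
            natural_13c_abundance=0.0,
            elongation_fraction=0.0,
            noise_cv=0.0,
            n_replicates=1,
        )
        table, _ = synthetic.make_isotopologue_dataset(sc)
        vec = table.vector("C16:0", 1)
        p_tail = 1.0 - 0.2**8 - 8 * 0.8 * 0.2**7
        assert vec[4:].sum() == pytest.approx(0.6 * p_tail, abs=1e-12)

    def test_vectors_nonnegative_and_normalized(self, labeling_tables):
        for table, _ in labeling_tables.values():
            for fa in table.fatty_acids:
                for rep in table.replicates:
                    vec = table.vector(fa, rep)
                    assert (vec >= 0).all()
                    assert vec.sum() == pytest.approx(1.0, abs=1e-9)

    def test_essential_fatty_acids_receive_no_label(self):
        sc = LabelingScenario(noise_cv=0.0, natural_13c_abundance=0.0, n_replicates=1)
        table, truth = synthetic.make_isotopologue_dataset(sc)
        assert truth["per_fa_fraction"]["C20:4"] == 0.0
        vec = table.vector("C20:4", 1)
        # only elongation (+2) mass beyond M+0 and nothing at >= +4
        assert vec[4:].sum() == pytest.approx(0.0, abs=1e-12)

    def test_invalid_enrichment_rejected(self):
        with pytest.raises(ValueError):
            synthetic.make_isotopologue_dataset(LabelingScenario(precursor_enrichment=1.5))

    def test_abundances_must_sum_to_one(self):
        fas = (FattyAcid("C16:0", 16, 8, False, 0.5),)
        with pytest.raises(ValueError, match="sum to 1"):
            synthetic.make_isotopologue_dataset(LabelingScenario(fatty_acids=fas))

    def test_csv_round_trip_preserves_values(self, tmp_path, labeling_tables):
        table, _ = labeling_tables[1]
        path = tmp_path / "iso.csv"
        table.to_csv(path)
        back = tracing.IsotopologueTable.from_csv(path)
        pd.testing.assert_frame_equal(
            back.data.reset_index(drop=True), table.data.reset_index(drop=True)
        )


class TestTagProfile:
    def test_zero_cv_quantities_are_exact(self):
        sc = TagScenario(
            species=(("TAG 52:3 (16:0/18:1/18:2)", 10.0, 0.0),),
            condition_fold_changes={"ref": 1.0, "hi": 2.0},
        )
        for cond, expected in (("ref", 10.0), ("hi", 20.0)):
            profile, truth = synthetic.make_tag_profile(sc, cond)
            q = lipidomics.quantify(profile)
            assert lipidomics.total_tag(q) == pytest.approx(expected)
            assert truth["fold_change"] == pytest.approx(expected / 10.0)

    def test_noise_free_fold_change_by_construction(self):
        species = tuple((name, mean, 0.0) for name, mean, _ in synthetic.DEFAULT_TAG_SPECIES)
        sc = TagScenario(species=species, condition_fold_changes={"a": 25.0, "b": 1.0})
        pa = lipidomics.quantify(synthetic.make_tag_profile(sc, "a")[0])
        pb = lipidomics.quantify(synthetic.make_tag_profile(sc, "b")[0])
        assert lipidomics.total_tag_fold_change(pa, pb) == pytest.approx(25.0)

    def test_default_composition_dominated_by_five_major_fatty_acids(self):
        profile, _ = synthetic.make_tag_profile(
            synthetic.default_intracellular_tag_scenario(seed=0), "FADS2_WT"
        )
        profile = lipidomics.quantify(profile)
        five = {(14, 0), (16, 0), (16, 1), (18, 0), (18, 1)}
        total = named = 0.0
        for s in profile.species:
            for chain in s.chains:
                total += s.quantity
                named += s.quantity * (chain in five)
        assert named / total >= 0.90

    def test_unknown_condition_raises(self):
        sc = synthetic.default_secretion_tag_scenario()
        with pytest.raises(KeyError, match="unknown condition"):
            synthetic.make_tag_profile(sc, "nope")

    def test_species_bias_preserves_total_fold(self):
        sc = synthetic.default_intracellular_tag_scenario(seed=5)
        noise_free = TagScenario(
            species=tuple((n, m, 0.0) for n, m, _ in sc.species),
            condition_fold_changes=sc.condition_fold_changes,
            condition_species_bias=sc.condition_species_bias,
        )
        wt = lipidomics.quantify(synthetic.make_tag_profile(noise_free, "FADS2_WT")[0])
        ko = lipidomics.quantify(synthetic.make_tag_profile(noise_free, "FADS2_KO")[0])
        assert lipidomics.total_tag_fold_change(ko, wt) == pytest.approx(3.0)


class TestScreenDataset:
    def test_full_effect_reverts_to_wt(self):
        drugs = (synthetic.DrugSpec("X", (1.0, 1.0, 1.0, 1.0)),)
        sc = ScreenScenario(drugs=drugs, replicate_sd=0.0, seed=0)
        frame, _ = synthetic.make_screen_dataset(sc)
        assert np.allclose(frame["coverage"], sc.wt_coverage_mean)

    def test_zero_effect_stays_at_steatotic_mean(self):
        drugs = (synthetic.DrugSpec("X", (0.0, 0.0, 0.0, 0.0)),)
        sc = ScreenScenario(drugs=drugs, replicate_sd=0.0, seed=0)
        frame, _ = synthetic.make_screen_dataset(sc)
        assert np.allclose(frame["coverage"], sc.steatotic_coverage_mean)

    def test_toxic_cells_have_no_coverage(self, screen_data):
        frame, _ = screen_data
        assert frame.loc[frame["toxic"], "coverage"].isna().all()
        assert frame.loc[~frame["toxic"], "coverage"].notna().all()

    def test_reproducible_given_seed(self):
        sc = ScreenScenario(seed=9)
        a, _ = synthetic.make_screen_dataset(sc)
        b, _ = synthetic.make_screen_dataset(sc)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_reference_means_rejected(self):
        with pytest.raises(ValueError):
            synthetic.make_screen_dataset(
                ScreenScenario(wt_coverage_mean=0.3, steatotic_coverage_mean=0.1)
            )
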