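"""Generator determinism, ground-truth consistency and statistical calibration."""

import numpy as np
import pytest

from cmhquant.stats import pearson_correlation
from cmhquant.synthetic import (
    CohortSpec,
    PhantomSpec,
    SectionSpec,
    generate_cohort,
    generate_deposit_channel,
    generate_histology_section,
    generate_vessel_phantom,
    sample_diameters,
)


class TestVesselPhantom:
    def test_straight_tube_width(self):
        """A noise-free axis-aligned 6 µm tube has a 6 ± 1 voxel-wide
        half-max support in cross-section."""
        spec = PhantomSpec(
            volume_shape=(30, 31, 31),
            n_vessels=1,
            n_lesions=0,
            diameter_distribution=("fixed", {"value": 6.0}),
            tortuosity=0.0,
            psf_sigma=0.0,
            noise_sigma=0.0,
            seed=4,
        )
        fluor, truth = generate_vessel_phantom(spec)
        support = fluor > spec.background_level + spec.vessel_intensity / 2
        # measure width perpendicular to the tube on a mid-volume slice
        areas = []
        for z in range(10, 20):
            if support[z].any():
                areas.append(support[z].sum())
        # cross-section area ≈ π r² / cos(angle); width from area
        widths = 2 * np.sqrt(np.asarray(areas) / np.pi)
        assert abs(np.median(widths) - 6.0) <= 1.5

    def test_empty_spec_gives_background_stack(self):
        spec = PhantomSpec(n_vessels=0, n_lesions=0, volume_shape=(16, 16, 16), seed=0)
        fluor, truth = generate_vessel_phantom(spec)
        assert truth.n_nodes == 0 and not truth.segments
        assert fluor.mean() == pytest.approx(spec.background_level, abs=3.0)

    def test_seeded_regeneration_bit_identical(self):
        spec = PhantomSpec(volume_shape=(24, 32, 32), n_vessels=5, seed=9)
        f1, t1 = generate_vessel_phantom(spec)
        f2, t2 = generate_vessel_phantom(spec)
        assert np.array_equal(f1, f2)
        assert np.array_equal(t1.positions, t2.positions)
        assert np.array_equal(t1.radii, t2.radii)

    def test_truth_radii_match_drawn_sample(self):
        spec = PhantomSpec(
            volume_shape=(48, 64, 64),
            n_vessels=12,
            diameter_distribution=("uniform", {"low": 2.0, "high": 11.0}),
            seed=21,
        )
        _, truth = generate_vessel_phantom(spec)
        rng = np.random.default_rng(21)
        drawn = sample_diameters(rng, 12, spec.diameter_distribution)
        per_segment = sorted({round(2 * truth.radii[p[0]], 9) for p in truth.segments.values()})
        assert per_segment == sorted(round(d, 9) for d in drawn)

    def test_capillary_profile_mass_below_10(self):
        rng = np.random.default_rng(0)
        d = sample_diameters(rng, 20000, ("lognormal-capillary", {}))
        assert d.min() >= 2.0 and d.max() <= 11.0
        assert np.mean(d < 10.0) >= 0.97

    def test_overfull_volume_rejected(self):
        spec = PhantomSpec(
            volume_shape=(16, 16, 16),
            n_vessels=200,
            seed=0,
        )
        with pytest.raises(ValueError, match="volume too small"):
            generate_vessel_phantom(spec)

    def test_no_orphan_voxels_outside_truth_support(self):
        """Ground-truth consistency: every voxel above half-max lies within
        the drawn radius (+ PSF allowance) of a truth centerline node."""
        from scipy.spatial import cKDTree

        spec = PhantomSpec(volume_shape=(32, 48, 48), n_vessels=6, seed=13)
        fluor, truth = generate_vessel_phantom(spec)
        hot = np.argwhere(fluor > spec.background_level + 0.5 * spec.vessel_intensity)
        tree = cKDTree(truth.positions)
        dist, idx = tree.query((hot + 0.5) * np.asarray(spec.voxel_spacing))
        allowance = truth.radii[idx] + 2 * spec.psf_sigma + 2.0
        assert np.all(dist <= allowance)


class TestDepositChannel:
    def test_no_lesions_uniform_bright(self):
        spec = PhantomSpec(volume_shape=(16, 16, 16), n_vessels=2, n_lesions=0, seed=1)
        _, truth = generate_vessel_phantom(spec)
        trans, deposits = generate_deposit_channel(spec, truth)
        assert deposits == []
        assert trans.mean() == pytest.approx(spec.transmission_background, abs=5.0)

    def test_anchor_vessel_recorded_nearby(self, small_phantom):
        _, _, truth, deposits, spec = small_phantom
        anchors = [d for d in deposits if d.anchor_distance is not None]
        assert anchors
        # the anchor deposit of each lesion sits within wall offset + its
        # radius + anchor vessel radius of the centerline
        by_lesion = {}
        for d in anchors:
            by_lesion.setdefault(d.lesion_id, d)
        for d in by_lesion.values():
            assert d.anchor_distance <= spec.deposit_offset[1] + d.radius + 11.0 / 2

    def test_seeded_centroids_reproducible(self):
        spec = PhantomSpec(volume_shape=(48, 64, 64), n_vessels=8, n_lesions=5, seed=3)
        _, truth = generate_vessel_phantom(spec)
        _, d1 = generate_deposit_channel(spec, truth)
        _, d2 = generate_deposit_channel(spec, truth)
        assert [d.centroid for d in d1] == [d.centroid for d in d2]

    def test_oversized_deposit_rejected(self):
        with pytest.raises(ValueError, match="lesion_extent"):
            PhantomSpec(deposit_radius=(3.0, 150.0), lesion_extent=200.0)

    def test_lesions_need_vessels(self):
        spec = PhantomSpec(volume_shape=(16, 16, 16), n_vessels=0, n_lesions=1, seed=0)
        _, truth = generate_vessel_phantom(spec)
        with pytest.raises(ValueError, match="anchor"):
            generate_deposit_channel(spec, truth)


class TestHistologySection:
    def test_clean_section_has_no_stain(self):
        spec = SectionSpec(
            image_shape=(300, 340), pixel_size=4.0, tissue_area=0.01,
            cmh_density=0.0, dab_fraction=0.0, seed=2,
        )
        img, truth = generate_histology_section(spec)
        assert truth.lesion_count == 0
        assert truth.dab_fraction == 0.0
        b, r = img[..., 2], img[..., 0]
        assert not np.any((b > r * 1.2) & (b > 100) & truth.tissue_mask)

    def test_lesion_count_from_density(self):
        spec = SectionSpec(
            image_shape=(700, 800), pixel_size=5.0, tissue_area=0.1,
            cmh_density=20.0, seed=5,
        )
        img, truth = generate_histology_section(spec)
        assert truth.lesion_count == 2  # round(20 × 0.1)

    def test_dab_fraction_exact_by_construction(self):
        spec = SectionSpec.dab_section(1.52, seed=8)
        _, truth = generate_histology_section(spec)
        assert abs(truth.dab_fraction - 1.52) <= 0.1

    def test_indistinct_stain_colors_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            SectionSpec(
                stain_colors={
                    "background": (255, 255, 255),
                    "counterstain": (250, 250, 250),
                    "prussian_blue": (60, 70, 170),
                }
            )

    def test_subpixel_lesion_area_rejected(self):
        with pytest.raises(ValueError, match="pixel"):
            SectionSpec(pixel_size=30.0, cmh_area_range=(500.0, 20000.0))

    def test_seeded_section_reproducible(self):
        spec = SectionSpec(image_shape=(300, 340), tissue_area=0.01, seed=12)
        i1, _ = generate_histology_section(spec)
        i2, _ = generate_histology_section(spec)
        assert np.array_equal(i1, i2)


class TestCohort:
    def test_zero_noise_records_equal_group_means(self):
        spec = CohortSpec.experiment_two_group(
            n_per_group=1,
            measurement_noise={"cmh_density": 0.0, "map": 0.0, "iba1": 0.0, "cd206": 0.0},
            seed=0,
        )
        df = generate_cohort(spec)
        for _, row in df.iterrows():
            gi = list(spec.group_labels).index(row["group"])
            assert row["map_final"] == spec.map_final_means[gi]
            assert row["iba1_fraction"] == spec.iba1_means[gi]
            assert row["cmh_count"] == round(
                spec.cmh_density_means[gi] * spec.section_area_cm2
            )

    def test_counts_are_nonnegative_integers(self):
        df = generate_cohort(CohortSpec(seed=7))
        assert (df["cmh_count"] >= 0).all()
        assert (df["cmh_count"] == df["cmh_count"].astype(int)).all()

    def test_correlation_calibration_monte_carlo(self):
        """Mean empirical Pearson r over replicates approaches the requested r."""
        rs = []
        for rep in range(60):
            df = generate_cohort(CohortSpec.experiment_two_group(seed=5000 + rep))
            r, _ = pearson_correlation(df["cmh_density"], df["map_final"])
            rs.append(r)
        assert np.mean(rs) == pytest.approx(0.52, abs=0.04)

    def test_group_means_converge(self):
        df = generate_cohort(CohortSpec.experiment_two_group(n_per_group=4000, seed=2))
        means = df.groupby("group")["cmh_density"].mean()
        assert means["AngII-CTL"] == pytest.approx(1.26, abs=0.03)
        assert means["PBS-CTL"] == pytest.approx(0.59, abs=0.03)
        ratio = means["AngII-CTL"] / means["PBS-CTL"]
        assert round(ratio, 1) == pytest.approx(2.1, abs=0.1)

    def test_infeasible_correlation_rejected(self):
        spec = CohortSpec.experiment_two_group(
            cmh_map_correlation=0.999,
            measurement_noise={"cmh_density": 0.05, "map": 1.0, "iba1": 0.4, "cd206": 0.005},
        )
        with pytest.raises(ValueError, match="[Ii]nfeasible"):
            generate_cohort(spec)

    def test_seeded_cohort_reproducible(self):
        d1 = generate_cohort(CohortSpec(seed=3))
        d2 = generate_cohort(CohortSpec(seed=3))
        assert d1.equals(d2)
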