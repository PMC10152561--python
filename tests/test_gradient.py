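"""Mask construction, distance transform, exclusion rules and statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csfgrad import gradient as gr
from csfgrad import phantom as ph
from csfgrad.config import PipelineConfig
from csfgrad.validation import brute_force_distance


class TestBinarize:
    def test_boundary_is_inclusive(self):
        prob = np.array([[[0.94, 0.95, 0.96]]])
        np.testing.assert_array_equal(gr.binarize_probability(prob),
                                      np.array([[[False, True, True]]]))

    def test_all_zero_gives_empty_mask(self):
        assert not gr.binarize_probability(np.zeros((3, 3, 3))).any()

    def test_values_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            gr.binarize_probability(np.full((2, 2, 2), 1.2))


class TestNawm:
    def test_empty_lesions_identity(self, rng):
        wm = rng.random((6, 6, 6)) < 0.5
        np.testing.assert_array_equal(gr.make_nawm_mask(wm, np.zeros_like(wm)), wm)

    def test_lesions_covering_wm_empty_result(self):
        wm = np.ones((4, 4, 4), dtype=bool)
        assert not gr.make_nawm_mask(wm, wm).any()

    def test_random_masks_equal_set_difference(self, rng):
        wm = rng.random((8, 8, 8)) < 0.5
        les = rng.random((8, 8, 8)) < 0.3
        got = gr.make_nawm_mask(wm, les)
        want = np.array([[[wm[i, j, k] and not les[i, j, k] for k in range(8)]
                          for j in range(8)] for i in range(8)])
        np.testing.assert_array_equal(got, want)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            gr.make_nawm_mask(np.ones((3, 3, 3), bool), np.ones((4, 4, 4), bool))


class TestDistanceTransform:
    def test_pythagorean_single_voxel(self):
        csf = np.zeros((8, 8, 8), dtype=bool)
        csf[0, 0, 0] = True
        d = gr.euclidean_distance_to_csf(csf, (1, 1, 1))
        assert d[3, 4, 0] == pytest.approx(5.0)
        assert d[0, 0, 0] == 0.0

    def test_anisotropic_spacing(self):
        csf = np.zeros((4, 4, 4), dtype=bool)
        csf[0, 0, 0] = True
        d = gr.euclidean_distance_to_csf(csf, (1, 1, 3))
        assert d[0, 0, 1] == pytest.approx(3.0)
        assert d[1, 0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("spacing", [(1, 1, 1), (1, 1, 3)])
    def test_matches_brute_force_on_random_masks(self, rng, spacing):
        for _ in range(5):
            mask = rng.random((10, 10, 10)) < 0.08
            mask[tuple(rng.integers(0, 10, 3))] = True
            d = gr.euclidean_distance_to_csf(mask, spacing)
            np.testing.assert_allclose(d, brute_force_distance(mask, spacing),
                                       atol=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gr.euclidean_distance_to_csf(np.zeros((3, 3, 3), bool), (1, 1, 1))


def _plane_setup(n=9):
    """CSF plane at the bottom of an n³ grid; white matter everywhere else."""
    csf = np.zeros((n, n, n), dtype=bool)
    csf[:, :, 0] = True
    wm = ~csf
    empty = np.zeros_like(csf)
    masks = gr.TissueMasks(csf=csf, wm=wm, irl=empty, non_irl=empty)
    dist = gr.euclidean_distance_to_csf(csf, (1, 1, 1))
    return masks, dist


class TestExclusions:
    def test_zero_bands_are_identity(self):
        masks, dist = _plane_setup()
        out = gr.apply_exclusions(masks, dist, (1, 1, 1), 0.0, 0.0)
        np.testing.assert_array_equal(out["NAWM"], masks.nawm)

    def test_csf_band_count_matches_enumeration(self):
        masks, dist = _plane_setup()
        out = gr.apply_exclusions(masks, dist, (1, 1, 1), csf_band_mm=2.0)
        brute = sum(1 for i, j, k in itertools.product(range(9), repeat=3)
                    if k >= 1 and float(k) >= 2.0)  # distance is exactly k (mm)
        assert out["NAWM"].sum() == brute
        # voxels at exactly 2.0 mm survive (strict < exclusion)
        assert out["NAWM"][:, :, 2].all()

    def test_subvoxel_radius_lesion_fully_eroded(self):
        n = 11
        csf = np.zeros((n, n, n), dtype=bool)
        csf[:, :, 0] = True
        lesion = np.zeros_like(csf)
        center = np.array([5.0, 5.0, 6.0])
        for idx in itertools.product(range(n), repeat=3):
            if np.sum((np.array(idx) - center) ** 2) <= 1.4**2:
                lesion[idx] = True
        assert lesion.sum() == 7  # center plus face neighbours
        masks = gr.TissueMasks(csf=csf, wm=~csf, irl=lesion,
                               non_irl=np.zeros_like(csf))
        dist = gr.euclidean_distance_to_csf(csf, (1, 1, 1))
        out = gr.apply_exclusions(masks, dist, (1, 1, 1), 2.0, 1.5)
        assert out["IRL"].sum() == 0

    def test_monotone_in_band_widths(self, rng):
        masks, dist = _plane_setup()
        lesion = rng.random((9, 9, 9)) < 0.2
        lesion &= masks.nawm
        masks = gr.TissueMasks(csf=masks.csf, wm=masks.wm, irl=lesion,
                               non_irl=np.zeros_like(lesion))
        counts = []
        for band in (0.0, 1.0, 2.0, 3.0, 4.0):
            out = gr.apply_exclusions(masks, dist, (1, 1, 1), band, band)
            counts.append({cls: int(m.sum()) for cls, m in out.items()})
        for a, b in zip(counts, counts[1:]):
            for cls in a:
                assert b[cls] <= a[cls]

    def test_alternative_csf_distance_rule_subsumed_by_band(self):
        masks, dist = _plane_setup()
        lesion = np.zeros((9, 9, 9), dtype=bool)
        lesion[4, 4, 3:6] = True
        masks = gr.TissueMasks(csf=masks.csf, wm=masks.wm, irl=lesion,
                               non_irl=np.zeros_like(lesion))
        out = gr.apply_exclusions(masks, dist, (1, 1, 1), 2.0, 1.5,
                                  lesion_rule="csf_distance")
        np.testing.assert_array_equal(out["IRL"], lesion & (dist >= 2.0))

    def test_negative_band_rejected(self):
        masks, dist = _plane_setup()
        with pytest.raises(ValueError):
            gr.apply_exclusions(masks, dist, (1, 1, 1), -1.0, 0.0)


class TestVoxelTable:
    def test_empty_filtered_sets_give_empty_table(self):
        table = gr.build_voxel_table(np.zeros((3, 3, 3)), np.zeros((3, 3, 3)),
                                     {"NAWM": np.zeros((3, 3, 3), bool)}, "p")
        assert table.empty

    def test_counts_match_masks(self, noiseless_phantom, noiseless_table):
        counts = noiseless_table.groupby("tissue_class").size()
        # oracle: recompute surviving voxels by brute arithmetic
        from scipy import ndimage
        m = noiseless_phantom.masks
        dist = gr.euclidean_distance_to_csf(m.csf, (1, 1, 1))
        keep = dist >= 2.0
        for cls, mask in (("IRL", m.irl), ("nonIRL", m.non_irl)):
            interior = ndimage.distance_transform_edt(mask, sampling=(1, 1, 1))
            assert counts[cls] == int((mask & keep & (interior >= 1.5)).sum())
        assert counts["NAWM"] == int((m.nawm & keep).sum())

    def test_overlapping_lesion_classes_rejected(self):
        m = np.ones((2, 2, 2), dtype=bool)
        with pytest.raises(ValueError, match="both lesion classes"):
            gr.build_voxel_table(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)),
                                 {"IRL": m, "nonIRL": m}, "p")

    def test_adc_positive_for_positive_field(self, noiseless_table):
        assert (noiseless_table["adc_mm2_per_s"] > 0).all()


class TestTissueSummary:
    def test_single_patient_levels_agree(self, rng):
        vals = rng.normal(1.0, 0.1, 11)
        table = pd.DataFrame({"patient_id": "p", "tissue_class": "NAWM",
                              "distance_mm": np.arange(11.0), "adc_mm2_per_s": vals})
        pooled = gr.tissue_summary(table, "pooled")
        per = gr.tissue_summary(table, "per_patient")
        assert pooled.loc[0, "median"] == per.loc[0, "median"] == np.median(vals)

    def test_constant_field_iqr_zero(self):
        table = pd.DataFrame({"patient_id": "p", "tissue_class": "IRL",
                              "distance_mm": np.arange(5.0),
                              "adc_mm2_per_s": np.full(5, 1.1e-3)})
        s = gr.tissue_summary(table)
        assert s.loc[0, "median"] == 1.1e-3 and s.loc[0, "q1"] == s.loc[0, "q3"]

    def test_baseline_ordering_preserved(self, noiseless_table):
        s = gr.tissue_summary(noiseless_table, "pooled").set_index("tissue_class")
        assert s.loc["IRL", "median"] > s.loc["nonIRL", "median"] > s.loc["NAWM", "median"]

    def test_absent_class_absent_not_zero(self):
        table = pd.DataFrame({"patient_id": "p", "tissue_class": "NAWM",
                              "distance_mm": [2.0, 3.0], "adc_mm2_per_s": [1.0, 2.0]})
        s = gr.tissue_summary(table)
        assert "IRL" not in set(s["tissue_class"])


class TestDistanceCorrelation:
    def test_exact_linear_relation(self):
        d = np.linspace(2, 20, 50)
        table = pd.DataFrame({"patient_id": "p", "tissue_class": "NAWM",
                              "distance_mm": d, "adc_mm2_per_s": 2e-3 - 3e-6 * d})
        for method in ("pearson", "spearman"):
            res = gr.distance_correlation(table, "NAWM", method)
            assert res.r == pytest.approx(-1.0)
        assert gr.distance_correlation(table, "NAWM").slope == pytest.approx(-3e-6, rel=1e-9)

    def test_independent_noise_gives_near_zero_r(self, rng):
        n = 20000
        table = pd.DataFrame({"patient_id": "p", "tissue_class": "NAWM",
                              "distance_mm": rng.uniform(2, 20, n),
                              "adc_mm2_per_s": rng.normal(1e-3, 1e-4, n)})
        res = gr.distance_correlation(table, "NAWM")
        assert abs(res.r) < 4.0 / math.sqrt(n)

    def test_degenerate_inputs_rejected(self):
        t1 = pd.DataFrame({"patient_id": "p", "tissue_class": "NAWM",
                           "distance_mm": [2.0, 2.0, 2.0], "adc_mm2_per_s": [1, 2, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            gr.distance_correlation(t1, "NAWM")
        t2 = pd.DataFrame({"patient_id": "p", "tissue_class": "NAWM",
                           "distance_mm": [2.0, 3.0], "adc_mm2_per_s": [1.0, 2.0]})
        with pytest.raises(ValueError, match="at least 3"):
            gr.distance_correlation(t2, "NAWM")


class TestFisher:
    def test_equal_correlations_give_zero(self):
        z, p = gr.fisher_compare(0.4, 50, 0.4, 120)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # atanh(0.5) / sqrt(1/100 + 1/100) evaluated independently
        z, p = gr.fisher_compare(0.5, 103, 0.0, 103)
        assert z == pytest.approx(math.atanh(0.5) / math.sqrt(2 / 100), rel=1e-12)
        assert z == pytest.approx(3.8843, abs=5e-4)

    def test_antisymmetry(self):
        z1, p1 = gr.fisher_compare(0.6, 40, 0.2, 60)
        z2, p2 = gr.fisher_compare(0.2, 60, 0.6, 40)
        assert z1 == -z2 and p1 == p2

    def test_strictly_increasing_in_r1(self):
        zs = [gr.fisher_compare(r, 50, 0.1, 50)[0] for r in np.linspace(-0.9, 0.9, 19)]
        assert np.all(np.diff(zs) > 0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            gr.fisher_compare(1.0, 50, 0.0, 50)
        with pytest.raises(ValueError):
            gr.fisher_compare(0.5, 3, 0.0, 50)


class TestZMatrix:
    def test_matches_elementwise_fisher(self):
        entries = [("a", 0.5, 100), ("b", 0.2, 80), ("c", -0.1, 60)]
        zm, pm = gr.z_matrix(entries)
        for la, ra, na in entries:
            for lb, rb_, nb in entries:
                if la == lb:
                    assert zm.loc[la, lb] == 0.0
                else:
                    z, p = gr.fisher_compare(ra, na, rb_, nb)
                    assert zm.loc[la, lb] == pytest.approx(z)
                    assert pm.loc[la, lb] == pytest.approx(p)
        np.testing.assert_allclose(zm.to_numpy(), -zm.to_numpy().T, atol=1e-12)

    def test_identical_entries_zero_matrix(self):
        zm, _ = gr.z_matrix([("a", 0.3, 50), ("b", 0.3, 50)])
        assert (zm.to_numpy() == 0).all()

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            gr.z_matrix([("a", 0.3, 50), ("a", 0.4, 50)])


class TestDichotomize:
    def test_even_untied_split_is_balanced(self):
        values = {f"p{i}": float(i) for i in range(1, 103)}
        high, low = gr.dichotomize_by_median(values)
        assert len(high) == 51 and len(low) == 51
        assert set(high) | set(low) == set(values)

    def test_all_equal_goes_low(self):
        high, low = gr.dichotomize_by_median({"a": 1.0, "b": 1.0, "c": 1.0})
        assert high == [] and len(low) == 3

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.integers(0, 9), min_size=2, max_size=25))
    def test_partition_and_tie_rule(self, vals):
        values = {f"p{i}": float(v) for i, v in enumerate(vals)}
        high, low = gr.dichotomize_by_median(values)
        med = float(np.median(list(values.values())))
        assert set(high) | set(low) == set(values) and not set(high) & set(low)
        assert all(values[k] > med for k in high)
        assert all(values[k] <= med for k in low)


def _study_patients(slope_scales, seed=0, grid=(40, 40, 40)):
    patients, grouping = [], {}
    rng = np.random.default_rng(seed)
    base = ph.PhantomSpec(grid_shape=grid, ventricle_semiaxes=(6.0, 7.0, 6.0),
                          lesions=[], seed=0)
    from dataclasses import replace
    for grp, scale in slope_scales.items():
        for i in range(2):
            lesions = ph.random_lesions(rng, base, 1, 2, radius_range=(3.0, 4.0))
            spec = replace(base, lesions=lesions,
                           gradient_slope={k: v * scale for k, v in
                                           base.gradient_slope.items()},
                           seed=int(rng.integers(2**31)))
            out = ph.make_phantom(spec)
            pid = f"{grp}{i}"
            patients.append(gr.PatientVolumes(pid, out.adc, out.masks.wm,
                                              out.masks.irl, out.masks.non_irl,
                                              csf_prob=out.prob["CSF"], group=grp))
            grouping[pid] = grp
    return patients, grouping


class TestGradientStudy:
    def test_identical_groups_zero_z(self):
        patients, grouping = _study_patients({"g1": 1.0}, seed=4)
        twins = []
        for pv in patients:
            twins.append(pv)
            twins.append(gr.PatientVolumes(pv.patient_id + "_twin", pv.adc,
                                           pv.wm_mask, pv.irl_mask, pv.non_irl_mask,
                                           csf_prob=pv.csf_prob, group="g2"))
        res = gr.run_gradient_study(twins)
        for cls, (zm, pm) in res.z_between_groups.items():
            assert zm.loc["g1", "g2"] == pytest.approx(0.0, abs=1e-12)

    def test_steeper_group_correlates_more_strongly(self):
        patients, grouping = _study_patients({"low": 1.0, "high": 2.0}, seed=9)
        res = gr.run_gradient_study(patients, grouping=grouping)
        corr = res.correlations.set_index(["group", "tissue_class"])
        for cls in ("NAWM",):  # the well-powered class at this small size
            assert abs(corr.loc[("high", cls), "r"]) > abs(corr.loc[("low", cls), "r"])
            zm, _ = res.z_between_groups[cls]
            # r's are negative: atanh(r_low) − atanh(r_high) > 0 when high is steeper
            assert zm.loc["low", "high"] > 0

    def test_single_patient_smoke_outputs_well_formed(self):
        patients, grouping = _study_patients({"only": 1.0}, seed=2)
        res = gr.run_gradient_study(patients[:1])
        assert set(res.voxel_table.columns) >= {"patient_id", "tissue_class",
                                                "distance_mm", "adc_mm2_per_s"}
        assert not res.correlations.empty
        assert not res.summaries.empty
        assert res.voxel_table["distance_mm"].min() >= 2.0

    def test_end_to_end_determinism(self):
        patients, grouping = _study_patients({"g": 1.0}, seed=13)
        r1 = gr.run_gradient_study(patients, grouping=grouping)
        r2 = gr.run_gradient_study(patients, grouping=grouping)
        pd.testing.assert_frame_equal(r1.voxel_table, r2.voxel_table)
        pd.testing.assert_frame_equal(r1.correlations, r2.correlations)
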