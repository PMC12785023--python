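"""Phantom generator: determinism, ground truth, recovery, degradation."""

import json

import numpy as np
import pytest
from scipy import ndimage
from sklearn.metrics import adjusted_rand_score

from msimargin import (CANONICAL_WINDOWS, hca_segment, tic_normalize,
                       window_mass_range)
from msimargin.phantom import (PhantomSpec, RegionSpec, iter_case_collection,
                               make_phantom, phantom_spec, write_fixture_suite)


def segment_window(cube, window_idx=3, k=2):
    wc = window_mass_range(tic_normalize(cube), CANONICAL_WINDOWS[window_idx])
    return hca_segment(wc, k)


def binary_ari(res, truth):
    tl, valid = truth.binary_truth()
    pred = res.label_map.labels
    m = valid & (pred != -1)
    return adjusted_rand_score(tl[m].ravel(), pred[m].ravel())


class TestDeterminism:
    def test_same_seed_identical(self):
        spec = phantom_spec(seed=5, width=24, height=24)
        c1, _ = make_phantom(spec)
        c2, _ = make_phantom(spec)
        np.testing.assert_array_equal(c1.intensities, c2.intensities)

    def test_distinct_seeds_differ(self):
        c1, _ = make_phantom(phantom_spec(seed=1, width=24, height=24))
        c2, _ = make_phantom(phantom_spec(seed=2, width=24, height=24))
        assert not np.array_equal(c1.intensities, c2.intensities)

    def test_collection_reproducible(self):
        a = next(iter_case_collection(n_cases=1, seed=9, width=20, height=20))
        b = next(iter_case_collection(n_cases=1, seed=9, width=20, height=20))
        for mode in a.cubes_by_mode:
            np.testing.assert_array_equal(a.cubes_by_mode[mode].intensities,
                                          b.cubes_by_mode[mode].intensities)


class TestGroundTruth:
    def test_uncovered_pixels_error(self):
        spec = PhantomSpec(width=8, height=8, regions=[
            RegionSpec("tumor_core_a",
                       {"kind": "disk", "cx": 4, "cy": 4, "r": 2},
                       [(500.0, 50.0, 0.1)]),
        ])
        with pytest.raises(ValueError, match="cover"):
            make_phantom(spec)

    def test_regions_and_rois_well_formed(self):
        cube, truth = make_phantom(phantom_spec(seed=3))
        assert set(np.unique(truth.region_labels)) <= set(range(len(truth.region_names)))
        roles = sorted(r.role for r in truth.rois.rois)
        assert roles == ["peritumor", "peritumor", "tumor", "tumor"]
        # ROIs never touch the margin band (not even diagonally)
        margin = truth.region_labels == truth.region_names.index("margin_band")
        near_margin = ndimage.binary_dilation(margin)
        for roi in truth.rois.rois:
            assert not (roi.mask & near_margin).any()
        # tumor ROIs sit on tumor tissue, peritumor ROIs on peritumor
        names = truth.region_names
        for roi in truth.rois.rois:
            regions = {names[i] for i in np.unique(truth.region_labels[roi.mask])}
            if roi.role == "tumor":
                assert regions <= {"tumor_core_a", "tumor_core_b"}
            else:
                assert regions == {"peritumor"}

    def test_modes_share_geometry(self):
        case = next(iter_case_collection(n_cases=1, seed=4, width=24, height=24))
        assert set(case.cubes_by_mode) == {"negative", "positive"}
        neg, pos = case.cubes_by_mode["negative"], case.cubes_by_mode["positive"]
        np.testing.assert_array_equal(neg.pixel_coords, pos.pixel_coords)
        assert not np.array_equal(neg.intensities, pos.intensities)


class TestRecovery:
    def test_high_snr_two_region_phantom_perfectly_recovered(self):
        """Tumor 885.75 at amplitude 100 vs peritumor at 10, low noise:
        binary segmentation of the 800-1000 Da window is exact (ARI 1)."""
        spec = PhantomSpec(width=16, height=16, regions=[
            RegionSpec("peritumor", {"kind": "full"}, [(885.75, 10.0, 0.05)]),
            RegionSpec("tumor_core_a",
                       {"kind": "ellipse", "cx": 10, "cy": 10, "rx": 4, "ry": 4},
                       [(885.75, 100.0, 0.05)]),
        ], noise_sd=1.0, seed=42)
        cube, truth = make_phantom(spec)
        res = segment_window(cube)
        assert binary_ari(res, truth) == pytest.approx(1.0)

    def test_default_phantom_margin_recognized(self):
        from msimargin import assess_margin

        cube, truth = make_phantom(phantom_spec(seed=11))
        res = segment_window(cube)
        assert binary_ari(res, truth) >= 0.9
        a = assess_margin(res.label_map, truth.rois)
        assert a.recognized

    def test_identical_panels_margin_not_recognized(self):
        """With tumor == peritumor chemistry there is nothing to segment:
        the margin must never be called recognized."""
        from msimargin import assess_margin

        zero = {w.label: 0.0 for w in CANONICAL_WINDOWS}
        for seed in (0, 1):
            spec = phantom_spec(seed=seed, contrast_by_window=zero)
            cube, truth = make_phantom(spec)
            res = segment_window(cube)
            a = assess_margin(res.label_map, truth.rois)
            assert not a.recognized
            assert binary_ari(res, truth) <= 0.1

    def test_noise_degrades_recovery_monotonically(self):
        """Median ARI over seeds never improves as noise grows."""
        medians = []
        for noise in (1.0, 20.0, 60.0):
            aris = []
            for seed in range(8):
                spec = phantom_spec(seed=seed, width=24, height=24,
                                    noise_sd=noise)
                cube, truth = make_phantom(spec)
                # clip at zero: negative ARI just means "no better than chance"
                aris.append(max(0.0, binary_ari(segment_window(cube), truth)))
            medians.append(np.median(aris))
        assert medians[0] >= medians[1] >= medians[2]

    def test_case_peak_panels_individual(self):
        """Per-case top-20 peak lists share few m/z values (interindividual
        variability: panels are mostly case-specific)."""
        cases = list(iter_case_collection(n_cases=5, seed=77, width=20, height=20))
        tops = []
        for case in cases:
            cube = case.cubes_by_mode["negative"]
            mean = cube.intensities.astype(np.float64).mean(axis=0)
            top = set(np.round(cube.mz_axis[np.argsort(mean)[-20:]], 1))
            tops.append(top)
        shared = [len(a & b) for i, a in enumerate(tops) for b in tops[i + 1:]]
        assert np.mean(shared) < 5


class TestFixtureSuite:
    def test_suite_layout_and_checksums(self, tmp_path):
        m1 = write_fixture_suite(tmp_path / "a", seed=123, n_cases=2,
                                 width=16, height=16)
        m2 = write_fixture_suite(tmp_path / "b", seed=123, n_cases=2,
                                 width=16, height=16)
        assert len(m1["cases"]) == 2
        for c1, c2 in zip(m1["cases"], m2["cases"]):
            assert c1["checksums"] == c2["checksums"]
        files = {f.name for f in (tmp_path / "a").iterdir()}
        assert "manifest.json" in files
        assert "case01_negative.imzML" in files
        assert "case01_rois.json" in files

    def test_fixture_imzml_reads_back(self, tmp_path):
        from msimargin import read_imzml
        from msimargin.phantom import _content_checksum

        manifest = write_fixture_suite(tmp_path, seed=321, n_cases=1,
                                       width=16, height=16)
        entry = manifest["cases"][0]
        cube = read_imzml(tmp_path / entry["files"]["negative"])
        # checksum verification detects tampering
        assert _content_checksum(cube) == entry["checksums"]["negative"]
        manifest["cases"][0]["checksums"]["negative"] = "0" * 64
        assert _content_checksum(cube) != manifest["cases"][0]["checksums"]["negative"]

    def test_truth_json_round_trips(self, tmp_path):
        write_fixture_suite(tmp_path, seed=5, n_cases=1, width=16, height=16)
        truth = json.loads((tmp_path / "case01_truth.json").read_text())
        labels = np.array(truth["region_labels"])
        assert labels.shape == (16, 16)
        assert "peritumor" in truth["region_names"]
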