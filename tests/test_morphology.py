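"""Tests of segmentation, the aspect-ratio statistic, and classification."""

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk
from sklearn.metrics import adjusted_rand_score

from dnacondense import (
    annotate_phase_diagram,
    aspect_ratio,
    classify_conditions,
    measure_condensates,
    segment_condensates,
)
from dnacondense.synthetic import gen_shapes


def render_ellipse(shape, cy, cx, ra, rb, theta=0.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    return (u / ra) ** 2 + (v / rb) ** 2 <= 1.0


class TestAspectRatio:
    def test_disc_vanishes(self):
        mask = render_ellipse((128, 128), 64, 64, 40, 40)
        assert aspect_ratio(mask).aspect_ratio < 0.05

    def test_two_to_one_ellipse_is_one_third(self):
        mask = render_ellipse((256, 256), 128, 128, 80, 40)
        ar = aspect_ratio(mask).aspect_ratio
        assert ar == pytest.approx(1.0 / 3.0, abs=0.03)

    def test_thin_rod_approaches_unity(self):
        mask = np.zeros((64, 256), dtype=bool)
        mask[30:34, 8:248] = True
        assert aspect_ratio(mask).aspect_ratio > 0.9

    @pytest.mark.parametrize("theta", [0.3, 0.9, 1.4])
    def test_rotation_invariance(self, theta):
        base = aspect_ratio(render_ellipse((256, 256), 128, 128, 80, 40)).aspect_ratio
        rot = aspect_ratio(
            render_ellipse((256, 256), 128, 128, 80, 40, theta)
        ).aspect_ratio
        assert abs(rot - base) <= 0.03

    def test_scale_invariance(self):
        small = aspect_ratio(render_ellipse((160, 160), 80, 80, 60, 30)).aspect_ratio
        large = aspect_ratio(render_ellipse((320, 320), 160, 160, 120, 60)).aspect_ratio
        assert abs(small - large) <= 0.03

    def test_single_pixel_mask_is_degenerate(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[8, 8] = True
        shape = aspect_ratio(mask)
        assert shape.degenerate and shape.aspect_ratio == 0.0

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            aspect_ratio(np.zeros((8, 8), dtype=bool))


class TestSegmentation:
    def test_blank_image_yields_nothing(self):
        assert segment_condensates(np.zeros((64, 64))) == []

    def test_five_discs_recovered_with_areas(self):
        img = np.zeros((256, 256))
        truth_areas = []
        for cy, cx, r in [(40, 40, 12), (40, 200, 18), (128, 128, 25), (210, 60, 10), (210, 210, 15)]:
            rr, cc = disk((cy, cx), r, shape=img.shape)
            img[rr, cc] = 1.0
            truth_areas.append(len(rr))
        masks = segment_condensates(img, min_area=20)
        assert len(masks) == 5
        found = sorted(m.sum() for m in masks)
        for got, want in zip(found, sorted(truth_areas)):
            assert abs(got - want) / want < 0.05

    def test_touching_blobs_split_by_watershed(self):
        img = np.zeros((128, 128))
        for cx in (50, 78):
            rr, cc = disk((64, cx), 16, shape=img.shape)
            img[rr, cc] = 1.0
        assert len(segment_condensates(img, watershed=False)) == 1
        assert len(segment_condensates(img, watershed=True, watershed_min_distance=10)) == 2

    def test_measured_aspect_ratios_track_generator_truth(self):
        img, truth = gen_shapes(
            seed=21, n_discs=3, n_ellipses=3, n_blobs=3, noise_sd=0.0
        )
        measured = measure_condensates(img, smooth_sigma=0.0)
        assert len(measured) == len(truth)
        errs = []
        for _, tr in truth.iterrows():
            d = np.hypot(measured["centroid_y"] - tr["cy"], measured["centroid_x"] - tr["cx"])
            errs.append(
                abs(measured.loc[d.idxmin(), "aspect_ratio"] - tr["target_aspect_ratio"])
            )
        assert np.mean(errs) <= 0.05


def planted_records(rng, n_per=8, sd=0.01):
    centers = {"I": (0.05, 0.7), "II": (0.1, 0.1), "III": (0.5, 0.05)}
    rows = []
    for region, (ar, mf) in centers.items():
        for _ in range(n_per):
            rows.append(
                {
                    "dna_length_bp": 1000.0,
                    "dna_concentration": 1e-6,
                    "mean_aspect_ratio": rng.normal(ar, sd),
                    "mean_mobile_fraction": rng.normal(mf, sd),
                    "truth_region": region,
                }
            )
    return pd.DataFrame(rows)


class TestClassification:
    def test_planted_clusters_recovered_perfectly(self, rng):
        records = planted_records(rng)
        out = classify_conditions(records)
        assert adjusted_rand_score(records["truth_region"], out["cluster"]) == 1.0
        # region semantics: I = most mobile, III = most irregular
        assert (out["cluster"] == records["truth_region"]).all()

    def test_permutation_invariance(self, rng):
        records = planted_records(rng)
        shuffled = records.sample(frac=1.0, random_state=5)
        out1 = classify_conditions(records)
        out2 = classify_conditions(shuffled).sort_index()
        assert (out1["cluster"] == out2["cluster"]).all()

    def test_identical_records_deterministic(self):
        records = pd.DataFrame(
            {
                "mean_aspect_ratio": [0.2] * 5,
                "mean_mobile_fraction": [0.4] * 5,
            }
        )
        out = classify_conditions(records)
        assert (out["cluster"] == "I").all()

    def test_too_few_records_raises(self):
        records = pd.DataFrame(
            {"mean_aspect_ratio": [0.1, 0.2], "mean_mobile_fraction": [0.5, 0.4]}
        )
        with pytest.raises(ValueError):
            classify_conditions(records)

    def test_undetected_rows_passed_through(self, rng):
        records = planted_records(rng)
        records["detected"] = True
        records.loc[records.index[:2], "detected"] = False
        out = classify_conditions(records)
        assert (out.loc[~out["detected"], "cluster"] == "no condensates").all()


class TestAnnotate:
    def test_empty_records_give_empty_table(self):
        out = annotate_phase_diagram(pd.DataFrame())
        assert len(out) == 0

    def test_glyphs_and_absence_flags(self, rng):
        records = planted_records(rng)
        records["detected"] = True
        records.loc[records.index[0], "detected"] = False
        records.loc[records.index[0], ["mean_aspect_ratio", "mean_mobile_fraction"]] = np.nan
        out = annotate_phase_diagram(classify_conditions(records))
        absent = out[~out["detected"]]
        assert (absent["glyph"] == "diamond").all()
        assert set(out.loc[out["detected"], "glyph"]) <= {"circle", "triangle", "square"}
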