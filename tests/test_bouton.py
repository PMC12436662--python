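"""Bouton ROIs, actin enrichment, ring autocorrelation, density, group stats."""

import numpy as np
import pytest
from scipy import stats

from caq import synth
from caq.bouton import (
    actin_enrichment,
    bouton_rois,
    cluster_density,
    compare_groups,
    grubbs_outliers,
    ring_autocorrelation,
)


def brute_force_density_count(img, mask, theta_i, theta_a):
    """Pure-python pixel-scan connected components (8-connected BFS)."""
    h, w = img.shape
    hot = [(y, x) for y in range(h) for x in range(w)
           if mask[y, x] and img[y, x] > theta_i]
    hot_set = set(hot)
    seen, n = set(), 0
    for start in hot:
        if start in seen:
            continue
        stack, comp = [start], 0
        seen.add(start)
        while stack:
            y, x = stack.pop()
            comp += 1
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    q = (y + dy, x + dx)
                    if q in hot_set and q not in seen:
                        seen.add(q)
                        stack.append(q)
        if comp > theta_a:
            n += 1
    return n


class TestBoutonRois:
    def test_roi_count_matches_planted_puncta(self):
        sc = synth.make_bouton_scene(n_puncta=12, enriched_fraction=0.5,
                                     seed=1, noise_sd=0.0)
        rois = bouton_rois(sc.image.plane(c=0))
        assert len(rois.table) == 12

    def test_empty_gfp_channel_in_rescue_mode_gives_no_rois(self):
        sc = synth.make_bouton_scene(n_puncta=6, seed=2)
        rois = bouton_rois(sc.image.plane(c=0),
                           gfp_channel=np.zeros_like(sc.image.plane(c=0)))
        assert len(rois.table) == 0

    def test_fused_elongated_blob_split_by_circularity(self):
        img = np.zeros((80, 80))
        yy, xx = np.ogrid[:80, :80]
        img[((yy - 40) ** 2 + (xx - 30) ** 2 <= 100)] = 100.0
        img[((yy - 40) ** 2 + (xx - 48) ** 2 <= 100)] = 100.0
        merged = bouton_rois(img, split_by_circularity=False)
        split = bouton_rois(img, split_by_circularity=True,
                            circularity_threshold=0.9)
        assert len(merged.table) == 1
        assert len(split.table) == 2


class TestEnrichment:
    def test_roi_holding_global_max_normalizes_to_one(self):
        sc = synth.make_bouton_scene(n_puncta=5, enriched_fraction=1.0, seed=3,
                                     noise_sd=0.0)
        rois = bouton_rois(sc.image.plane(c=0))
        table, median = actin_enrichment(rois, sc.image.plane(c=1))
        assert table.max_actin_norm.max() == pytest.approx(1.0)
        assert 0 < median <= 1

    def test_single_roi_median_is_its_value(self):
        sc = synth.make_bouton_scene(n_puncta=1, enriched_fraction=1.0, seed=4,
                                     noise_sd=0.0)
        rois = bouton_rois(sc.image.plane(c=0))
        table, median = actin_enrichment(rois, sc.image.plane(c=1))
        assert median == pytest.approx(table.max_actin_norm.iloc[0])

    def test_invariant_under_actin_rescaling(self):
        sc = synth.make_bouton_scene(n_puncta=8, enriched_fraction=0.5, seed=5,
                                     noise_sd=0.05)
        rois = bouton_rois(sc.image.plane(c=0))
        actin = sc.image.plane(c=1)
        _, m1 = actin_enrichment(rois, actin)
        _, m2 = actin_enrichment(rois, 42.0 * actin)
        assert m1 == pytest.approx(m2, rel=1e-12)

    def test_enriched_scenes_beat_background_scenes(self):
        wins = 0
        for seed in range(20):
            hi = synth.make_bouton_scene(n_puncta=10, enriched_fraction=1.0,
                                         seed=seed, noise_sd=0.05)
            lo = synth.make_bouton_scene(n_puncta=10, enriched_fraction=0.0,
                                         seed=seed + 1000, noise_sd=0.05)
            _, m_hi = actin_enrichment(bouton_rois(hi.image.plane(c=0)),
                                       hi.image.plane(c=1))
            _, m_lo = actin_enrichment(bouton_rois(lo.image.plane(c=0)),
                                       lo.image.plane(c=1))
            wins += m_hi > m_lo
        assert wins == 20

    def test_zero_actin_channel_rejected(self):
        sc = synth.make_bouton_scene(n_puncta=3, seed=6)
        rois = bouton_rois(sc.image.plane(c=0))
        with pytest.raises(ValueError, match="normalization"):
            actin_enrichment(rois, np.zeros_like(sc.image.plane(c=1)))


class TestRingAutocorrelation:
    def test_zero_lag_is_one(self):
        profile, _ = synth.make_ring_profile(noise_sd=0.0)
        res = ring_autocorrelation(profile, 0.02)
        assert res["autocorrelation"][0] == pytest.approx(1.0)

    def test_planted_period_detected(self):
        profile, _ = synth.make_ring_profile(period_um=0.19, pixel_um=0.02,
                                             length_um=10.0, noise_sd=0.0)
        res = ring_autocorrelation(profile, 0.02)
        assert 0.18 <= res["period_um"] <= 0.20

    def test_white_noise_has_no_strong_secondary_peak(self):
        rng = np.random.default_rng(0)
        res = ring_autocorrelation(rng.normal(0, 1, 500), 0.02)
        ac = res["autocorrelation"]
        n = 500
        band = 1.96 / np.sqrt(n)
        secondary = ac[1 : n // 2]
        assert np.max(secondary) < 3 * band

    def test_constant_profile_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ring_autocorrelation(np.full(100, 2.0), 0.02)


class TestDensity:
    def test_planted_cluster_count(self):
        sc = synth.make_density_scene(n_pass=3, n_fail_intensity=2,
                                      n_fail_area=2, seed=7)
        img = sc.image.plane()
        res = cluster_density(img, np.ones_like(img, bool))
        assert res.n_objects == 3

    def test_threshold_above_max_gives_zero(self):
        sc = synth.make_density_scene(seed=8)
        img = sc.image.plane()
        res = cluster_density(img, np.ones_like(img, bool),
                              theta_intensity=img.max() + 1)
        assert res.n_objects == 0

    def test_density_halves_when_area_doubles(self):
        sc = synth.make_density_scene(seed=9, shape=(128, 128))
        img = np.hstack([sc.image.plane(), np.zeros((128, 128))])
        mask_small = np.zeros_like(img, bool)
        mask_small[:, :128] = True
        mask_big = np.ones_like(img, bool)
        d_small = cluster_density(img, mask_small)
        d_big = cluster_density(img, mask_big)
        assert d_big.n_objects == d_small.n_objects
        assert d_big.density_per_px2 == pytest.approx(d_small.density_per_px2 / 2)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cluster_density(np.ones((16, 16)), np.zeros((16, 16), bool))

    def test_matches_pixel_scan_oracle(self, rng):
        for _ in range(8):
            sc = synth.make_density_scene(
                n_pass=int(rng.integers(1, 5)),
                n_fail_intensity=int(rng.integers(0, 3)),
                n_fail_area=int(rng.integers(0, 3)),
                seed=int(rng.integers(0, 2**31)), shape=(128, 128),
            )
            img = sc.image.plane()
            mask = np.ones_like(img, bool)
            res = cluster_density(img, mask)
            assert res.n_objects == brute_force_density_count(img, mask, 4000.0, 10)


class TestGroupStats:
    def test_identical_samples_p_one(self, rng):
        a = np.round(rng.normal(0, 1, 15), 1)  # ties force the MWU route check
        res = compare_groups(a, a.copy(), outlier_method="none")
        assert res["p_value"] == pytest.approx(1.0, abs=0.02)

    def test_grubbs_removes_planted_outlier(self, rng):
        a = np.append(rng.normal(0, 1, 30), 50.0)
        kept, removed = grubbs_outliers(a)
        assert 50.0 in removed
        assert len(kept) >= 29

    def test_nonnormal_data_routes_to_mann_whitney(self, rng):
        a = rng.exponential(1.0, 40) ** 3
        b = rng.exponential(1.0, 40) ** 3
        res = compare_groups(a, b, outlier_method="none")
        assert res["test"] == "mann_whitney_u"

    def test_normal_data_routes_to_welch(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0, 1, 40)
        res = compare_groups(a, b, outlier_method="none")
        assert res["test"] == "welch_t"

    def test_power_against_unit_shift(self, rng):
        rejections = 0
        for _ in range(50):
            a = rng.normal(0, 1, 50)
            b = rng.normal(1, 1, 50)
            if compare_groups(a, b, outlier_method="none")["p_value"] < 0.05:
                rejections += 1
        # large-sample normal approximation: power > 0.99 at this effect size
        assert rejections >= 49

    def test_routing_is_deterministic(self, rng):
        a = rng.normal(0, 1, 25)
        b = rng.normal(0.5, 1, 25)
        r1 = compare_groups(a, b)
        r2 = compare_groups(a, b)
        assert r1 == r2

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])
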