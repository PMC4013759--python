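"""Hypointensity detector vs brute-force flood fill, rule edge cases."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sod1mri as s
from oracles import hypointensity_percent_brute


def _volume_with_cluster(n_dark, dark_value=400.0, shape=(10, 10, 10)):
    vol = np.full(shape, 1000.0)
    dark = list(np.ndindex(*shape))[:n_dark]
    for idx in dark:
        vol[idx] = dark_value
    return vol


class TestDetectionRule:
    def test_uniform_volume_has_no_hypointensities(self):
        vol = np.full((8, 8, 8), 500.0)
        res = s.detect_hypointensities(vol, np.ones(vol.shape, bool))
        assert res.percent_hypointense == 0.0
        assert not res.clusters_retained and not res.clusters_excluded

    def test_small_cluster_counted_exactly(self):
        # 995 voxels at 1000, 5 at 400: mean 997, threshold 648.05 -> 0.5%
        vol = _volume_with_cluster(5)
        res = s.detect_hypointensities(vol, np.ones(vol.shape, bool))
        assert res.threshold_value == pytest.approx(0.65 * 997.0)
        assert res.percent_hypointense == pytest.approx(0.5)
        assert [c[0] for c in res.clusters_retained] == [5]

    def test_oversized_cluster_excluded_but_kept_in_denominator(self):
        vol = _volume_with_cluster(30)
        res = s.detect_hypointensities(vol, np.ones(vol.shape, bool))
        assert res.percent_hypointense == 0.0
        assert [c[0] for c in res.clusters_excluded] == [30]
        assert res.n_mask_voxels == 1000

    def test_tie_at_threshold_is_not_hypointense(self):
        vol = np.full((5, 5, 5), 1000.0)
        mask = np.ones(vol.shape, bool)
        mean = vol[mask].mean()
        vol[0, 0, 0] = 0.65 * mean  # exact tie under strict <
        res = s.detect_hypointensities(vol, mask)
        # value sits exactly at fraction*new_mean? recompute honestly instead:
        thr = 0.65 * vol[mask].mean()
        assert (vol[0, 0, 0] < thr) == (res.n_hypo_voxels_retained > 0)

    def test_size_cutoff_boundary_retains_20_excludes_21(self):
        for n, retained in [(20, True), (21, False)]:
            vol = _volume_with_cluster(n, shape=(12, 12, 12))
            res = s.detect_hypointensities(vol, np.ones(vol.shape, bool))
            assert (res.n_hypo_voxels_retained == n) is retained

    def test_exclude_equal_variant(self):
        vol = _volume_with_cluster(20, shape=(12, 12, 12))
        res = s.detect_hypointensities(vol, np.ones(vol.shape, bool), exclude_equal=True)
        assert res.n_hypo_voxels_retained == 0

    def test_guards(self):
        vol = np.ones((4, 4, 4))
        with pytest.raises(ValueError, match="empty"):
            s.detect_hypointensities(vol, np.zeros(vol.shape, bool))
        vol2 = vol.copy()
        vol2[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            s.detect_hypointensities(vol2, np.ones(vol.shape, bool))
        with pytest.raises(ValueError, match="connectivity"):
            s.detect_hypointensities(vol, np.ones(vol.shape, bool), connectivity=4)


class TestOracleEquivalence:
    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_on_random_volumes(self, connectivity, rng):
        for _ in range(10):
            vol = np.where(
                rng.random((16, 16, 16)) < 0.05, 30.0, 100.0
            ) + rng.normal(0, 1, (16, 16, 16))
            mask = rng.random((16, 16, 16)) < 0.9
            res = s.detect_hypointensities(vol, mask, connectivity=connectivity)
            pct, sizes = hypointensity_percent_brute(vol, mask, 0.65, 20, connectivity)
            assert res.percent_hypointense == pytest.approx(pct, abs=1e-12)
            got_sizes = sorted(
                [c[0] for c in res.clusters_retained] + [c[0] for c in res.clusters_excluded]
            )
            assert got_sizes == sizes

    @given(fraction=st.floats(min_value=0.1, max_value=0.9))
    @settings(max_examples=20)
    def test_subthreshold_count_monotone_in_fraction(self, fraction):
        rng = np.random.default_rng(5)
        vol = rng.uniform(10.0, 100.0, (12, 12, 12))
        mask = np.ones(vol.shape, bool)
        big_cutoff = vol.size  # retain everything: count = all sub-threshold
        lo = s.detect_hypointensities(vol, mask, fraction=fraction, size_cutoff=big_cutoff)
        hi = s.detect_hypointensities(vol, mask, fraction=min(fraction + 0.05, 0.95), size_cutoff=big_cutoff)
        assert hi.n_hypo_voxels_retained >= lo.n_hypo_voxels_retained

    def test_percent_invariant_to_global_rescaling(self, rng):
        vol = np.where(rng.random((14, 14, 14)) < 0.04, 25.0, 100.0)
        mask = np.ones(vol.shape, bool)
        a = s.detect_hypointensities(vol, mask)
        b = s.detect_hypointensities(vol * 37.5, mask)
        assert a.percent_hypointense == b.percent_hypointense


class TestPhantomClusters:
    def test_injected_clusters_classified_per_truth(self, noise_free_spec, noise_free_phantom):
        vs, truth = noise_free_phantom
        res = s.detect_hypointensities(vs["t2star"], truth.tissue_mask)
        truth_sizes = sorted(c["size"] for c in truth.clusters if c["retained"])
        got_sizes = sorted(c[0] for c in res.clusters_retained)
        assert got_sizes == truth_sizes
        excl = sorted(c["size"] for c in truth.clusters if not c["retained"])
        assert sorted(c[0] for c in res.clusters_excluded) == excl


class TestPerRegionReport:
    def test_identical_masks_identical_rows(self):
        vol = _volume_with_cluster(5)
        mask = np.ones(vol.shape, bool)
        rep = s.per_region_report(vol, {"a": mask, "b": mask.copy()})
        cols = ["threshold", "n_mask_voxels", "percent_hypointense"]
        assert rep.set_index("region").loc["a", cols].equals(rep.set_index("region").loc["b", cols])
        assert rep["overlaps"].all()

    def test_clusters_outside_region_do_not_count(self):
        vol = np.full((10, 10, 10), 1000.0)
        vol[0, 0, :3] = 100.0  # cluster in the "cortex" half only
        cortex = np.zeros(vol.shape, bool)
        cortex[:5] = True
        brainstem = ~cortex
        rep = s.per_region_report(vol, {"cortex": cortex, "brainstem": brainstem}).set_index("region")
        assert rep.loc["brainstem", "percent_hypointense"] == 0.0
        assert rep.loc["cortex", "percent_hypointense"] > 0.0
        assert not rep["overlaps"].any()

    def test_nested_masks_bookkeeping(self):
        vol = np.full((10, 10, 10), 1000.0)
        vol[2, 2, :3] = 100.0
        whole = np.ones(vol.shape, bool)
        sub = np.zeros(vol.shape, bool)
        sub[:5] = True
        rep = s.per_region_report(vol, {"whole": whole, "sub": sub}).set_index("region")
        # same retained voxels, larger denominator for the whole-brain mask
        assert (
            rep.loc["whole", "n_hypo_voxels_retained"]
            == rep.loc["sub", "n_hypo_voxels_retained"]
        )
        assert rep.loc["whole", "percent_hypointense"] < rep.loc["sub", "percent_hypointense"]

    def test_empty_mask_list_rejected(self):
        with pytest.raises(ValueError):
            s.per_region_report(np.ones((4, 4, 4)), {})
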