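import numpy as np
import pytest
from hypothesis import given, strategies as st

import naive_reference as naive
from tvfc.dynvar import (
    TemporalVariabilityExtractor,
    WindowScheme,
    inter_network_variability,
    intra_network_variability,
    multiscale_variability,
    regional_variability,
    segment_windows,
    window_fc,
)
from tvfc.parcellation import Parcellation
from tvfc.preprocess import RoiTimeSeries


class TestSegmentation:
    @pytest.mark.parametrize(
        "T,l,s,expected_num",
        [(240, 30, 1, 8), (240, 21, 1, 11), (240, 30, 5, 7)],
    )
    def test_window_counts(self, T, l, s, expected_num):
        windows = segment_windows(T, l, s)
        assert len(windows) == expected_num
        starts = [a for a, _ in windows]
        assert starts[0] == s - 1
        assert all(b - a == l for a, b in windows)
        # non-overlapping and in order
        assert all(windows[i][1] == windows[i + 1][0] for i in range(len(windows) - 1))

    def test_trailing_volumes_discarded(self):
        windows = segment_windows(240, 21, 1)
        assert windows[-1][1] == 231  # last 9 volumes unused

    def test_offset_bounds(self):
        with pytest.raises(ValueError):
            segment_windows(100, 20, 0)
        with pytest.raises(ValueError):
            segment_windows(100, 20, 20)

    def test_scheme_counts_all_offsets(self):
        scheme = WindowScheme()
        segs = scheme.segmentations(240)
        assert len(segs) == sum(l - 1 for l in range(21, 31)) == 245


class TestWindowFc:
    def test_affine_pair_perfectly_correlated(self, rng):
        a = rng.standard_normal(30)
        data = np.column_stack([a, 2 * a + 3, rng.standard_normal(30)])
        fc = window_fc(data, (0, 30))
        assert fc[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_negated_pair(self, rng):
        a = rng.standard_normal(30)
        data = np.column_stack([a, -a])
        fc = window_fc(data, (0, 30))
        assert fc[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_hand_computed_pearson(self):
        block = np.array(
            [
                [1.0, 2.0, 0.5],
                [2.0, 1.5, 0.1],
                [3.0, 3.5, 0.9],
                [4.0, 2.5, 0.2],
                [5.0, 4.0, 0.7],
            ]
        )
        fc = window_fc(block, (0, 5))
        for a in range(3):
            for b in range(3):
                x, y = block[:, a], block[:, b]
                num = np.sum((x - x.mean()) * (y - y.mean()))
                den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
                assert fc[a, b] == pytest.approx(num / den, abs=1e-12)

    def test_constant_roi_flagged_nan(self, rng):
        data = np.column_stack([np.full(20, 2.0), rng.standard_normal(20)])
        fc = window_fc(data, (0, 20))
        assert np.isnan(fc[0]).all() and np.isnan(fc[:, 0]).all()
        assert fc[1, 1] == 1.0

    def test_short_window_rejected(self, rng):
        with pytest.raises(ValueError):
            window_fc(rng.standard_normal((10, 3)), (0, 2))


def random_fc_stack(rng, num, R):
    """Valid symmetric unit-diagonal stacks from random data windows."""
    data = rng.standard_normal((num * 10, R))
    return np.stack([window_fc(data, (i * 10, (i + 1) * 10)) for i in range(num)])


class TestStatisticLevels:
    def test_identical_windows_give_zero(self, rng):
        fc = random_fc_stack(rng, 1, 5)[0]
        stack = np.stack([fc] * 4)
        for k in range(5):
            assert regional_variability(stack, k) == pytest.approx(0.0, abs=1e-12)
        assert intra_network_variability(stack, [0, 1, 2]) == pytest.approx(0.0, abs=1e-12)
        assert inter_network_variability(stack, [0, 1], [2, 3]) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_anticorrelated_windows_give_two(self, rng):
        fc1 = random_fc_stack(rng, 1, 6)[0]
        fc2 = -fc1.copy()
        np.fill_diagonal(fc2, 1.0)
        stack = np.stack([fc1, fc2])
        for k in range(6):
            assert regional_variability(stack, k) == pytest.approx(2.0, abs=1e-12)
        assert intra_network_variability(stack, [0, 1, 2, 3]) == pytest.approx(
            2.0, abs=1e-12
        )
        assert inter_network_variability(stack, [0, 1, 2], [3, 4]) == pytest.approx(
            2.0, abs=1e-12
        )

    def test_regional_matches_naive_oracle(self, rng):
        stack = random_fc_stack(rng, 5, 7)
        fcs = [stack[i] for i in range(5)]
        for k in range(7):
            assert regional_variability(stack, k) == pytest.approx(
                naive.naive_regional(fcs, k), abs=1e-12
            )

    def test_intra_matches_naive_oracle(self, rng):
        stack = random_fc_stack(rng, 4, 8)
        fcs = [stack[i] for i in range(4)]
        members = [1, 3, 4, 6, 7]
        assert intra_network_variability(stack, members) == pytest.approx(
            naive.naive_intra(fcs, members), abs=1e-12
        )

    def test_inter_matches_naive_oracle(self, rng):
        stack = random_fc_stack(rng, 5, 8)
        fcs = [stack[i] for i in range(5)]
        m, n = [0, 2, 5], [1, 3, 6, 7]
        assert inter_network_variability(stack, m, n) == pytest.approx(
            naive.naive_inter(fcs, m, n), abs=1e-12
        )

    def test_inter_symmetric_in_networks(self, rng):
        stack = random_fc_stack(rng, 4, 8)
        m, n = [0, 1, 4], [2, 3, 5]
        assert inter_network_variability(stack, m, n) == pytest.approx(
            inter_network_variability(stack, n, m), abs=1e-14
        )

    def test_two_roi_network_undefined(self, rng):
        stack = random_fc_stack(rng, 4, 6)
        assert np.isnan(intra_network_variability(stack, [0, 1]))

    def test_overlapping_networks_rejected(self, rng):
        stack = random_fc_stack(rng, 3, 6)
        with pytest.raises(ValueError, match="overlap"):
            inter_network_variability(stack, [0, 1, 2], [2, 3])


class TestMultiscale:
    def test_default_grid_averages_245_segmentations(self, rng, toy_parcellation):
        data = rng.standard_normal((240, 6))
        prof = multiscale_variability(data, toy_parcellation)
        assert prof.n_segmentations_used == 245

    def test_single_segmentation_equals_per_window_value(self, rng, toy_parcellation):
        data = rng.standard_normal((60, 6))
        scheme = WindowScheme(lengths=(20,), min_windows=2)
        prof = multiscale_variability(data, toy_parcellation, scheme)
        # scheme (20,) has offsets 1..19; restrict to single (l,s) via T
        scheme1 = WindowScheme(lengths=(30,), min_windows=2)
        prof1 = multiscale_variability(data, toy_parcellation, scheme1)
        assert prof1.n_segmentations_used == 1  # only s=1 keeps 2 windows
        fcs = naive.naive_fc_stack(data, naive.naive_segment(60, 30, 1))
        for k in range(6):
            assert prof1.regional.iloc[k] == pytest.approx(
                naive.naive_regional(fcs, k), abs=1e-10
            )
        assert prof.n_segmentations_used == 19

    def test_matches_naive_multiscale_reference(self, rng, toy_parcellation):
        data = rng.standard_normal((60, 6))
        scheme = WindowScheme(lengths=(8, 9, 10), min_windows=2)
        prof = multiscale_variability(data, toy_parcellation, scheme)
        expected = naive.naive_multiscale_regional(data, (8, 9, 10))
        np.testing.assert_allclose(prof.regional.values, expected, atol=1e-10)

    def test_scale_and_shift_invariance(self, rng, toy_parcellation):
        data = rng.standard_normal((120, 6))
        scaled = data * np.array([3.0, 0.5, 7.0, 1.0, 2.0, 9.0]) + np.array(
            [1.0, -4.0, 0.0, 2.5, 100.0, -7.0]
        )
        scheme = WindowScheme(lengths=(15, 20), min_windows=2)
        p1 = multiscale_variability(data, toy_parcellation, scheme)
        p2 = multiscale_variability(scaled, toy_parcellation, scheme)
        np.testing.assert_allclose(p1.regional.values, p2.regional.values, atol=1e-9)
        np.testing.assert_allclose(p1.inter.values, p2.inter.values, atol=1e-9)

    def test_periodic_series_zero_variability_at_matching_offset(self, toy_parcellation):
        rng = np.random.default_rng(7)
        block = rng.standard_normal((20, 6))
        data = np.tile(block, (6, 1))  # period 20, T=120
        scheme = WindowScheme(lengths=(20,), min_windows=2)
        # offset s=1 aligns windows with the period -> identical FC
        fcs = naive.naive_fc_stack(data, naive.naive_segment(120, 20, 1))
        stack = np.stack(fcs)
        for k in range(6):
            assert regional_variability(stack, k) == pytest.approx(0.0, abs=1e-9)

    def test_iid_noise_rois_exchangeable(self, toy_parcellation):
        # no planted dynamics: regional values within +/-0.15 of each other
        parc = Parcellation(
            tuple(f"r{i}" for i in range(10)), tuple("n1" for _ in range(10))
        )
        spreads, all_vals = [], []
        for seed in range(20):
            data = np.random.default_rng(seed).standard_normal((240, 10))
            prof = multiscale_variability(data, parc)
            vals = prof.regional.values
            spreads.append(vals.max() - vals.min())
            all_vals.append(vals)
        assert max(spreads) < 0.3
        vals = np.concatenate(all_vals)
        assert np.all(vals > 0) and np.all(vals < 2)

    def test_no_valid_segmentation_errors(self, rng, toy_parcellation):
        with pytest.raises(ValueError, match="segmentation"):
            multiscale_variability(
                rng.standard_normal((30, 6)), toy_parcellation, WindowScheme()
            )


class TestExtractor:
    def test_feature_names_and_shape(self, rng, toy_parcellation):
        X = [rng.standard_normal((60, 6)) for _ in range(3)]
        ext = TemporalVariabilityExtractor(toy_parcellation, lengths=(10, 12))
        out = ext.fit(X).transform(X)
        names = ext.get_feature_names_out()
        assert out.shape == (3, len(names))
        assert names[0] == "regional_A"
        assert "intra_net1" in names
        assert "inter_net1__net2" in names

    def test_undefined_networks_are_nan_not_zero(self, rng, toy_parcellation):
        X = [rng.standard_normal((60, 6))]
        ext = TemporalVariabilityExtractor(toy_parcellation, lengths=(10,))
        out = ext.fit(X).transform(X)[0]
        names = list(ext.get_feature_names_out())
        assert np.isnan(out[names.index("intra_net2")])  # 2-ROI network
        assert np.isnan(out[names.index("intra_net3")])  # 1-ROI network
        assert np.isfinite(out[names.index("intra_net1")])

    def test_sklearn_params_roundtrip(self, toy_parcellation):
        ext = TemporalVariabilityExtractor(toy_parcellation, lengths=(10,), fisher_z=True)
        params = ext.get_params()
        clone = TemporalVariabilityExtractor(**params)
        assert clone.get_params()["fisher_z"] is True

    def test_fisher_z_changes_values_keeps_bounds(self, rng, toy_parcellation):
        X = [rng.standard_normal((80, 6))]
        raw = TemporalVariabilityExtractor(toy_parcellation, lengths=(10,)).fit(X).transform(X)
        fz = (
            TemporalVariabilityExtractor(toy_parcellation, lengths=(10,), fisher_z=True)
            .fit(X)
            .transform(X)
        )
        assert not np.allclose(raw, fz, equal_nan=True)
        vals = fz[np.isfinite(fz)]
        assert vals.min() >= 0 and vals.max() <= 2

    def test_wrong_roi_count_rejected(self, rng, toy_parcellation):
        ext = TemporalVariabilityExtractor(toy_parcellation)
        with pytest.raises(ValueError, match="ROIs"):
            ext.fit([rng.standard_normal((60, 5))])


@given(st.integers(0, 2**31 - 1))
def test_variability_range_property(seed):
    """Any defined variability value lies in [0, 2]."""
    rng = np.random.default_rng(seed)
    num = int(rng.integers(2, 7))
    R = int(rng.integers(4, 9))
    stack = random_fc_stack(rng, num, R)
    vals = [regional_variability(stack, k) for k in range(R)]
    vals.append(intra_network_variability(stack, list(range(3))))
    vals.append(inter_network_variability(stack, [0, 1], list(range(2, R))))
    vals = np.array(vals)
    defined = vals[np.isfinite(vals)]
    assert np.all(defined >= 0.0) and np.all(defined <= 2.0)
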