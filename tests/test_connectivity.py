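"""Pearson/Fisher-Z connectivity, block averaging, paired contrasts."""

import numpy as np
import pytest
from scipy import stats

from fnirspeech.connectivity import (
    ConnectivityMatrix,
    average_blocks,
    condition_fc,
    contrast_to_csv,
    fisher_z,
    paired_contrast,
    read_contrast_csv,
    render_contrast,
)
from fnirspeech.io import EventAnnotation
from fnirspeech.montage import region_ordered_ids
from fnirspeech.preprocess import HbSeries
from fnirspeech.segmentation import build_condition_timeline

FS = 10.0


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half_maps_to_known_value(self):
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_odd_function(self, rng):
        r = rng.uniform(-0.99, 0.99, 50)
        np.testing.assert_allclose(fisher_z(-r), -fisher_z(r), rtol=1e-12)

    def test_unit_correlation_clipped(self):
        assert np.isfinite(fisher_z(1.0))
        assert fisher_z(1.0) == pytest.approx(np.arctanh(1 - 1e-7))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.5)

    def test_strictly_monotone(self, rng):
        r = np.sort(rng.uniform(-0.999, 0.999, 100))
        assert np.all(np.diff(fisher_z(r)) > 0)


def _hb_and_timeline(data, private=((70.0, 100.0),)):
    T = data.shape[0]
    dur = T / FS
    ann = EventAnnotation(
        intervals=[
            ("rest", 0.0, 60.0),
            ("preparation", 60.0, dur - 30.0),
            ("execution", dur - 30.0, dur),
        ]
        + [("private_speech", a, b) for a, b in private]
    )
    hb = HbSeries(hbo=data, hbr=-data / 3, fs=FS)
    return hb, build_condition_timeline(ann, FS, dur)


class TestConditionFC:
    def test_identical_channels_give_clipped_unit_correlation(self, rng):
        x = rng.standard_normal(3000)
        data = np.column_stack([x, x, rng.standard_normal(3000)])
        hb, tl = _hb_and_timeline(data)
        fc = condition_fc(hb, tl, "rest")
        assert fc.z[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))
        assert np.isnan(fc.z[0, 0])

    def test_independent_channels_have_small_correlations(self, rng):
        data = rng.standard_normal((6200, 20))
        hb, tl = _hb_and_timeline(data, private=())
        ann_long = EventAnnotation(intervals=[("rest", 0.0, 600.0)])
        tl = build_condition_timeline(ann_long, FS, 620.0)
        fc = condition_fc(hb, tl, "rest")
        off = np.tanh(fc.z[np.triu_indices(20, 1)])
        assert np.mean(np.abs(off) < 0.05) > 0.95

    def test_matches_brute_force_pearson_on_pooled_segments(self, rng):
        """r equals a direct-formula Pearson on the concatenated, per-segment
        demeaned samples."""
        data = rng.standard_normal((2000, 4)) + 0.3 * rng.standard_normal((2000, 1))
        hb, tl = _hb_and_timeline(data, private=((70.0, 90.0), (120.0, 150.0)))
        fc = condition_fc(hb, tl, "private")
        segs = tl.segments("private")
        pooled = np.concatenate(
            [data[s:e] - data[s:e].mean(axis=0) for s, e in segs], axis=0
        )
        for i in range(4):
            for j in range(i + 1, 4):
                xi, xj = pooled[:, i], pooled[:, j]
                r = np.sum(xi * xj) / np.sqrt(np.sum(xi**2) * np.sum(xj**2))
                assert fc.z[i, j] == pytest.approx(np.arctanh(r), abs=1e-10)

    def test_insufficient_samples_error_names_condition(self, rng):
        data = rng.standard_normal((1500, 3))
        hb, tl = _hb_and_timeline(data, private=((70.0, 71.5),))
        with pytest.raises(ValueError, match="private"):
            condition_fc(hb, tl, "private", min_samples=30)

    def test_symmetric_output(self, rng):
        data = rng.standard_normal((2000, 6))
        hb, tl = _hb_and_timeline(data)
        fc = condition_fc(hb, tl, "inner")
        off = ~np.eye(6, dtype=bool)
        np.testing.assert_allclose(fc.z[off], fc.z.T[off], rtol=1e-12)

    def test_region_ordered_40x40_with_paper_montage(self, paper_map, rng):
        data = rng.standard_normal((2000, 44))
        hb, tl = _hb_and_timeline(data)
        fc = condition_fc(hb, tl, "rest", cmap=paper_map)
        assert fc.z.shape == (40, 40)
        assert fc.channel_ids == region_ordered_ids(paper_map)
        assert fc.channel_ids[:6] == [12, 17, 21, 13, 18, 22]


def _cm(z, cond="rest", pid="p1", ids=None):
    return ConnectivityMatrix(
        z=z, condition=cond, participant_id=pid,
        channel_ids=ids or list(range(1, z.shape[0] + 1)), n_samples_used=100,
    )


class TestAverageBlocks:
    def _sym(self, rng, n=5):
        a = rng.standard_normal((n, n))
        z = (a + a.T) / 2
        np.fill_diagonal(z, np.nan)
        return z

    def test_identical_blocks_unchanged(self, rng):
        z = self._sym(rng)
        out = average_blocks(_cm(z), _cm(z))
        np.testing.assert_allclose(out.z[~np.isnan(z)], z[~np.isnan(z)])
        assert out.n_blocks == 2

    def test_mean_is_elementwise(self, rng):
        z1, z2 = self._sym(rng), self._sym(rng)
        out = average_blocks(_cm(z1), _cm(z2))
        expected = (z1 + z2) / 2
        m = ~np.isnan(expected)
        np.testing.assert_allclose(out.z[m], expected[m], rtol=1e-12)

    def test_missing_block_passes_through(self, rng):
        z = self._sym(rng)
        out = average_blocks(_cm(z), None)
        np.testing.assert_array_equal(
            np.nan_to_num(out.z), np.nan_to_num(z)
        )
        assert out.n_blocks == 1  # degenerate case flagged via block count

    def test_condition_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="condition"):
            average_blocks(_cm(self._sym(rng), "rest"), _cm(self._sym(rng), "outer"))


class TestPairedContrast:
    def _stack(self, rng, P=10, n=6, delta=0.0):
        zA = rng.standard_normal((P, n, n)) * 0.1
        zB = rng.standard_normal((P, n, n)) * 0.1
        zA = (zA + zA.transpose(0, 2, 1)) / 2 + delta
        zB = (zB + zB.transpose(0, 2, 1)) / 2
        for z in (zA, zB):
            for k in range(P):
                np.fill_diagonal(z[k], np.nan)
        return zA, zB

    def test_equal_conditions_give_null_result(self, rng):
        zA, zB = self._stack(rng)
        cm = paired_contrast(zA, zA.copy(), label="x")
        off = ~np.isnan(cm.t)
        np.testing.assert_allclose(cm.t[off], 0.0, atol=1e-12)
        np.testing.assert_allclose(cm.p[off], 1.0)
        assert not cm.mask_pos.any() and not cm.mask_neg.any()

    def test_t_matches_closed_form_on_planted_differences(self):
        """Differences {1,2,3,4,5} across participants give the closed-form
        one-sample t of the differences."""
        P, n = 5, 3
        zB = np.zeros((P, n, n))
        zA = np.zeros((P, n, n))
        for k in range(P):
            zA[k, 0, 1] = zA[k, 1, 0] = float(k + 1)
        cm = paired_contrast(zA, zB)
        expected = 3 / (np.sqrt(2.5) / np.sqrt(5))
        assert cm.t[0, 1] == pytest.approx(expected, abs=1e-10)
        assert cm.df == 4

    def test_neglog10p_and_mask_threshold(self, rng):
        """A connection with p just under 0.005 enters the signed mask and
        -log10(p) is computed elementwise."""
        P, n = 16, 4
        zA = rng.standard_normal((P, n, n)) * 0.05
        zA = (zA + zA.transpose(0, 2, 1)) / 2
        zB = zA.copy()
        zA[:, 0, 1] += 0.4
        zA[:, 1, 0] += 0.4
        zB[:, 2, 3] += 0.4
        zB[:, 3, 2] += 0.4
        cm = paired_contrast(zA, zB, alpha=0.005)
        assert cm.p[0, 1] < 0.005 and cm.mask_pos[0, 1]
        assert cm.p[2, 3] < 0.005 and cm.mask_neg[2, 3]
        finite = np.isfinite(cm.p)
        np.testing.assert_allclose(
            cm.neglog10p[finite], -np.log10(cm.p[finite]), rtol=1e-12
        )
        assert not (cm.mask_pos & cm.mask_neg).any()

    def test_neglog10_of_p_0004(self):
        assert -np.log10(0.004) == pytest.approx(2.3979, abs=1e-4)

    def test_participant_mismatch_rejected(self, rng):
        z = np.zeros((3, 3))
        a = [_cm(z.copy(), pid="p1"), _cm(z.copy(), pid="p2")]
        b = [_cm(z.copy(), pid="p1"), _cm(z.copy(), pid="p3")]
        with pytest.raises(ValueError, match="participant"):
            paired_contrast(a, b)

    def test_invariant_under_common_permutation(self, rng):
        zA, zB = self._stack(rng, delta=0.1)
        cm = paired_contrast(zA, zB)
        perm = rng.permutation(zA.shape[1])
        cm_p = paired_contrast(
            zA[:, perm][:, :, perm], zB[:, perm][:, :, perm]
        )
        np.testing.assert_allclose(
            np.nan_to_num(cm_p.t), np.nan_to_num(cm.t[np.ix_(perm, perm)]), rtol=1e-10
        )

    def test_null_calibration_at_0005(self, rng):
        """With no condition difference the p < 0.005 rate is nominal
        (500 simulated groups of 16, 40x40 matrices)."""
        P, n, reps = 16, 40, 500
        hits = total = 0
        iu = np.triu_indices(n, 1)
        for _ in range(reps):
            zA = rng.normal(0, 0.25, (P, n, n))
            zB = rng.normal(0, 0.25, (P, n, n))
            d = (zA - zB)[:, iu[0], iu[1]]  # (P, n_conn)
            t = d.mean(0) / (d.std(0, ddof=1) / np.sqrt(P))
            p = 2 * stats.t.sf(np.abs(t), P - 1)
            hits += (p < 0.005).sum()
            total += p.size
        assert abs(hits / total - 0.005) < 0.001

    def test_planted_effect_detected(self, rng):
        """A Dz = 0.4 difference at one connection (n = 16, within-subject
        SD 0.25) is detected at p < 0.005 in >= 80% of replicates."""
        P, n, reps = 16, 10, 200
        detected = 0
        for _ in range(reps):
            zA = rng.normal(0, 0.25 / np.sqrt(2), (P, n, n))
            zB = rng.normal(0, 0.25 / np.sqrt(2), (P, n, n))
            zA = (zA + zA.transpose(0, 2, 1)) / 2
            zB = (zB + zB.transpose(0, 2, 1)) / 2
            zA[:, 2, 7] += 0.4
            zA[:, 7, 2] += 0.4
            cm = paired_contrast(zA, zB, alpha=0.005)
            detected += bool(cm.mask_pos[2, 7])
        assert detected / reps >= 0.80


class TestRendering:
    def test_csv_twin_round_trips(self, tmp_path, rng):
        z = rng.standard_normal((16, 40, 40))
        cm = paired_contrast(z, np.zeros_like(z), label="demo")
        path = tmp_path / "c.csv"
        contrast_to_csv(cm, path, "t")
        mat, ids = read_contrast_csv(path)
        np.testing.assert_allclose(
            np.nan_to_num(mat), np.nan_to_num(cm.t), rtol=1e-9
        )
        assert ids == cm.channel_ids

    def test_heatmap_dimensions_and_order(self, tmp_path, paper_map, rng):
        z = rng.standard_normal((6, 40, 40)) * 0.2
        ids = region_ordered_ids(paper_map)
        cm = paired_contrast(z, np.zeros_like(z), label="demo", channel_ids=ids)
        assert cm.t.shape == (40, 40)
        fig = render_contrast(cm, paper_map, tmp_path / "c.svg")
        assert (tmp_path / "c.svg").exists()
        assert cm.channel_ids == ids
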