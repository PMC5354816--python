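"""Mark/TF occupancy, chi-squared, signal matrices and K-means clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from bivatlas.domains import ConsensusRegion
from bivatlas.intervals import GenomicInterval, PeakSet
from bivatlas.occupancy import (
    FACTORS,
    assign_marks_two_lines,
    chi_squared_2x2,
    extract_features,
    kmeans_three,
    label_clusters,
    signal_matrix,
    tf_occupancy,
)
from bivatlas.signal import SignalTrack

from oracles import pearson_chi2_2x2

GI = GenomicInterval


def region(s, e, rid="", chrom="chr1"):
    return ConsensusRegion(GI(chrom, s, e), "bivalent", frozenset(["H1"]), region_id=rid)


def flat_track(chrom="chr1", start=0, end=1_000_000, value=1.0, total=None):
    return SignalTrack(
        {chrom: (np.array([start]), np.array([end]), np.array([value]))},
        total_reads=total,
    )


class TestMarkAssignment:
    def test_requires_both_lines(self):
        r = region(1000, 3000)
        h1 = PeakSet("H1", "H3K9ac", [GI("chr1", 500, 1500)])
        h9_hit = PeakSet("H9", "H3K9ac", [GI("chr1", 2500, 4000)])
        h9_miss = PeakSet("H9", "H3K9ac", [GI("chr1", 10_000, 12_000)])
        assert assign_marks_two_lines(r, h1, h9_hit)
        assert not assign_marks_two_lines(r, h1, h9_miss)

    def test_composition_of_two_overlap_checks(self, rng):
        r = region(5000, 7000)
        for _ in range(50):
            mk = lambda line: PeakSet(
                line,
                "H2AZ",
                [
                    GI("chr1", int(s), int(s) + 800)
                    for s in rng.integers(0, 20_000, size=3)
                ],
            )
            a, b = mk("H1"), mk("H9")
            want = a.interval_set.overlaps_any(r.interval) and b.interval_set.overlaps_any(
                r.interval
            )
            assert assign_marks_two_lines(r, a, b) == want

    def test_mark_mismatch_rejected(self):
        with pytest.raises(ValueError):
            assign_marks_two_lines(
                region(0, 1000),
                PeakSet("H1", "H3K9ac", []),
                PeakSet("H9", "H2AZ", []),
            )


class TestTfOccupancy:
    def test_full_occupancy(self):
        regions = [region(0, 2000), region(5000, 7000)]
        peaks = PeakSet("H1", "EZH2", [GI("chr1", 0, 10_000)], fdr=[0.001])
        frac = tf_occupancy({"bivalent": regions}, peaks)
        assert frac["bivalent"] == 1.0

    def test_high_fdr_peak_not_counted(self):
        regions = [region(0, 2000)]
        peaks = PeakSet("H1", "EZH2", [GI("chr1", 0, 10_000)], fdr=[0.2])
        assert tf_occupancy({"bivalent": regions}, peaks)["bivalent"] == 0.0

    def test_planted_rates_recovered(self, rng):
        occupied = [region(i * 10_000, i * 10_000 + 2000, rid=f"r{i}") for i in range(100)]
        peaks, truth = [], []
        for i, r in enumerate(occupied):
            hit = rng.random() < (0.9 if i < 50 else 0.2)
            truth.append(hit)
            if hit:
                peaks.append(GI("chr1", r.interval.start + 500, r.interval.start + 900))
        ps = PeakSet("H1", "EZH2", peaks, fdr=[0.01] * len(peaks))
        frac = tf_occupancy(
            {"A": occupied[:50], "B": occupied[50:]}, ps
        )
        assert frac["A"] == np.mean(truth[:50])
        assert frac["B"] == np.mean(truth[50:])


class TestChiSquared:
    def test_identical_proportions(self):
        stat, p = chi_squared_2x2(50, 100, 50, 100)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # 90/100 vs 50/100: expected 70/30 in each group,
        # chi2 = 2*(20^2/70) + 2*(20^2/30) = 38.095...
        stat, p = chi_squared_2x2(90, 100, 50, 100)
        assert stat == pytest.approx(2 * 400 / 70 + 2 * 400 / 30, abs=1e-9)
        assert stat == pytest.approx(38.095, abs=1e-3)
        assert p < 1e-9

    def test_symmetric_in_groups(self):
        assert chi_squared_2x2(90, 100, 50, 100)[0] == pytest.approx(
            chi_squared_2x2(50, 100, 90, 100)[0]
        )

    def test_zero_expected_cell_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_2x2(0, 100, 0, 100)

    def test_matches_closed_form_on_random_tables(self, rng):
        for _ in range(200):
            na, nb = rng.integers(5, 500, size=2)
            a = int(rng.integers(1, na))
            b = int(rng.integers(1, nb))
            stat, _ = chi_squared_2x2(a, int(na), b, int(nb))
            assert stat == pytest.approx(pearson_chi2_2x2(a, int(na), b, int(nb)), abs=1e-9)


class TestSignalMatrix:
    def test_constant_track_fills_cells(self):
        mat, prof = signal_matrix([region(10_000, 12_000)], flat_track(value=2.0, total=1e6), 5000, 10)
        assert np.allclose(mat.to_numpy(), 2.0)
        assert np.allclose(prof.to_numpy(), 2.0)

    def test_track_zero_outside_region_zero_bins(self):
        track = SignalTrack(
            {"chr1": (np.array([10_000]), np.array([12_000]), np.array([3.0]))},
            total_reads=1e6,
        )
        mat, _ = signal_matrix([region(10_000, 12_000)], track, 5000, 10)
        v = mat.to_numpy()[0]
        assert v[0] == 0 and v[-1] == 0
        assert v[4] > 0 and v[5] > 0

    def test_matches_per_bin_recomputation(self, rng):
        starts = np.arange(0, 100_000, 250)
        vals = rng.random(len(starts)) * 5
        track = SignalTrack(
            {"chr1": (starts, starts + 250, vals)}, total_reads=1e6
        )
        regions = [region(int(s), int(s) + 2000, rid=f"r{i}") for i, s in enumerate(rng.integers(10_000, 80_000, 5))]
        half, nb = 4000, 16
        mat, prof = signal_matrix(regions, track, half, nb)
        for i, r in enumerate(regions):
            center = (r.interval.start + r.interval.end) // 2
            for k in range(nb):
                lo = center - half + k * (2 * half // nb)
                hi = lo + 2 * half // nb
                # direct mean over 1-bp steps of the piecewise track
                idx = np.arange(lo, hi)
                base_vals = vals[np.clip(idx // 250, 0, len(vals) - 1)]
                base_vals = np.where((idx >= 0) & (idx < 100_000), base_vals, 0.0)
                assert mat.iloc[i, k] == pytest.approx(base_vals.mean(), rel=1e-9)
        assert np.allclose(prof.to_numpy(), mat.to_numpy().mean(axis=0))

    def test_linearity_in_track_scale(self, rng):
        starts = np.arange(0, 50_000, 500)
        vals = rng.random(len(starts))
        t1 = SignalTrack({"chr1": (starts, starts + 500, vals)}, total_reads=1e6)
        t3 = SignalTrack({"chr1": (starts, starts + 500, 3 * vals)}, total_reads=1e6)
        regions = [region(20_000, 22_000)]
        m1, _ = signal_matrix(regions, t1, 3000, 12)
        m3, _ = signal_matrix(regions, t3, 3000, 12)
        assert np.allclose(m3.to_numpy(), 3 * m1.to_numpy())


class TestExtractFeatures:
    def _tracks(self, value=0.0):
        return {
            f: flat_track(value=value, total=1e6) for f in FACTORS
        }

    def test_zero_tracks_zero_vectors(self):
        feats = extract_features([region(10_000, 12_000)], self._tracks(0.0))
        assert (feats.to_numpy() == 0).all()

    def test_delta_signal_conserved(self):
        tracks = self._tracks(0.0)
        tracks["EZH2"] = SignalTrack(
            {"chr1": (np.array([10_500]), np.array([10_510]), np.array([7.0]))},
            total_reads=1e6,
        )
        feats = extract_features([region(10_000, 12_000)], tracks)
        assert feats.loc[:, "EZH2"].iloc[0] == pytest.approx(70.0)  # 10 bp * 7 RPM
        assert (feats[["PolII", "TAF1", "TCF12"]].to_numpy() == 0).all()

    def test_matches_direct_window_sums(self, rng):
        starts = np.arange(0, 60_000, 200)
        tracks = {}
        vals = {}
        for f in FACTORS:
            v = rng.random(len(starts))
            vals[f] = v
            tracks[f] = SignalTrack({"chr1": (starts, starts + 200, v)}, total_reads=1e6)
        r = region(20_000, 23_000)
        feats = extract_features([r], tracks)
        lo, hi = 19_000, 24_000
        for f in FACTORS:
            idx = np.arange(lo, hi)
            want = vals[f][idx // 200].sum()
            assert feats[f].iloc[0] == pytest.approx(want, rel=1e-9)

    def test_missing_factor_rejected(self):
        with pytest.raises(ValueError, match="missing factor"):
            extract_features([region(0, 1000)], {"EZH2": flat_track()})


def planted_blobs(rng, n=300, proportions=(0.17, 0.22, 0.61), sep=6.0):
    """Well-separated log-normal factor blobs mimicking the 3-cluster design."""
    centers = {
        1: np.array([1.0, 1.0 + sep, 1.0 + sep, 1.0]),
        2: np.array([1.0 + sep, 1.0, 1.0, 1.0 + 0.6 * sep]),
        3: np.array([1.0 + sep / 2] * 4),
    }
    labels = rng.choice([1, 2, 3], size=n, p=list(proportions))
    x = np.array([centers[l] + rng.normal(0, 1.0, 4) for l in labels])
    feats = pd.DataFrame(2.0**x, columns=list(FACTORS), index=[f"r{i}" for i in range(n)])
    return feats, pd.Series(labels, index=feats.index)


class TestKMeans:
    def test_planted_blobs_perfectly_partitioned(self, rng):
        feats, truth = planted_blobs(rng, sep=10.0)
        labels = label_clusters(kmeans_three(feats), feats)
        assert adjusted_rand_score(truth, labels) == 1.0
        assert (labels == truth).all()  # semantic labels match the construction

    def test_duplicated_dataset_same_partition(self, rng):
        feats, _ = planted_blobs(rng, n=120)
        doubled = pd.concat([feats, feats.set_index(feats.index + "_b")])
        l1 = label_clusters(kmeans_three(feats), feats)
        l2 = label_clusters(kmeans_three(doubled), doubled)
        assert (l2.loc[feats.index] == l1).all()

    def test_permutation_invariant_under_fixed_seed(self, rng):
        feats, _ = planted_blobs(rng, n=150)
        perm = feats.sample(frac=1.0, random_state=5)
        l1 = kmeans_three(feats, seed=1729, n_starts=10)
        l2 = kmeans_three(perm, seed=1729, n_starts=10)
        assert (l2.loc[feats.index] == l1).all()

    def test_too_few_distinct_points_rejected(self):
        feats = pd.DataFrame(
            [[1, 1, 1, 1]] * 5, columns=list(FACTORS), index=[f"r{i}" for i in range(5)]
        )
        with pytest.raises(ValueError, match="distinct"):
            kmeans_three(feats)


class TestLabelClusters:
    def _feats(self, rows):
        return pd.DataFrame(rows, columns=list(FACTORS), index=[f"r{i}" for i in range(len(rows))])

    def test_semantic_rules(self):
        # EZH2, PolII, TAF1, TCF12
        feats = self._feats(
            [[1, 100, 100, 1], [100, 1, 1, 50], [30, 30, 30, 30]]
        )
        raw = pd.Series([0, 1, 2], index=feats.index)
        labels = label_clusters(raw, feats)
        assert labels.tolist() == [1, 2, 3]

    def test_tie_broken_by_cluster_size(self):
        feats = self._feats(
            [[10, 50, 50, 10], [10, 50, 50, 10], [10, 50, 50, 10], [5, 5, 5, 5]]
        )
        raw = pd.Series([0, 0, 1, 2], index=feats.index)
        labels = label_clusters(raw, feats)
        # clusters 0 and 1 tie on PolII+TAF1; the larger cluster (0) wins label 1
        assert labels.iloc[0] == 1 and labels.iloc[2] != 1

    def test_requires_three_clusters(self):
        feats = self._feats([[1, 2, 3, 4], [4, 3, 2, 1]])
        with pytest.raises(ValueError):
            label_clusters(pd.Series([0, 1], index=feats.index), feats)
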