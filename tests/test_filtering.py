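"""Tests of the quality filters, each checked against a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from dimspipe.core import PeakList
from dimspipe.filtering import (
    TicProfile,
    align_samples,
    blank_filter,
    electrospray_check,
    missing_value_filter,
    replicate_filter,
    sample_filter,
    tic_filter,
)

from conftest import toy_matrix


# ---------------------------------------------------------------------------
# Brute-force oracles, deliberately naive
# ---------------------------------------------------------------------------

def oracle_cluster(mz_list, tol_ppm):
    """O(n^2) single-linkage gap clustering by repeated merging."""
    items = sorted(mz_list)
    clusters = [[m] for m in items]
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters) - 1):
            a, b = clusters[i], clusters[i + 1]
            if b[0] - a[-1] <= tol_ppm * 1e-6 * b[0]:
                clusters[i] = a + b
                del clusters[i + 1]
                changed = True
                break
    return clusters


def oracle_replicate_filter(peaklists, tol_ppm, min_present):
    entries = []
    for pl in peaklists:
        for m, i, f in zip(pl.mz, pl.intensity, pl.noise_flag):
            if f == 1:
                entries.append((m, i, pl.replicate_index))
    out = []
    for cluster in oracle_cluster([e[0] for e in entries], tol_ppm):
        members = [e for e in entries if e[0] in cluster]
        reps = {e[2] for e in members}
        if len(reps) >= min_present:
            out.append(
                (np.mean([e[0] for e in members]),
                 np.mean([e[1] for e in members]), len(reps))
            )
    return sorted(out)


def oracle_blank_removals(pm, ratio):
    removed = []
    blanks, bios = pm.blank_ids, pm.biological_ids
    for feat in pm.intensities.columns:
        bvals = pm.intensities.loc[blanks, feat].dropna()
        if len(bvals) == 0:
            continue
        xvals = pm.intensities.loc[bios, feat].dropna()
        if len(xvals) == 0 or np.median(bvals) >= ratio * np.median(xvals):
            removed.append(feat)
    return removed


def oracle_sample_removals(pm, presence):
    removed = []
    bios = pm.biological_ids
    for feat in pm.intensities.columns:
        n_obs = pm.intensities.loc[bios, feat].notna().sum()
        if n_obs / len(bios) < presence - 1e-12:
            removed.append(feat)
    return removed


def oracle_missing_removals(pm, sd_mult):
    ids = [s for s in pm.samples.index
           if pm.samples.loc[s, "sample_type"] in ("QC", "biological")]
    pcts = {s: 100.0 * pm.intensities.loc[s].isna().mean() for s in ids}
    vals = np.array(list(pcts.values()))
    thr = vals.mean() + sd_mult * vals.std(ddof=1)
    return [s for s, p in pcts.items() if p > thr]


def random_toy_matrix(rng, n_bio=8, n_qc=3, n_blank=2, n_feat=12, miss=0.3):
    types = (["biological"] * n_bio + ["QC"] * n_qc + ["blank"] * n_blank)
    vals = rng.uniform(10, 1000, (len(types), n_feat))
    mask = rng.random(vals.shape) < miss
    values = [[None if mask[i, j] else vals[i, j] for j in range(n_feat)]
              for i in range(len(types))]
    return toy_matrix(values, types)


# ---------------------------------------------------------------------------
# Electrospray check
# ---------------------------------------------------------------------------

class TestElectrospray:
    def test_all_positive_passes(self):
        traces = {"s1": [np.ones(20), np.ones(20), np.ones(20)]}
        assert electrospray_check(traces) == {"s1": True}

    def test_sustained_zero_fails_whole_sample(self):
        good = np.ones(20)
        bad = np.ones(20)
        bad[5:10] = 0.0
        assert electrospray_check({"s1": [good, bad, good]}) == {"s1": False}

    def test_isolated_zero_tolerated(self):
        trace = np.ones(20)
        trace[7] = 0.0
        assert electrospray_check({"s1": [trace]}, zero_run=3) == {"s1": True}

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            electrospray_check({"s1": [np.array([])]})


# ---------------------------------------------------------------------------
# TIC filter
# ---------------------------------------------------------------------------

class TestTicFilter:
    def test_identical_profiles_no_outliers(self):
        profiles = [TicProfile(f"s{i}", 1, np.full(7, 5.0)) for i in range(20)]
        assert tic_filter(profiles) == set()

    def test_deviant_profile_flagged_on_pc2(self):
        """Cohort varies along one dominant direction (overall TIC level =
        PC1); a sample deviating orthogonally to it lands on PC2 and is
        flagged."""
        rng = np.random.default_rng(0)
        mean = np.full(7, 150.0)
        v = np.ones(7) / np.sqrt(7)                      # common-scale direction
        w = np.array([1.0, -1, 1, -1, 1, -1, 0])
        w -= (w @ v) * v
        w /= np.linalg.norm(w)                           # orthogonal shape change
        profiles = [
            TicProfile(f"s{i}", 1, mean + rng.normal(0, 20) * v + rng.normal(0, 0.5, 7))
            for i in range(50)
        ]
        profiles.append(TicProfile("weird", 1, mean + 60.0 * w))
        assert "weird" in tic_filter(profiles)

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        profiles = [
            TicProfile(f"s{i}", 1, rng.uniform(50, 150, 7)) for i in range(30)
        ]
        flagged_fwd = tic_filter(profiles)
        flagged_rev = tic_filter(profiles[::-1])
        assert flagged_fwd == flagged_rev

    def test_too_few_profiles(self):
        profiles = [TicProfile(f"s{i}", 1, np.ones(7)) for i in range(5)]
        with pytest.raises(ValueError, match=">= 10"):
            tic_filter(profiles)


# ---------------------------------------------------------------------------
# Replicate filter
# ---------------------------------------------------------------------------

def make_pl(mz, inten, rep, flags=None):
    mz = np.asarray(mz, float)
    flags = np.ones(len(mz), int) if flags is None else np.asarray(flags, int)
    return PeakList(mz, inten, np.full(len(mz), 10.0), flags,
                    sample_id="s", replicate_index=rep)


class TestReplicateFilter:
    def test_triple_peak_mean(self):
        pls = [make_pl([100.0], [10.0], 1), make_pl([100.0], [20.0], 2),
               make_pl([100.0], [30.0], 3)]
        out = replicate_filter(pls, mz_tolerance_ppm=1.5)
        assert len(out) == 1
        assert out.intensity[0] == pytest.approx(20.0)
        assert out.num_spectra[0] == 3

    def test_singleton_removed(self):
        pls = [make_pl([100.0], [10.0], 1), make_pl([200.0], [20.0], 2),
               make_pl([200.0], [30.0], 3)]
        out = replicate_filter(pls, mz_tolerance_ppm=1.5)
        assert out.mz.tolist() == [200.0]

    def test_flag_zero_peaks_ignored(self):
        pls = [make_pl([100.0], [10.0], 1, [0]), make_pl([100.0], [20.0], 2, [0]),
               make_pl([100.0], [30.0], 3, [1])]
        out = replicate_filter(pls, mz_tolerance_ppm=1.5)
        assert len(out) == 0

    def test_more_than_three_rejected(self):
        pls = [make_pl([100.0], [1.0], i) for i in range(1, 5)]
        with pytest.raises(ValueError, match="at most 3"):
            replicate_filter(pls)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pls = []
        for rep in (1, 2, 3):
            n = int(rng.integers(1, 15))
            base = rng.choice(np.arange(100, 150, 0.5), n, replace=False)
            mz = np.sort(base * (1 + rng.normal(0, 3e-7, n)))
            while np.any(np.diff(mz) <= 0):
                mz = np.sort(base * (1 + rng.normal(0, 3e-7, n)))
            pls.append(make_pl(mz, rng.uniform(1, 100, n), rep,
                               (rng.random(n) < 0.8).astype(int)))
        out = replicate_filter(pls, mz_tolerance_ppm=2.0, min_present=2)
        expected = oracle_replicate_filter(pls, 2.0, 2)
        assert len(out) == len(expected)
        for (mz_o, int_o, n_o), mz_i, int_i, n_i in zip(
            expected, out.mz, out.intensity, out.num_spectra
        ):
            assert mz_i == pytest.approx(mz_o, rel=1e-9)
            assert int_i == pytest.approx(int_o, rel=1e-9)
            assert n_i == n_o


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def frame_for(n, types=None):
    from dimspipe.core import SampleRecord, records_to_frame

    types = types or ["biological"] * n
    recs = [
        SampleRecord(
            f"s{i}", types[i], 1, i + 1,
            "cow" if types[i] == "biological" else "none",
            f"G{i}" if types[i] == "biological" else "",
        )
        for i in range(n)
    ]
    return records_to_frame(recs)


class TestAlignSamples:
    def test_identical_lists_no_missing(self):
        from dimspipe.core import ReplicateFilteredPeakList

        rf = lambda: ReplicateFilteredPeakList([100.0, 200.0], [5.0, 6.0], [3, 3])
        pm = align_samples({"s0": rf(), "s1": rf()}, frame_for(2), 1.5)
        assert pm.intensities.shape == (2, 2)
        assert not pm.intensities.isna().any().any()

    def test_two_ppm_apart_distinct_at_one_ppm(self):
        from dimspipe.core import ReplicateFilteredPeakList

        a = ReplicateFilteredPeakList([100.0], [5.0], [3])
        b = ReplicateFilteredPeakList([100.0002], [6.0], [3])  # 2 ppm away
        pm = align_samples({"s0": a, "s1": b}, frame_for(2), 1.0)
        assert pm.n_features == 2
        assert int(pm.intensities.isna().sum().sum()) == 2

    @pytest.mark.parametrize("seed", range(50))
    def test_feature_count_matches_oracle(self, seed):
        from dimspipe.core import ReplicateFilteredPeakList

        rng = np.random.default_rng(seed)
        rfpls, all_mz = {}, []
        n_samp = int(rng.integers(2, 6))
        for i in range(n_samp):
            n = int(rng.integers(1, 12))
            mz = np.sort(rng.choice(np.arange(100, 120, 0.01), n, replace=False))
            rfpls[f"s{i}"] = ReplicateFilteredPeakList(
                mz, rng.uniform(1, 10, n), np.full(n, 3)
            )
            all_mz.extend(mz)
        pm = align_samples(rfpls, frame_for(n_samp), 5.0)
        assert pm.n_features == len(oracle_cluster(all_mz, 5.0))


# ---------------------------------------------------------------------------
# Blank / sample / missing-value filters
# ---------------------------------------------------------------------------

class TestBlankFilter:
    def test_exact_one_third_removed(self):
        pm = toy_matrix(
            [[30.0, 30.0], [30.0, 30.0], [10.0, 9.999]],
            ["biological", "biological", "blank"],
        )
        out = blank_filter(pm, ratio=1 / 3)
        assert out.n_features == 1  # the exactly-1/3 feature is removed
        assert out.features.tolist() == [200.0]

    def test_absent_from_blanks_retained(self):
        pm = toy_matrix(
            [[30.0], [30.0], [None]], ["biological", "biological", "blank"]
        )
        out = blank_filter(pm)
        assert out.n_features == 1
        assert out.blank_ids == []  # blanks dropped afterwards

    def test_requires_blanks_and_bios(self):
        pm = toy_matrix([[1.0], [2.0]], ["QC", "biological"])
        with pytest.raises(ValueError, match="blank"):
            blank_filter(pm)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        pm = random_toy_matrix(rng)
        out = blank_filter(pm, ratio=1 / 3, drop_blanks=False)
        removed = sorted(set(pm.features) - set(out.features))
        assert removed == sorted(oracle_blank_removals(pm, 1 / 3))


class TestSampleFilter:
    def test_sixteen_of_twenty_retained(self):
        vals = [[1.0] for _ in range(16)] + [[None] for _ in range(4)]
        pm = toy_matrix(vals, ["biological"] * 20)
        assert sample_filter(pm, presence=0.80).n_features == 1

    def test_fifteen_of_twenty_removed(self):
        vals = [[1.0] for _ in range(15)] + [[None] for _ in range(5)]
        pm = toy_matrix(vals, ["biological"] * 20)
        assert sample_filter(pm, presence=0.80).n_features == 0

    def test_all_present_unchanged(self):
        pm = toy_matrix([[1.0, 2.0]] * 5, ["biological"] * 5)
        out = sample_filter(pm)
        assert out.n_features == 2

    def test_qcs_not_counted(self):
        # feature seen in all QCs but only 1 of 2 biologicals -> 50% < 80%
        pm = toy_matrix(
            [[1.0], [None], [1.0], [1.0]],
            ["biological", "biological", "QC", "QC"],
        )
        assert sample_filter(pm, presence=0.80).n_features == 0

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(2000 + seed)
        pm = random_toy_matrix(rng)
        out = sample_filter(pm, presence=0.8)
        removed = sorted(set(pm.features) - set(out.features))
        assert removed == sorted(oracle_sample_removals(pm, 0.8))


class TestMissingValueFilter:
    def test_equal_missingness_none_removed(self):
        pm = toy_matrix(
            [[1.0, None, 1.0], [1.0, None, 1.0], [None, 1.0, 1.0]],
            ["biological", "biological", "QC"],
        )
        out, removed = missing_value_filter(pm)
        assert removed == []

    def test_extreme_sample_removed(self):
        vals = [[1.0] * 30 for _ in range(12)]
        vals.append([None] * 29 + [1.0])  # ~97% missing
        pm = toy_matrix(vals, ["biological"] * 12 + ["QC"])
        out, removed = missing_value_filter(pm)
        assert removed == ["S12"]
        assert "S12" not in out.intensities.index

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(3000 + seed)
        pm = random_toy_matrix(rng, miss=float(rng.uniform(0.05, 0.5)))
        _, removed = missing_value_filter(pm)
        assert sorted(removed) == sorted(oracle_missing_removals(pm, 2.0))


class TestIdempotenceAndMonotonicity:
    @pytest.mark.parametrize("seed", range(20))
    def test_filters_idempotent(self, seed):
        rng = np.random.default_rng(4000 + seed)
        pm = random_toy_matrix(rng)
        once = blank_filter(pm, drop_blanks=False)
        twice = blank_filter(once, drop_blanks=False)
        assert once.features.tolist() == twice.features.tolist()
        s_once = sample_filter(pm)
        s_twice = sample_filter(s_once)
        assert s_once.features.tolist() == s_twice.features.tolist()

    @pytest.mark.parametrize("seed", range(20))
    def test_counts_non_increasing(self, seed):
        rng = np.random.default_rng(5000 + seed)
        pm = random_toy_matrix(rng)
        a = blank_filter(pm, drop_blanks=True)
        b = sample_filter(a)
        c, _ = missing_value_filter(b)
        assert pm.n_features >= a.n_features >= b.n_features >= c.n_features
        assert pm.n_samples >= a.n_samples >= b.n_samples >= c.n_samples
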