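"""Entropy gating and the exhaustive outlier-assignment search."""

import itertools
import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import graftgrn as gg
from graftgrn.errors import (
    InvalidConfigError,
    MissingSampleError,
    NoValidPartitionError,
)


def brute_force_best(values, direction="both"):
    """Independent enumeration oracle: plain loops, stdlib statistics."""
    m = len(values)
    best = None
    for bits in itertools.product((0, 1), repeat=m):
        non = [v for v, b in zip(values, bits) if b == 0]
        out = [v for v, b in zip(values, bits) if b == 1]
        if direction == "high" and out and non and min(out) < max(non):
            continue
        n, s = len(non), m - len(non)
        if n < 2:
            continue
        sigma = statistics.stdev(non)
        if sigma <= 0:
            continue
        u = n * math.log(sigma) + 2.0 * s * math.log(math.factorial(n)) / n
        key = (u, s, bits)
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError("no valid partition")
    return best[2], best[0]


class TestEntropyScore:
    @pytest.mark.parametrize(
        "values,expected",
        [([1, 1, 1, 1], 2.0), ([0, 0, 0, 8], 0.0), ([1, 1, 2], 1.5)],
    )
    def test_closed_forms(self, values, expected):
        assert abs(gg.entropy_score(values) - expected) < 1e-12

    def test_all_zero_profile_is_an_error(self):
        with pytest.raises(InvalidConfigError):
            gg.entropy_score([0, 0, 0])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.001, 1e5), min_size=2, max_size=16))
    def test_entropy_bounded_by_log_m(self, xs):
        h = gg.entropy_score(xs)
        assert -1e-9 <= h <= np.log2(len(xs)) + 1e-9


class TestEntropyGate:
    def test_strict_threshold_at_thirty_percent(self):
        kept = gg.select_low_entropy({"a": 0.5, "b": 0.6}, n_samples=4, fraction=0.30)
        assert kept == ["a"]  # 0.30 * log2(4) = 0.6; strict inequality

    @pytest.mark.parametrize("m", range(2, 9))
    def test_uniform_profile_never_kept(self, m):
        h = gg.entropy_score([5.0] * m)
        assert gg.select_low_entropy({"g": h}, n_samples=m) == []


class TestBestAssignment:
    def test_single_high_outlier_flagged(self):
        partition, _ = gg.best_outlier_assignment([10, 10.1, 9.9, 20])
        assert partition == (0, 0, 0, 1)

    def test_partition_follows_sample_permutation(self):
        values = [10.0, 10.1, 9.9, 20.0, 30.0]
        base, _ = gg.best_outlier_assignment(values)
        perm = [3, 0, 4, 2, 1]
        shuffled, _ = gg.best_outlier_assignment([values[i] for i in perm])
        assert tuple(shuffled[j] for j in np.argsort(perm)) == base

    def test_translation_leaves_argmin_unchanged(self):
        values = np.array([3.0, 3.3, 2.9, 8.0, 3.1])
        a, _ = gg.best_outlier_assignment(values)
        b, _ = gg.best_outlier_assignment(values + 100.0)
        assert a == b

    @pytest.mark.parametrize("direction", ["high", "both"])
    def test_matches_bruteforce_oracle(self, direction):
        rng = np.random.default_rng(71)
        for _ in range(40):
            m = int(rng.integers(4, 10))
            values = rng.normal(10, 2, m)
            if rng.random() < 0.5:
                values[rng.integers(m)] *= 5  # plant a spike sometimes
            got_part, got_u = gg.best_outlier_assignment(values, direction=direction)
            exp_part, exp_u = brute_force_best(list(values), direction=direction)
            assert got_part == exp_part
            assert got_u == pytest.approx(exp_u, abs=1e-10)

    def test_constant_values_have_no_valid_partition(self):
        with pytest.raises(NoValidPartitionError):
            gg.best_outlier_assignment([4.0, 4.0, 4.0, 4.0])

    def test_exhaustive_cap(self):
        with pytest.raises(InvalidConfigError):
            gg.best_outlier_assignment(list(range(25)))

    def test_scale_invariant_ranking_within_fixed_split_sizes(self):
        # scaling by c > 0 shifts U of every assignment with n nonoutliers by
        # the same n*ln(c), so rankings within a fixed (s, n) are preserved
        rng = np.random.default_rng(5)
        values = rng.normal(10, 2, 6)
        for c in (0.01, 37.0):
            for n_out in (1, 2):
                base = [
                    (u, part) for part, u in self._all_assignments(values)
                    if sum(part) == n_out
                ]
                scaled = [
                    (u, part) for part, u in self._all_assignments(values * c)
                    if sum(part) == n_out
                ]
                assert [p for _, p in sorted(base)] == [p for _, p in sorted(scaled)]

    @staticmethod
    def _all_assignments(values):
        out = []
        m = len(values)
        for bits in itertools.product((0, 1), repeat=m):
            non = [v for v, b in zip(values, bits) if b == 0]
            if len(non) < 2:
                continue
            sigma = statistics.stdev(non)
            if sigma <= 0:
                continue
            n, s = len(non), m - len(non)
            u = n * math.log(sigma) + 2.0 * s * math.log(math.factorial(n)) / n
            out.append((bits, u))
        return out


class TestPatternSelection:
    def _results(self):
        values = pd.DataFrame(
            {
                "s1": [1.0, 1.0, 1.0],
                "s2": [1.1, 1.0, 1.05],
                "s3": [0.9, 1.1, 0.95],
                "s4": [8.0, 0.9, 1.0],
            },
            index=["spiked", "flatish", "flat2"],
        )
        return values, gg.mse_analysis(values, fraction=0.9)

    def test_empty_requirements_return_every_scored_gene(self):
        values, res = self._results()
        hits = gg.select_by_pattern(res, list(values.columns))
        assert set(hits) == set(res.index[res["selected"]])

    def test_contradictory_requirement_returns_nothing(self):
        values, res = self._results()
        hits = gg.select_by_pattern(res, list(values.columns),
                                    required_outlier_samples=["s1"],
                                    required_nonoutlier_samples=["s1"])
        assert hits == []

    def test_unknown_sample_raises(self):
        values, res = self._results()
        with pytest.raises(MissingSampleError):
            gg.select_by_pattern(res, list(values.columns), ["nope"])

    def test_planted_spikes_recovered_by_matching_pattern(self):
        # scion-specific spike genes: high in the two "scion" samples only
        rng = np.random.default_rng(77)
        samples = [f"s{i}" for i in range(8)]
        spike_cols = ["s2", "s3"]
        rows = {}
        for i in range(50):
            # near-noiseless baseline: an exactly constant background would
            # make the nonoutlier spread zero and the statistic undefined
            base = 1.0 + rng.normal(0, 1e-3, 8)
            base[2:4] = 12.0  # spike in s2, s3
            rows[f"spike{i}"] = base
        for i in range(50):
            rows[f"flat{i}"] = rng.uniform(0.5, 2.0) + rng.normal(0, 1e-3, 8)
        values = pd.DataFrame(rows, index=samples).T
        res = gg.mse_analysis(values, fraction=0.8)
        hits = gg.select_by_pattern(
            res, samples,
            required_outlier_samples=spike_cols,
            required_nonoutlier_samples=[s for s in samples if s not in spike_cols],
        )
        recovered = sum(1 for h in hits if h.startswith("spike"))
        assert recovered >= 45  # >=90 percent of the planted genes
        assert not any(h.startswith("flat") for h in hits)


class TestMSEAnalysis:
    def test_gated_genes_have_complete_records(self):
        rng = np.random.default_rng(83)
        vals = pd.DataFrame(rng.lognormal(0, 0.2, size=(30, 6)))
        vals.iloc[:5, 0] *= 50  # low-entropy spikes
        res = gg.mse_analysis(vals, fraction=0.5)
        gated = res[res["selected"]]
        assert len(gated) >= 1
        assert (gated["s"] + gated["n"] == 6).all()
        assert (gated["sigma"] > 0).all()
        assert gated["partition"].str.len().eq(6).all()

    def test_entropy_matches_direct_computation(self):
        vals = pd.DataFrame([[1, 1, 1, 1], [0.01, 0.01, 0.01, 8]],
                            index=["uniform", "peaked"], dtype=float)
        res = gg.mse_analysis(vals, fraction=0.3)
        assert res.loc["uniform", "entropy"] == pytest.approx(2.0)
        assert not res.loc["uniform", "selected"]
        assert res.loc["peaked", "selected"]
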