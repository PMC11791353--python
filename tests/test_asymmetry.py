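"""Asymmetry scan: statistic, breakpoint estimation, permutation test, bias removal."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusionskew.asymmetry import (
    AsymmetryConfig,
    cohort_scan,
    correct_positional_bias,
    detect_asymmetry,
    scan_statistic,
)
from fusionskew.synthetic_data import (
    SimProfileConfig,
    simulate_exon_profile,
    simulate_profiles,
)

from conftest import make_profile


def brute_force_scan(coverage, epsilon):
    """Independent recomputation of S(k) from plain segment means."""
    coverage = list(coverage)
    out = []
    for k in range(2, len(coverage) + 1):
        left = sum(coverage[: k - 1]) / (k - 1)
        right = sum(coverage[k - 1 :]) / (len(coverage) - k + 1)
        out.append(math.log2((right + epsilon) / (left + epsilon)))
    return np.array(out)


class TestScanStatistic:
    def test_flat_profile_near_zero(self):
        stats = scan_statistic([1, 1, 1, 1, 1, 1], epsilon=0.01)
        assert np.all(np.abs(stats) < 0.02)

    def test_step_profile_exact_value(self):
        stats = scan_statistic([1, 1, 1, 4, 4, 4], epsilon=1e-12)
        # k=4 separates the segments exactly: log2(4/1) = 2, and it is the max
        assert stats[2] == pytest.approx(2.0, abs=1e-9)
        assert np.argmax(stats) == 2

    def test_matches_brute_force_on_random_profiles(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n_exons = int(rng.integers(2, 40))
            coverage = rng.gamma(1.0, 2.0, n_exons)
            np.testing.assert_allclose(
                scan_statistic(coverage, 0.01),
                brute_force_scan(coverage, 0.01),
                atol=1e-10,
            )

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(0, 1e4, allow_nan=False, width=32), min_size=2, max_size=40),
        st.floats(1e-6, 1.0),
    )
    def test_brute_force_agreement_property(self, coverage, epsilon):
        np.testing.assert_allclose(
            scan_statistic(coverage, epsilon), brute_force_scan(coverage, epsilon), atol=1e-9
        )

    def test_too_short_profile_rejected(self):
        with pytest.raises(ValueError):
            scan_statistic([1.0], 0.01)


class TestDetectAsymmetry:
    def test_all_zero_profile_not_scanned(self):
        result = detect_asymmetry(make_profile([0] * 10), AsymmetryConfig())
        assert not result.called
        assert result.reason == "low_coverage"
        assert result.k_hat is None

    def test_too_few_exons_not_scanned(self):
        result = detect_asymmetry(make_profile([100] * 4), AsymmetryConfig())
        assert result.reason == "too_few_exons"

    def test_step_profile_recovers_breakpoint(self):
        counts = [50] * 10 + [200] * 10
        result = detect_asymmetry(make_profile(counts), AsymmetryConfig(seed=0))
        assert result.k_hat == 11
        assert result.direction == "3prime_elevated"
        assert result.s_max == pytest.approx(2.0, abs=0.01)
        assert result.p_value <= 0.01

    def test_five_prime_elevated_direction(self):
        counts = [200] * 10 + [50] * 10
        result = detect_asymmetry(make_profile(counts), AsymmetryConfig(seed=0))
        assert result.direction == "5prime_elevated"
        assert result.s_max < 0

    def test_tie_broken_to_smallest_k(self):
        # symmetric bump: |S| ties at the two flanks of the elevated block
        counts = [10.0, 10.0, 40.0, 40.0, 40.0, 40.0, 10.0, 10.0]
        profile = make_profile(counts)
        from fusionskew.asymmetry import _cut_weights

        standardized = np.abs(scan_statistic(profile.normalized, 0.01)) * _cut_weights(8)
        ties = np.flatnonzero(np.isclose(standardized, standardized.max()))
        result = detect_asymmetry(profile, AsymmetryConfig(seed=0))
        assert result.k_hat == ties[0] + 2

    def test_breakpoint_equivariant_under_prepended_exon(self):
        base = [10.0] * 8 + [40.0] * 6
        shifted = [10.0] + base
        config = AsymmetryConfig(seed=3)
        k_base = detect_asymmetry(make_profile(base), config).k_hat
        k_shift = detect_asymmetry(make_profile(shifted), config).k_hat
        assert k_shift == k_base + 1

    def test_deterministic_under_seed(self):
        profile, _ = simulate_exon_profile(SimProfileConfig(fusion_k=10, fold=3, seed=4))
        first = detect_asymmetry(profile, AsymmetryConfig(seed=9))
        second = detect_asymmetry(profile, AsymmetryConfig(seed=9))
        assert first == second
        third = detect_asymmetry(profile, AsymmetryConfig(seed=10))
        assert third.k_hat == first.k_hat  # estimate is seed-free

    def test_simulated_fusion_recovered(self):
        config = SimProfileConfig(n_exons=29, fusion_k=20, fold=4.0, seed=21)
        profile, truth = simulate_exon_profile(config)
        result = detect_asymmetry(profile, AsymmetryConfig(seed=2))
        assert abs(result.k_hat - truth.fusion_k) <= 1
        assert result.direction == "3prime_elevated"

    def test_null_profiles_rarely_called(self):
        # permutation p is valid: at alpha 0.01 the null call rate stays near 1%
        calls = 0
        for i in range(100):
            profile, _ = simulate_exon_profile(SimProfileConfig(seed=3000 + i))
            result = detect_asymmetry(profile, AsymmetryConfig(alpha=0.01, seed=i))
            calls += result.called
        assert calls <= 5

    def test_power_monotone_in_fold(self):
        folds = [1.5, 2.0, 4.0, 8.0]
        rates = []
        for fold in folds:
            hits = 0
            for i in range(40):  # matched seeds across folds
                profile, _ = simulate_exon_profile(
                    SimProfileConfig(fusion_k=20, fold=fold, seed=7000 + i)
                )
                hits += detect_asymmetry(profile, AsymmetryConfig(seed=i)).p_value <= 0.05
            rates.append(hits / 40)
        assert all(a <= b + 0.05 for a, b in zip(rates, rates[1:]))


class TestCorrectPositionalBias:
    def test_flat_profiles_are_fixed_point(self):
        profiles = [
            make_profile([50.0] * 12, lengths=[100.0] * 12, gene_id=f"G{i}")
            for i in range(60)
        ]
        adjusted = correct_positional_bias(profiles)
        for before, after in zip(profiles, adjusted):
            np.testing.assert_allclose(after.normalized, before.normalized, rtol=1e-9)

    def test_too_few_genes_returns_unchanged_with_warning(self):
        profiles = [make_profile([50.0] * 12, gene_id=f"G{i}") for i in range(5)]
        with pytest.warns(UserWarning, match="scannable genes"):
            adjusted = correct_positional_bias(profiles)
        for before, after in zip(profiles, adjusted):
            np.testing.assert_allclose(after.normalized, before.normalized)

    def test_global_ramp_flattened(self):
        config = SimProfileConfig(bias_strength=2.0, mean_depth=2.0, dispersion=0.01, seed=8)
        profiles, _ = simulate_profiles(150, config)
        adjusted = correct_positional_bias(profiles)
        # mean log2 ratio of last vs first exon drops from ~1 to ~0
        def mean_edge_ratio(ps):
            return np.mean([np.log2((p.normalized[-1] + 0.01) / (p.normalized[0] + 0.01)) for p in ps])

        assert mean_edge_ratio(profiles) > 0.7
        assert abs(mean_edge_ratio(adjusted)) < 0.2

    def test_fusion_breakpoint_survives_correction(self):
        config = SimProfileConfig(seed=12)
        profiles, _ = simulate_profiles(100, config)
        fusion, _ = simulate_exon_profile(
            replace(config, fusion_k=20, fold=4.0, seed=555), gene_id="FUS"
        )
        adjusted = correct_positional_bias(profiles + [fusion])
        result = detect_asymmetry(adjusted[-1], AsymmetryConfig(seed=1))
        assert result.k_hat == 20


class TestCohortScan:
    def test_empty_input_gives_empty_table(self):
        frame = cohort_scan([])
        assert frame.empty
        assert "q_value" in frame.columns

    def test_fusion_gene_ranks_first_among_nulls(self):
        config = SimProfileConfig(seed=31)
        profiles, _ = simulate_profiles(100, config)
        fusion, _ = simulate_exon_profile(
            replace(config, fusion_k=20, fold=8.0, seed=77), gene_id="FUSION"
        )
        # enough permutations that the p-value floor 1/(B+1) clears BH at m=101
        frame = cohort_scan(profiles + [fusion], AsymmetryConfig(seed=5, n_permutations=2500))
        scanned = frame[frame["reason"] == "ok"]
        fusion_row = frame[frame["gene_id"] == "FUSION"].iloc[0]
        assert fusion_row["q_value"] == scanned["q_value"].min()
        assert fusion_row["called"]
        assert abs(fusion_row["k_hat"] - 20) <= 1

    def test_called_implies_q_below_alpha(self):
        config = SimProfileConfig(seed=41)
        profiles, _ = simulate_profiles(30, config)
        frame = cohort_scan(profiles, AsymmetryConfig(seed=2, alpha=0.05))
        called = frame[frame["called"] == True]  # noqa: E712
        assert (called["q_value"] <= 0.05).all()

    def test_byte_identical_rerun(self, tmp_path):
        profiles, _ = simulate_profiles(20, SimProfileConfig(seed=51))
        config = AsymmetryConfig(seed=3)
        paths = []
        for name in ("a.tsv", "b.tsv"):
            path = tmp_path / name
            cohort_scan(profiles, config).to_csv(path, sep="\t", index=False)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_order_invariance(self):
        profiles, _ = simulate_profiles(15, SimProfileConfig(seed=61))
        config = AsymmetryConfig(seed=4)
        forward = cohort_scan(profiles, config)
        backward = cohort_scan(profiles[::-1], config)
        import pandas as pd

        pd.testing.assert_frame_equal(forward, backward)


def test_config_validation():
    with pytest.raises(ValueError):
        AsymmetryConfig(epsilon=0)
    with pytest.raises(ValueError):
        AsymmetryConfig(min_exons=3)
    with pytest.raises(ValueError):
        AsymmetryConfig(n_permutations=10)
    with pytest.raises(ValueError):
        AsymmetryConfig(alpha=1.5)
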