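"""Profile correlation, permutation null, and empirical p-value contracts."""

import numpy as np
import pytest
from scipy.stats import ks_2samp, pearsonr

from chemonet import (
    DrugProfile,
    build_profiles,
    compare_drug_pairs,
    default_screen_config,
    empirical_pvalue,
    exhaustive_null,
    generate_screen,
    permutation_null,
    profile_correlation,
    score_screen,
)
from chemonet.errors import DegenerateProfileError, InputError
from chemonet.similarity import NullDistribution, fisher_z_pvalue


def prof(drug, values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = tuple(genes or (f"g{i}" for i in range(len(values))))
    return DrugProfile(drug=drug, day=7, genes=genes, values=values)


class TestProfileCorrelation:
    def test_self_correlation_is_one(self):
        x = prof("x", [0.1, -1.2, 0.7])
        assert profile_correlation(x, x) == pytest.approx(1.0)

    def test_antisymmetry(self):
        x = prof("x", [0.1, -1.2, 0.7])
        y = prof("y", -x.values)
        assert profile_correlation(x, y) == pytest.approx(-1.0)

    def test_hand_example_matches_reference(self):
        x, y = prof("x", [1, 2, 3]), prof("y", [2, 4, 7])
        r = profile_correlation(x, y)
        # closed form: 5 / sqrt(2 * 114 / 9)
        assert r == pytest.approx(0.9933992677987828, abs=1e-12)
        assert r == pytest.approx(pearsonr([1, 2, 3], [2, 4, 7]).statistic)

    def test_spearman_is_rank_based(self):
        x, y = prof("x", [1, 2, 3]), prof("y", [10, 100, 1000])
        assert profile_correlation(x, y, "spearman") == pytest.approx(1.0)

    def test_zero_variance_is_loud_error(self):
        with pytest.raises(DegenerateProfileError):
            profile_correlation(prof("x", [1, 1, 1]), prof("y", [1, 2, 3]))

    def test_mismatched_gene_order_rejected(self):
        x = prof("x", [1, 2, 3], genes=("a", "b", "c"))
        y = prof("y", [1, 2, 3], genes=("c", "b", "a"))
        with pytest.raises(InputError):
            profile_correlation(x, y)


class TestPermutationNull:
    def test_fixed_seed_reproducible(self):
        x, y = prof("x", [1, 2, 3, 4, 5]), prof("y", [3, 1, 4, 1, 5])
        a = permutation_null(x, y, 200, seed=11)
        b = permutation_null(x, y, 200, seed=11)
        assert np.array_equal(a.values, b.values)
        assert len(a.values) == 200
        assert np.all(np.abs(a.values) <= 1 + 1e-12)

    def test_degenerate_profile_is_loud_error(self):
        with pytest.raises(DegenerateProfileError):
            permutation_null(prof("x", [2, 2, 2]), prof("y", [1, 2, 3]), 10, 0)

    def test_zero_profiles_rejected(self):
        x, y = prof("x", [1, 2, 3]), prof("y", [3, 1, 4])
        with pytest.raises(InputError):
            permutation_null(x, y, 0, seed=0)

    def test_length3_sampled_null_supported_on_enumeration(self):
        """All sampled correlations appear in the 3!x3! enumerated set."""
        x, y = prof("x", [1.0, 2.0, 4.0]), prof("y", [0.0, 1.0, 3.0])
        full = exhaustive_null(x, y)
        assert len(full) == 36
        sampled = permutation_null(x, y, 500, seed=3).values
        assert all(np.isclose(full, v, atol=1e-9).any() for v in sampled)

    def test_exhaustive_matches_independent_enumeration(self):
        """The oracle itself agrees with a from-scratch enumeration."""
        from itertools import permutations

        x, y = prof("x", [1.0, 2.0, 4.0]), prof("y", [0.0, 1.0, 3.0])
        expected = sorted(
            float(np.corrcoef(px, py)[0, 1])
            for px in permutations(x.values)
            for py in permutations(y.values)
        )
        assert np.allclose(sorted(exhaustive_null(x, y)), expected)

    def test_sampled_converges_to_enumeration_length5(self):
        """KS distance between the sampled and fully enumerated null < 0.05."""
        x = prof("x", [0.3, -1.0, 0.2, 1.4, -0.6])
        y = prof("y", [1.0, 0.1, -0.4, 0.8, -2.0])
        full = exhaustive_null(x, y)  # 5!^2 = 14,400 pairs
        sampled = permutation_null(x, y, 10_000, seed=5).values
        assert ks_2samp(sampled, full).statistic < 0.05

    def test_resampling_variant_runs(self):
        x, y = prof("x", [1, 2, 3, 4]), prof("y", [4, 3, 2, 1])
        null = permutation_null(x, y, 100, seed=1, resample=True)
        assert np.isfinite(null.values).all()


class TestEmpiricalPvalue:
    def null(self, values):
        return NullDistribution(np.asarray(values, float), len(values), None)

    def test_plus_one_counting(self):
        assert empirical_pvalue(0.25, self.null([0.1, 0.2, 0.3])) == 0.5

    def test_observed_above_all(self):
        assert empirical_pvalue(0.99, self.null([0.1, 0.2, 0.3])) == 0.25

    def test_observed_below_all_is_one(self):
        assert empirical_pvalue(0.0, self.null([0.1, 0.2, 0.3])) == 1.0

    def test_two_sided_uses_magnitudes(self):
        p = empirical_pvalue(-0.25, self.null([0.1, -0.2, 0.3]), "two_sided")
        assert p == 0.5

    def test_nan_rejected(self):
        with pytest.raises(InputError):
            empirical_pvalue(float("nan"), self.null([0.1]))

    def test_always_positive(self):
        rng = np.random.default_rng(0)
        null = self.null(rng.uniform(-1, 1, 999))
        for obs in (-1.0, 0.0, 0.5, 1.0):
            assert 0 < empirical_pvalue(obs, null) <= 1


class TestCalibrationAndPower:
    def test_superuniform_under_independence(self):
        """Independent profiles: p <= 0.05 in at most ~5% of pairs (quick
        check at 100 pairs; the full 500-pair bound runs in acceptance)."""
        rng = np.random.default_rng(42)
        hits = 0
        for i in range(100):
            x = prof("x", rng.normal(size=30))
            y = prof("y", rng.normal(size=30))
            r = profile_correlation(x, y)
            null = permutation_null(x, y, 199, seed=1000 + i)
            if empirical_pvalue(r, null) <= 0.05:
                hits += 1
        assert hits <= 10

    def test_power_on_shared_planted_module(self):
        """Profiles sharing a 20/90-gene strongly sensitive module are
        detected (p <= 0.05) in >= 90% of seeded runs."""
        detected = 0
        n_runs = 100
        for seed in range(n_runs):
            rng = np.random.default_rng(10_000 + seed)
            base = np.zeros(90)
            base[:20] = -1.3  # shared strong-sensitivity module
            x = prof("x", base + rng.normal(0, 0.05, 90))
            y = prof("y", base + rng.normal(0, 0.05, 90))
            r = profile_correlation(x, y)
            null = permutation_null(x, y, 999, seed=seed)
            if empirical_pvalue(r, null) <= 0.05:
                detected += 1
        assert detected >= 0.90 * n_runs


class TestBuildProfiles:
    def test_alignment_imputation_and_order(self, default_screen):
        screen, _ = default_screen
        scores = score_screen(screen)
        profiles = build_profiles(scores, day=7)
        lengths = {len(p.values) for p in profiles.values()}
        assert lengths == {90}
        orders = {p.genes for p in profiles.values()}
        assert len(orders) == 1
        assert "WT" not in next(iter(orders))

    def test_missing_day_errors(self, default_screen):
        screen, _ = default_screen
        with pytest.raises(InputError):
            build_profiles(score_screen(screen), day=5)


@pytest.fixture(scope="module")
def profiles():
    screen, _ = generate_screen(default_screen_config(seed=3))
    return build_profiles(score_screen(screen), day=7)


class TestCompareDrugPairs:
    def test_pair_count_and_columns(self, profiles):
        table = compare_drug_pairs(profiles, n_profiles=199, seed=0)
        assert len(table) == 15  # C(6, 2)
        assert list(table.columns) == [
            "drug_a", "drug_b", "method", "correlation", "n_profiles",
            "p_value", "q_value", "seed",
        ]

    def test_deterministic_and_order_invariant(self, profiles):
        a = compare_drug_pairs(profiles, 199, seed=4)
        shuffled = dict(reversed(list(profiles.items())))
        b = compare_drug_pairs(shuffled, 199, seed=4)
        assert a.equals(b)

    def test_shared_module_pairs_significant(self, profiles):
        table = compare_drug_pairs(profiles, 999, seed=0).set_index(
            ["drug_a", "drug_b"]
        )
        assert table.loc[("CPT", "MMS"), "p_value"] <= 0.05
        assert table.loc[("CPT", "HU"), "p_value"] <= 0.05
        assert table.loc[("SAHA", "cisplatin"), "p_value"] > 0.05


def test_fisher_z_crosscheck_agrees_roughly_with_permutation():
    rng = np.random.default_rng(7)
    x = prof("x", rng.normal(size=60))
    y = prof("y", x.values * 0.6 + rng.normal(size=60))
    r = profile_correlation(x, y)
    p_perm = empirical_pvalue(r, permutation_null(x, y, 9999, seed=1))
    p_z = fisher_z_pvalue(r, 60)
    assert (p_perm <= 0.01) == (p_z <= 0.01)
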