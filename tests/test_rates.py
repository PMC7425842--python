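import numpy as np
import pytest

from kinerr import (
    Decision,
    DecisionPolicy,
    Relationship,
    classify,
    estimate_rates,
    exact_rates_bruteforce,
    rates_from_samples,
    sample_log10_lrs,
)
from kinerr.rates import write_histograms_csv, write_rates_csv

from conftest import make_freqset, make_marker

B100 = DecisionPolicy.binary(100)
B1000 = DecisionPolicy.binary(1000)
T100 = DecisionPolicy.ternary(0.01, 100)


class TestClassify:
    def test_inclusion_at_threshold(self):
        assert classify(100.0, B100) is Decision.INCLUSION

    def test_inconclusive_interval_is_open(self):
        assert classify(50.0, T100) is Decision.INCONCLUSIVE
        assert classify(0.01, T100) is Decision.EXCLUSION
        assert classify(100.0, T100) is Decision.INCLUSION

    def test_zero_lr_is_exclusion(self):
        assert classify(0.0, B100) is Decision.EXCLUSION
        assert classify(0.0, T100) is Decision.EXCLUSION

    def test_binary_below_threshold_is_exclusion(self):
        assert classify(99.999, B100) is Decision.EXCLUSION

    def test_policy_validation(self):
        with pytest.raises(ValueError):
            DecisionPolicy.binary(1.0)
        with pytest.raises(ValueError):
            DecisionPolicy.ternary(1.5, 100)
        with pytest.raises(ValueError):
            DecisionPolicy("BINARY", 100, t_excl=0.01)
        with pytest.raises(ValueError):
            classify(-1.0, B100)


class TestEstimateRates:
    def test_deterministic_given_seed(self, toy2_freqs):
        results = [
            estimate_rates(Relationship.FULL_SIB, toy2_freqs, B100, 5000, seed=3)
            for _ in range(2)
        ]
        (t1, hr1, hu1), (t2, hr2, hu2) = results
        assert t1 == t2
        assert np.array_equal(hr1.decade_counts, hr2.decade_counts)
        assert hr1.zero_count == hr2.zero_count

    def test_streaming_batches_change_nothing(self, toy2_freqs):
        full, _, _ = estimate_rates(
            Relationship.FULL_SIB, toy2_freqs, B100, 5000, seed=3
        )
        # batching only alters how many cases each engine call draws;
        # rates stay within Monte-Carlo noise of the unbatched run
        batched, _, _ = estimate_rates(
            Relationship.FULL_SIB, toy2_freqs, B100, 5000, seed=3, batch_size=700
        )
        assert batched.n_sims == full.n_sims == 5000
        assert abs(batched.fn_rate - full.fn_rate) < 5 * max(full.fn_se, 1e-3)

    def test_unreachable_threshold_zero_false_positives(self, freqs15):
        table, _, _ = estimate_rates(
            Relationship.TRIO, freqs15, DecisionPolicy.binary(1e9), 10_000, seed=1
        )
        assert table.fp_rate == 0.0

    def test_histograms_conserve_n_sims(self, toy2_freqs):
        _, h_rel, h_unrel = estimate_rates(
            Relationship.PARENT_CHILD, toy2_freqs, B100, 4000, seed=2
        )
        assert h_rel.n_sims == 4000
        assert h_unrel.n_sims == 4000

    def test_invalid_n_sims(self, toy2_freqs):
        with pytest.raises(ValueError):
            estimate_rates(Relationship.TRIO, toy2_freqs, B100, 0, seed=1)


class TestWorkedParentChildExample:
    """One biallelic 50/50 locus, threshold 1.5: only identical
    homozygote pairs (joint probability 1/4 under parent-child) reach
    LR = 2; every other parent-child pair sits at LR = 1."""

    def test_exact_enumeration_fn_is_three_quarters(self, toy_pc_freqs):
        table = exact_rates_bruteforce(
            Relationship.PARENT_CHILD, toy_pc_freqs, DecisionPolicy.binary(1.5)
        )
        assert table.fn_rate == pytest.approx(0.75, abs=1e-12)
        assert table.n_sims is None

    def test_monte_carlo_converges_to_exact(self, toy_pc_freqs):
        n = 100_000
        table, _, _ = estimate_rates(
            Relationship.PARENT_CHILD, toy_pc_freqs, DecisionPolicy.binary(1.5),
            n, seed=7,
        )
        se = np.sqrt(0.75 * 0.25 / n)
        assert abs(table.fn_rate - 0.75) < 4 * se


class TestExactOracle:
    def test_unrelated_pair_never_included(self, toy2_freqs):
        table = exact_rates_bruteforce(
            Relationship.UNRELATED_PAIR, toy2_freqs, B100
        )
        assert table.fp_rate == 0.0

    @pytest.mark.parametrize(
        "relationship", [Relationship.FULL_SIB, Relationship.HALF_SIB]
    )
    def test_monte_carlo_agrees_with_enumeration(self, toy2_freqs, relationship):
        policy = DecisionPolicy.binary(1.5)
        exact = exact_rates_bruteforce(relationship, toy2_freqs, policy)
        n = 100_000
        mc, _, _ = estimate_rates(relationship, toy2_freqs, policy, n, seed=5)
        for attr in ("fn_rate", "fp_rate"):
            p = getattr(exact, attr)
            se = np.sqrt(max(p * (1 - p), 1e-12) / n)
            assert abs(getattr(mc, attr) - p) <= 4 * se + 1e-9

    def test_ternary_enumeration_probabilities_sum(self, toy2_freqs):
        policy = DecisionPolicy.ternary(0.9, 1.5)
        t = exact_rates_bruteforce(Relationship.FULL_SIB, toy2_freqs, policy)
        # related arm: exclusion + inconclusive + inclusion = 1
        assert 0 <= t.fn_rate + t.inconclusive_related <= 1

    def test_state_space_cap(self, freqs15):
        with pytest.raises(ValueError, match="Monte-Carlo"):
            exact_rates_bruteforce(Relationship.FULL_SIB, freqs15, B100)

    def test_trio_unsupported(self, toy2_freqs):
        with pytest.raises(ValueError, match="pairwise"):
            exact_rates_bruteforce(Relationship.TRIO, toy2_freqs, B100)


@pytest.fixture(scope="module")
def pc_samples(freqs15):
    related = sample_log10_lrs(Relationship.PARENT_CHILD, True, freqs15, 20_000, 13)
    unrelated = sample_log10_lrs(Relationship.PARENT_CHILD, False, freqs15, 20_000, 14)
    return related, unrelated


class TestPolicyProperties:
    def test_threshold_monotonicity_on_fixed_sample(self, pc_samples):
        """Raising t_incl can only add false negatives and remove false
        positives when the LR sample is held fixed."""
        related, unrelated = pc_samples
        lo = rates_from_samples(related, unrelated, B100)
        hi = rates_from_samples(related, unrelated, B1000)
        assert hi.fn_rate >= lo.fn_rate
        assert hi.fp_rate <= lo.fp_rate

    def test_ternary_fn_no_greater_than_binary(self, pc_samples):
        related, unrelated = pc_samples
        binary = rates_from_samples(related, unrelated, B100)
        ternary = rates_from_samples(related, unrelated, T100)
        assert ternary.fn_rate <= binary.fn_rate
        assert ternary.fp_rate == binary.fp_rate

    def test_decision_counts_partition_sample(self, pc_samples):
        related, _ = pc_samples
        counts = related.decision_counts(T100)
        assert sum(counts.values()) == related.n


def test_rate_table_validation(toy2_freqs):
    from kinerr import RateTable

    with pytest.raises(ValueError):
        RateTable("X", "p", B100, 10, fn_rate=1.5, fp_rate=0.0)


def test_csv_outputs(tmp_path, toy2_freqs):
    import pandas as pd

    table, h_rel, h_unrel = estimate_rates(
        Relationship.FULL_SIB, toy2_freqs, T100, 2000, seed=1
    )
    write_rates_csv([table], tmp_path / "rates.csv")
    df = pd.read_csv(tmp_path / "rates.csv")
    assert df.shape[0] == 1
    assert {"relationship", "panel", "mode", "t_incl", "t_excl", "n_sims",
            "fn_rate", "fp_rate", "inconclusive_related",
            "inconclusive_unrelated", "fn_se", "fp_se"} <= set(df.columns)
    write_histograms_csv([h_rel, h_unrel], tmp_path / "hist.csv")
    hist = pd.read_csv(tmp_path / "hist.csv")
    assert hist["count"].sum() == 2 * 2000
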