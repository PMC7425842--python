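import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from kinerr import (
    Genotype,
    MutationMode,
    MutationPolicy,
    PAIRWISE_PRESETS,
    Relationship,
    RelationshipHypothesis,
    combined_lr,
    genotype_prob,
    pairwise_lr_locus,
    simulate_case,
    trio_lr_locus,
)

from conftest import make_freqset, make_marker
from oracles import all_genotypes, pairwise_lr_enum, trio_pi_enum

PC = PAIRWISE_PRESETS["PARENT_CHILD"]
FS = PAIRWISE_PRESETS["FULL_SIB"]
UNREL = PAIRWISE_PRESETS["UNRELATED"]
RATE_FLOOR = MutationPolicy(MutationMode.RATE_FLOOR, mu=0.002)


class TestGenotypeProb:
    def test_homozygote(self):
        m = make_marker("m", (0.2, 0.8))
        assert genotype_prob(Genotype("8", "8"), m) == pytest.approx(0.04)

    def test_heterozygote(self):
        m = make_marker("m", (0.2, 0.3, 0.5))
        assert genotype_prob(Genotype("8", "9"), m) == pytest.approx(0.12)

    def test_normalizes_over_all_genotypes(self):
        m = make_marker("m", (0.2, 0.3, 0.5))
        assert sum(genotype_prob(g, m) for g in all_genotypes(m)) == pytest.approx(1.0)

    def test_unknown_allele(self):
        m = make_marker("m", (0.5, 0.5))
        with pytest.raises(KeyError):
            genotype_prob(Genotype("8", "99"), m)


class TestPairwiseLR:
    def test_unrelated_hypothesis_is_identity(self, marker4):
        for g1, g2 in itertools.product(all_genotypes(marker4), repeat=2):
            assert pairwise_lr_locus(g1, g2, UNREL, marker4) == 1.0

    def test_full_sib_worked_example(self):
        # G1 = G2 = aa with p_a = 0.5: 1/4 + 1/2 * 2 + 1/4 * 4 = 2.25
        m = make_marker("m", (0.5, 0.5))
        g = Genotype("8", "8")
        assert pairwise_lr_locus(g, g, FS, m) == pytest.approx(2.25, abs=1e-12)

    def test_parent_child_exclusion(self):
        m = make_marker("m", (0.25, 0.25, 0.25, 0.25))
        assert pairwise_lr_locus(Genotype("8", "8"), Genotype("9", "10"), PC, m) == 0.0

    def test_mismatch_gives_k0(self, marker4):
        g1, g2 = Genotype("8", "8"), Genotype("9", "10")
        for hyp in (FS, PAIRWISE_PRESETS["HALF_SIB"], PAIRWISE_PRESETS["FIRST_COUSIN"]):
            assert pairwise_lr_locus(g1, g2, hyp, marker4) == pytest.approx(hyp.k[0])

    @pytest.mark.parametrize("preset", sorted(PAIRWISE_PRESETS))
    def test_matches_enumeration_oracle_exhaustively(self, marker4, preset):
        hyp = PAIRWISE_PRESETS[preset]
        for g1, g2 in itertools.product(all_genotypes(marker4), repeat=2):
            expected = pairwise_lr_enum(g1, g2, hyp.k, marker4)
            assert pairwise_lr_locus(g1, g2, hyp, marker4) == pytest.approx(
                expected, abs=1e-12
            )

    @pytest.mark.parametrize("preset", sorted(PAIRWISE_PRESETS))
    def test_symmetry(self, marker4, preset):
        hyp = PAIRWISE_PRESETS[preset]
        for g1, g2 in itertools.combinations(all_genotypes(marker4), 2):
            assert pairwise_lr_locus(g1, g2, hyp, marker4) == pytest.approx(
                pairwise_lr_locus(g2, g1, hyp, marker4), abs=1e-12
            )

    @given(
        freqs=st.lists(
            st.floats(0.05, 1.0), min_size=2, max_size=4
        ),
        k_raw=st.tuples(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)),
        idx=st.tuples(
            st.integers(0, 3), st.integers(0, 3), st.integers(0, 3), st.integers(0, 3)
        ),
    )
    def test_matches_oracle_for_arbitrary_k(self, freqs, k_raw, idx):
        """IBD-mixture LR equals brute-force enumeration for any k."""
        total = sum(freqs)
        m = make_marker("m", tuple(f / total for f in freqs))
        ks = sum(k_raw)
        if ks == 0:
            k = (1.0, 0.0, 0.0)
        else:
            k = tuple(x / ks for x in k_raw)
        hyp = RelationshipHypothesis.pairwise(*k)
        n = len(m.alleles)
        g1 = Genotype(m.alleles[idx[0] % n], m.alleles[idx[1] % n])
        g2 = Genotype(m.alleles[idx[2] % n], m.alleles[idx[3] % n])
        assert pairwise_lr_locus(g1, g2, hyp, m) == pytest.approx(
            pairwise_lr_enum(g1, g2, k, m), abs=1e-12
        )

    def test_rate_floor_rescues_exclusion(self):
        m = make_marker("m", (0.25, 0.25, 0.25, 0.25))
        g1, g2 = Genotype("8", "8"), Genotype("9", "10")
        lr = pairwise_lr_locus(g1, g2, PC, m, RATE_FLOOR)
        assert 0 < lr < 0.1


class TestTrioPI:
    def test_worked_example_one_over_pb(self):
        # mother aa, child ab, alleged father bb -> PI = 1 / p_b
        m = make_marker("m", (0.9, 0.1))
        pi = trio_lr_locus(
            Genotype("8", "8"), Genotype("8", "9"), Genotype("9", "9"), m
        )
        assert pi == pytest.approx(10.0, abs=1e-12)

    def test_paternal_exclusion_strict_zero(self):
        m = make_marker("m", (0.25, 0.25, 0.25, 0.25))
        pi = trio_lr_locus(
            Genotype("8", "8"), Genotype("8", "9"), Genotype("10", "10"), m
        )
        assert pi == 0.0

    def test_paternal_exclusion_rate_floor(self):
        m = make_marker("m", (0.25, 0.25, 0.25, 0.25))
        pi = trio_lr_locus(
            Genotype("8", "8"), Genotype("8", "9"), Genotype("10", "10"), m,
            RATE_FLOOR,
        )
        assert 0 < pi < 0.1

    def test_matches_enumeration_oracle_exhaustively(self):
        m = make_marker("m", (0.2, 0.3, 0.5))
        genotypes = all_genotypes(m)
        for gm, gc, gaf in itertools.product(genotypes, repeat=3):
            expected = trio_pi_enum(gm, gc, gaf, m)
            if expected is None:
                # maternal mismatch: implementation falls back to the
                # motherless duo LR between child and alleged father
                expected = pairwise_lr_enum(gaf, gc, (0, 1, 0), m)
            assert trio_lr_locus(gm, gc, gaf, m) == pytest.approx(
                expected, abs=1e-12
            )

    def test_mean_pi_over_random_men_is_one(self):
        # E[PI] = 1 over alleged fathers drawn from the population, by
        # construction of the random-man denominator
        m = make_marker("m", (0.2, 0.3, 0.5))
        p = dict(zip(m.alleles, m.freqs))
        gm, gc = Genotype("8", "9"), Genotype("8", "9")
        mean = 0.0
        for x, y in itertools.product(m.alleles, repeat=2):
            mean += p[x] * p[y] * trio_lr_locus(gm, gc, Genotype(x, y), m)
        assert mean == pytest.approx(1.0, abs=1e-12)

    def test_uninformative_mother_closed_forms(self):
        """Mother aa / child ab: trio PI is T_AF(b)/p_b; the motherless
        duo averages over which child allele is paternal, so the two
        coincide exactly in the symmetric case (p_a = p_b, AF = ab)."""
        m = make_marker("m", (0.3, 0.3, 0.4))
        gm, gc = Genotype("8", "8"), Genotype("8", "9")
        p_b = 0.3
        for gaf, t_af_b in [
            (Genotype("9", "9"), 1.0),
            (Genotype("9", "10"), 0.5),
            (Genotype("10", "10"), 0.0),
        ]:
            assert trio_lr_locus(gm, gc, gaf, m) == pytest.approx(
                t_af_b / p_b, abs=1e-12
            )
        sym = pairwise_lr_locus(Genotype("8", "9"), gc, PC, m)
        assert trio_lr_locus(gm, gc, Genotype("8", "9"), m) == pytest.approx(
            sym, abs=1e-12
        )


class TestCombinedLR:
    def test_unrelated_hypothesis_combined_is_one(self, toy2_freqs, rng):
        case = simulate_case(Relationship.FULL_SIB, True, toy2_freqs, rng)
        res = combined_lr(case, UNREL, toy2_freqs)
        assert res.combined == 1.0
        assert res.log10_combined == 0.0

    def test_product_law_fifteen_loci(self):
        from kinerr import FrequencySet, MultilocusGenotype, STRPanel
        from kinerr.pedigree import SimulatedCase

        markers = {f"L{i}": make_marker(f"L{i}", (0.5, 0.5)) for i in range(15)}
        panel = STRPanel("p15", tuple(markers))
        fs = FrequencySet("pop", panel, markers)
        hom = MultilocusGenotype({m: Genotype("8", "8") for m in markers})
        case = SimulatedCase(
            Relationship.PARENT_CHILD,
            {"person1": hom, "person2": hom},
            truth_related=True,
        )
        res = combined_lr(case, PC, fs)
        assert all(lr == pytest.approx(2.0) for lr in res.per_locus.values())
        assert res.combined == pytest.approx(2 ** 15)
        assert res.log10_combined == pytest.approx(15 * math.log10(2))

    def test_single_zero_locus_annihilates(self, toy2_freqs):
        from kinerr import MultilocusGenotype
        from kinerr.pedigree import SimulatedCase

        g1 = MultilocusGenotype(
            {"L1": Genotype("8", "8"), "L2": Genotype("8", "8")}
        )
        g2 = MultilocusGenotype(
            {"L1": Genotype("9", "10"), "L2": Genotype("8", "8")}
        )
        case = SimulatedCase(
            Relationship.PARENT_CHILD, {"person1": g1, "person2": g2}, True
        )
        res = combined_lr(case, PC, toy2_freqs)
        assert res.per_locus["L1"] == 0.0
        assert res.combined == 0.0
        assert res.log10_combined == -math.inf

    def test_structure_mismatch_rejected(self, toy2_freqs, rng):
        trio = simulate_case(Relationship.TRIO, True, toy2_freqs, rng)
        with pytest.raises(ValueError, match="incompatible"):
            combined_lr(trio, PC, toy2_freqs)
        pair = simulate_case(Relationship.FULL_SIB, True, toy2_freqs, rng)
        with pytest.raises(ValueError, match="incompatible"):
            combined_lr(pair, RelationshipHypothesis.trio(), toy2_freqs)

    def test_parent_child_pairs_never_excluded_without_mutation(
        self, toy2_freqs, rng
    ):
        for _ in range(100):
            case = simulate_case(Relationship.PARENT_CHILD, True, toy2_freqs, rng)
            assert combined_lr(case, PC, toy2_freqs).combined > 0


def test_lr_report_csv(tmp_path, toy2_freqs, rng):
    import pandas as pd

    from kinerr.lr import write_lr_report

    case = simulate_case(Relationship.PARENT_CHILD, True, toy2_freqs, rng)
    res = combined_lr(case, PC, toy2_freqs)
    path = tmp_path / "report.csv"
    write_lr_report({"case0": ("PARENT_CHILD", res)}, path)
    df = pd.read_csv(path)
    assert list(df.columns) == ["case_id", "hypothesis", "marker", "lr"]
    combined_row = df[df.marker == "combined"]
    assert combined_row["lr"].iloc[0] == pytest.approx(res.combined)
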