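"""Mappability-corrected quantification and the binomial two-group LRT."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats
from scipy.special import xlogy

from genebirth.quant import (QuantError, assign_reads, bh_fdr, de_table,
                             effective_length, filter_short_mappable,
                             group_samples, lrt_de, revcomp, rpmk)

from conftest import make_catalog


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def brute_force_unique_kmers(transcripts, k):
    """Independent oracle: explicit per-gene k-mer sets and cross-gene diff."""
    sets = {}
    for gene, seqs in transcripts.items():
        sets[gene] = {s[i:i + k] for s in seqs for i in range(len(s) - k + 1)}
    out = {}
    for gene, mine in sets.items():
        others = set().union(*(s for g, s in sets.items() if g != gene)) if len(sets) > 1 else set()
        out[gene] = len(mine - others)
    return out


class TestEffectiveLength:
    def test_single_unique_transcript(self, rng):
        seq = _random_seq(rng, 100)
        assert effective_length({"g": [seq]}, k=32) == {"g": 69}

    def test_shared_terminal_block(self, rng):
        """Two 50-nt genes sharing a terminal 40-nt block: 10 unique windows each."""
        shared = _random_seq(rng, 40)
        a = _random_seq(rng, 10) + shared
        b = _random_seq(rng, 10) + shared
        lengths = effective_length({"A": [a], "B": [b]}, k=32)
        assert lengths == {"A": 10, "B": 10}

    def test_transcript_shorter_than_k(self):
        assert effective_length({"g": ["A" * 31]}, k=32) == {"g": 0}

    def test_duplicate_kmers_within_gene_count_once(self):
        seq = "ACGT" * 20  # period-4 repeat: only 4 distinct 32-mers
        assert effective_length({"g": [seq]}, k=32) == {"g": 4}

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            transcripts = {
                f"g{i}": [_random_seq(rng, int(rng.integers(20, 400)))
                          for _ in range(int(rng.integers(1, 3)))]
                for i in range(int(rng.integers(2, 6)))
            }
            # splice a shared block into two genes to create multi-mapping
            donor = transcripts["g0"][0]
            if len(donor) > 60:
                transcripts["g1"][0] = donor[:60] + transcripts["g1"][0]
            for k in (8, 32):
                assert effective_length(transcripts, k) == \
                    brute_force_unique_kmers(transcripts, k)


class TestAssignReads:
    @pytest.fixture()
    def toy(self, rng):
        shared = _random_seq(rng, 50)
        a = _random_seq(rng, 50) + shared
        b = _random_seq(rng, 50) + shared
        return {"A": [a], "B": [b]}, shared

    def test_unique_read_counted(self, toy):
        transcripts, _ = toy
        read = transcripts["A"][0][:32]
        res = assign_reads([read], transcripts)
        assert res.counts["A"] == 1 and res.total_assigned == 1

    def test_shared_block_read_discarded(self, toy):
        transcripts, shared = toy
        res = assign_reads([shared[:32]], transcripts)
        assert res.n_multi_gene == 1 and res.total_assigned == 0

    def test_reverse_complement_matches_unless_stranded(self, toy):
        transcripts, _ = toy
        read = revcomp(transcripts["B"][0][:32])
        assert assign_reads([read], transcripts).counts["B"] == 1
        assert assign_reads([read], transcripts, stranded=True).n_unmatched == 1

    def test_conservation(self, toy, rng):
        transcripts, shared = toy
        reads = [transcripts["A"][0][:32], shared[:32], _random_seq(rng, 32)]
        res = assign_reads(reads, transcripts)
        assert res.total_assigned + res.n_multi_gene + res.n_unmatched == res.n_input == 3


class TestRPMK:
    def test_unit_case(self):
        assert rpmk(1000, 1000, 1_000_000) == 1000.0

    def test_closed_form(self):
        assert rpmk(250, 500, 2_000_000) == 250.0

    def test_total_scaling(self):
        assert rpmk(100, 1000, 2_000_000) == rpmk(100, 1000, 1_000_000) / 2

    def test_zero_length_rejected(self):
        with pytest.raises(QuantError):
            rpmk(10, 0, 1_000_000)


class TestShortMappableFilter:
    def test_mechanism_specific_exclusion(self):
        catalog = make_catalog(["dup", "retro", "denovo", "dup_ok"],
                               mechanism="unknown")
        catalog["mechanism"] = ["dna_duplicate", "retrogene", "de_novo", "dna_duplicate"]
        lengths = {"dup": 29, "retro": 29, "denovo": 10, "dup_ok": 30}
        retained, excluded = filter_short_mappable(catalog, lengths, min_bp=30)
        assert excluded == ["dup", "retro"]           # strict <30, duplicates only
        assert retained == ["denovo", "dup_ok"]       # de novo never excluded


def lrt_oracle(x1, n1, x2, n2):
    """Numerical-maximization oracle for the two-group binomial LRT."""
    def nll(p, x, n):
        return -(xlogy(x, p) + xlogy(n - x, 1 - p))
    null = optimize.minimize_scalar(
        lambda p: nll(p, x1, n1) + nll(p, x2, n2), bounds=(1e-12, 1 - 1e-12),
        method="bounded", options={"xatol": 1e-14})
    alt1 = optimize.minimize_scalar(lambda p: nll(p, x1, n1),
                                    bounds=(1e-12, 1 - 1e-12), method="bounded",
                                    options={"xatol": 1e-14})
    alt2 = optimize.minimize_scalar(lambda p: nll(p, x2, n2),
                                    bounds=(1e-12, 1 - 1e-12), method="bounded",
                                    options={"xatol": 1e-14})
    return 2 * (null.fun - alt1.fun - alt2.fun)


class TestLRT:
    def test_equal_rates_give_null(self):
        lam, p = lrt_de(30, 1000, 60, 2000)
        assert lam == 0.0 and p == 1.0

    def test_matches_numerical_maximization(self):
        lam, _ = lrt_de(10, 10**6, 40, 10**6)
        assert lam == pytest.approx(lrt_oracle(10, 10**6, 40, 10**6), abs=1e-8)

    def test_equals_g_test_of_2x2(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(50, 5000, size=2)
            x1 = rng.integers(1, n1); x2 = rng.integers(1, n2)
            lam, _ = lrt_de(x1, n1, x2, n2)
            g, _, _, _ = stats.chi2_contingency(
                [[x1, n1 - x1], [x2, n2 - x2]], correction=False,
                lambda_="log-likelihood")
            assert lam == pytest.approx(g, abs=1e-8)

    def test_symmetric_and_nonnegative(self, rng):
        x1, n1, x2, n2 = 17, 400, 3, 250
        lam_a, p_a = lrt_de(x1, n1, x2, n2)
        lam_b, p_b = lrt_de(x2, n2, x1, n1)
        assert lam_a == pytest.approx(lam_b) and lam_a >= 0

    def test_invalid_counts_rejected(self):
        with pytest.raises(QuantError):
            lrt_de(5, 3, 1, 10)
        with pytest.raises(QuantError):
            lrt_de(1, 0, 1, 10)


class TestBH:
    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_step_up_arithmetic(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_dominates_bonferroni(self, ps):
        q = bh_fdr(ps)
        bonf = np.minimum(1.0, np.asarray(ps) * len(ps))
        assert set(np.nonzero(bonf < 0.05)[0]) <= set(np.nonzero(q < 0.05)[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(QuantError):
            bh_fdr([0.5, 1.5])


class TestDETable:
    def test_direction_calls(self):
        counts1 = pd.Series({"up": 400, "down": 50, "flat": 100})
        counts2 = pd.Series({"up": 50, "down": 400, "flat": 100})
        calls = de_table(counts1, 10_000, counts2, 10_000, labels=("g1", "g2"))
        by_gene = calls.set_index("gene_id")["direction"]
        assert by_gene["up"] == "g1" and by_gene["down"] == "g2"
        assert by_gene["flat"] == "unbiased"


class TestGroupSamples:
    def test_planted_blocks_recovered(self, rng):
        base = rng.lognormal(0, 1, size=200)
        shift = np.exp(rng.normal(0, 2, size=200))
        cols = {}
        for i in range(3):
            cols[f"a{i}"] = base * rng.lognormal(0, 0.05, 200)
        for i in range(3):
            cols[f"b{i}"] = base * shift * rng.lognormal(0, 0.05, 200)
        expr = pd.DataFrame(cols)
        labels = group_samples(expr)
        assert len({labels[f"a{i}"] for i in range(3)}) == 1
        assert len({labels[f"b{i}"] for i in range(3)}) == 1
        assert labels["a0"] != labels["b0"]

    def test_order_invariant_up_to_swap(self, rng):
        expr = pd.DataFrame(rng.lognormal(0, 1, size=(100, 5)),
                            columns=list("vwxyz"))
        first = group_samples(expr)
        second = group_samples(expr[list("zyxwv")])
        pairs_first = {(s, t): first[s] == first[t] for s in "vwxyz" for t in "vwxyz"}
        pairs_second = {(s, t): second[s] == second[t] for s in "vwxyz" for t in "vwxyz"}
        assert pairs_first == pairs_second

    def test_two_samples_split_trivially(self):
        expr = pd.DataFrame({"s1": [1, 2, 3], "s2": [3, 2, 1]})
        assert set(group_samples(expr).values()) == {1, 2}

    def test_degenerate_input_rejected(self):
        expr = pd.DataFrame({"s1": [1, 2, 3], "s2": [2, 4, 6], "s3": [0.5, 1, 1.5]})
        with pytest.raises(QuantError):
            group_samples(expr)  # perfectly correlated profiles
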