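"""Counting-estimator unit tests against independent brute-force oracles.

The oracles deliberately avoid the package's own genetic-code machinery:
translation goes through Bio.Seq and pathway enumeration is written as a
fresh recursion, so agreement is meaningful.
"""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, strategies as st

from evorate.codon import (
    STANDARD_CODE,
    SimulationParams,
    count_differences,
    count_sites,
    estimate_pair,
    jukes_cantor,
    random_coding_sequence,
    simulate_pair,
)
from evorate.errors import CodonError, SaturationError, StopCodonError

BASES = "ACGT"
SENSE = [
    "".join(c) for c in itertools.product(BASES, repeat=3)
    if str(Seq("".join(c)).translate()) != "*"
]


def oracle_sites(codon):
    """Brute force over the nine neighbours, translation via biopython."""
    aa = str(Seq(codon).translate())
    s = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            nb = codon[:pos] + b + codon[pos + 1:]
            nb_aa = str(Seq(nb).translate())
            if nb_aa != "*" and nb_aa == aa:
                s += 1 / 3
    return s, 3 - s


def oracle_differences(c1, c2):
    """Exhaustive pathway enumeration with stop-path exclusion."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    paths = []
    for order in itertools.permutations(positions):
        cur, steps, blocked = c1, [], False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if str(Seq(nxt).translate()) == "*" and nxt != c2:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        if not blocked:
            paths.append(steps)
    assert paths, f"all pathways blocked for {c1}->{c2}"
    sd = nd = 0.0
    for steps in paths:
        for a, b in steps:
            if str(Seq(a).translate()) == str(Seq(b).translate()):
                sd += 1
            else:
                nd += 1
    return sd / len(paths), nd / len(paths)


class TestCountSites:
    def test_matches_bruteforce_for_all_sense_codons(self):
        for codon in SENSE:
            s, n = count_sites(codon)
            es, en = oracle_sites(codon)
            assert s == pytest.approx(es, abs=1e-12), codon
            assert s + n == 3.0

    @pytest.mark.parametrize(
        "codon,s", [("TTT", 1 / 3), ("CTG", 4 / 3), ("ATG", 0.0)]
    )
    def test_worked_examples(self, codon, s):
        got_s, got_n = count_sites(codon)
        assert got_s == pytest.approx(s)
        assert got_n == pytest.approx(3 - s)

    @pytest.mark.parametrize("bad", ["TAA", "TGA", "TAG"])
    def test_stop_codon_rejected(self, bad):
        with pytest.raises(CodonError):
            count_sites(bad)

    def test_ambiguous_codon_rejected(self):
        with pytest.raises(CodonError):
            count_sites("ANT")


class TestCountDifferences:
    def test_matches_pathway_oracle_on_sample(self):
        # the full 61x61 sweep lives in the acceptance suite; a seeded
        # subsample keeps this fast while exercising 1/2/3-step pairs
        rng = np.random.default_rng(7)
        for _ in range(300):
            c1, c2 = rng.choice(SENSE, size=2)
            d = count_differences(c1, c2)
            esd, end = oracle_differences(c1, c2)
            assert d.sd == pytest.approx(esd, abs=1e-12), (c1, c2)
            assert d.nd == pytest.approx(end, abs=1e-12), (c1, c2)
            hamming = sum(a != b for a, b in zip(c1, c2))
            assert d.sd + d.nd == pytest.approx(hamming)

    @pytest.mark.parametrize(
        "c1,c2,sd,nd",
        [("TTT", "TTC", 1.0, 0.0), ("TTT", "GTA", 0.5, 1.5), ("AAA", "AAA", 0.0, 0.0)],
    )
    def test_worked_examples(self, c1, c2, sd, nd):
        d = count_differences(c1, c2)
        assert (d.sd, d.nd) == (pytest.approx(sd), pytest.approx(nd))

    def test_symmetric(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            c1, c2 = rng.choice(SENSE, size=2)
            assert count_differences(c1, c2) == count_differences(c2, c1)

    def test_no_sense_pair_needs_stop_fallback(self):
        assert not any(
            count_differences(c1, c2).used_stop_paths
            for c1 in SENSE for c2 in SENSE
        )

    def test_stop_codon_rejected(self):
        with pytest.raises(StopCodonError):
            count_differences("TAA", "TTT")


class TestJukesCantor:
    def test_zero(self):
        assert jukes_cantor(0.0) == 0.0

    def test_closed_form(self):
        assert jukes_cantor(0.3) == pytest.approx(-0.75 * math.log(1 - 0.4))
        assert jukes_cantor(0.3) == pytest.approx(0.3831192178, abs=1e-9)

    def test_correction_inflates(self):
        for p in (0.05, 0.2, 0.5, 0.7):
            assert jukes_cantor(p) >= p

    def test_saturation(self):
        with pytest.raises(SaturationError):
            jukes_cantor(0.75)


class TestEstimatePair:
    def test_identical_sequences(self):
        seq = "TTTCTGATG"
        c = estimate_pair(seq, seq)
        assert c.ds == 0 and c.dn == 0 and c.omega is None

    def test_two_codon_toy(self):
        c = estimate_pair("TTTTTC", "TTCTTC")
        assert c.sd == pytest.approx(1.0)
        assert c.nd == pytest.approx(0.0)
        assert c.dn == 0.0
        assert c.omega == 0.0

    def test_internal_stop_flags_pseudogene(self):
        with pytest.raises(StopCodonError):
            estimate_pair("TTTTAA", "TTTAAA")

    def test_gap_rejected(self):
        with pytest.raises(CodonError):
            estimate_pair("TT-TTC", "TTCTTC")

    def test_site_counts_sum_to_three_per_codon(self):
        rng = np.random.default_rng(3)
        a = random_coding_sequence(40, rng)
        b = random_coding_sequence(40, rng)
        c = estimate_pair(a, b)
        assert c.s_sites + c.n_sites == pytest.approx(3 * 40)

    @given(st.integers(0, 1000))
    def test_symmetry(self, seed):
        a, b = simulate_pair(
            SimulationParams(omega_true=0.5, t=0.4, n_codons=30, seed=seed)
        )
        assert estimate_pair(a, b) == estimate_pair(b, a)

    def test_column_permutation_invariance(self, rng):
        a, b = simulate_pair(
            SimulationParams(omega_true=0.5, t=0.4, n_codons=30, seed=77)
        )
        perm = rng.permutation(30)
        ap = "".join(a[3 * i: 3 * i + 3] for i in perm)
        bp = "".join(b[3 * i: 3 * i + 3] for i in perm)
        c1, c2 = estimate_pair(a, b), estimate_pair(ap, bp)
        # float sums in permuted order: compare to tolerance, not bitwise
        assert c1.s_sites == pytest.approx(c2.s_sites)
        assert c1.sd == pytest.approx(c2.sd)
        assert c1.nd == pytest.approx(c2.nd)
        assert c1.omega == pytest.approx(c2.omega)


class TestSimulator:
    def test_no_time_no_change(self):
        anc, der = simulate_pair(SimulationParams(omega_true=0.5, t=0.0, seed=1))
        assert anc == der

    def test_deterministic_given_seed(self):
        p = SimulationParams(omega_true=0.3, t=0.5, n_codons=100, seed=9)
        assert simulate_pair(p) == simulate_pair(p)

    def test_purifying_limit_only_synonymous_changes(self):
        p = SimulationParams(omega_true=0.0, t=0.5, n_codons=300, seed=4)
        anc, der = simulate_pair(p)
        c = estimate_pair(anc, der)
        assert c.nd == 0.0
        assert c.sd > 0

    def test_neutral_recovery_kappa_one(self):
        # 50 replicates at omega=1, kappa=1: mean estimate within 0.15 of 1
        vals = []
        for seed in range(50):
            anc, der = simulate_pair(
                SimulationParams(omega_true=1.0, kappa=1.0, t=0.3,
                                 n_codons=2000, seed=seed)
            )
            vals.append(estimate_pair(anc, der).omega)
        assert abs(np.mean(vals) - 1.0) < 0.15
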