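"""Melting temperature and structure screens.

The Tm oracle here is an independent hand-coded nearest-neighbor sum
(unified parameter set with the Owczarzy monovalent correction), kept
separate from the package's Tm engine.
"""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from forkpcr.oligos import revcomp
from forkpcr.reference_primers import BP, FORK1, FORK2, NSP_TRIPLES
from forkpcr.thermo import (
    StructureThresholds,
    ThermoConditions,
    dimer_scan,
    hairpin_scan,
    melt_temp,
    severe_hits,
    terminal_inverted_repeat,
)

# ---- independent NN oracle (unified parameters, kcal/mol and cal/mol/K) ----

_NN = {
    "AA": (-7.6, -21.3), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_INIT = (0.2, -5.7)
_TERMINAL_AT = (2.2, 6.9)


def oracle_tm(seq: str, mono_mM: float, primer_nM: float) -> float:
    dh, ds = _INIT  # duplex initiation
    for end in (seq[0], seq[-1]):
        if end in "AT":
            dh += _TERMINAL_AT[0]
            ds += _TERMINAL_AT[1]
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if pair not in _NN:
            pair = revcomp(pair)
        h, s = _NN[pair]
        dh += h
        ds += s
    k = primer_nM * 1e-9
    tm_k = (dh * 1000) / (ds + 1.987 * math.log(k))
    # Owczarzy 2004 monovalent correction on 1/Tm
    fgc = sum(seq.count(b) for b in "GC") / len(seq)
    mon = mono_mM / 1000.0
    inv = 1 / tm_k + (4.29 * fgc - 3.95) * 1e-5 * math.log(mon) + 9.40e-6 * math.log(mon) ** 2
    return 1 / inv - 273.15


MONOVALENT_ONLY = ThermoConditions(monovalent_mM=50, mg_mM=0, dntp_mM=0, primer_uM=0.2)


class TestMeltTemp:
    def test_stem_within_design_window(self):
        assert 57 <= melt_temp(FORK1.stem) <= 68

    def test_full_length_primer_is_hot(self):
        assert 71 <= melt_temp(FORK1.pfp.seq) <= 79

    def test_all_stems_and_branches_in_window(self):
        segments = [FORK1.stem, FORK2.stem, FORK1.pfp_branch, FORK2.pfp_branch, BP.seq]
        for seg in segments:
            assert 57 <= melt_temp(seg) <= 68, seg

    def test_monotonic_in_length(self):
        assert melt_temp("ATGCTGCTCGTGGATGACTCT") > melt_temp("ATGCTGCTCGTG")

    @pytest.mark.parametrize("seq", ["ACGTACG", "A" * 65])
    def test_range_errors(self, seq):
        with pytest.raises(ValueError):
            melt_temp(seq)

    def test_deterministic_to_hundredth(self):
        a = melt_temp(FORK1.stem)
        assert a == melt_temp(FORK1.stem) == round(a, 2)

    def test_agrees_with_independent_oracle(self, random_dna):
        # 50 random 18-41-mers under monovalent-only conditions
        for i in range(50):
            n = 18 + (i * 7) % 24
            seq = random_dna(n, seed=1000 + i)
            ours = melt_temp(seq, MONOVALENT_ONLY)
            theirs = oracle_tm(seq, 50, 200)
            assert abs(ours - theirs) <= 1.5, (seq, ours, theirs)


# ---- brute-force structure oracles ----

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def oracle_hairpins(s, min_loop):
    """Every maximal (left start, right-window start, stem) triple, by
    exhaustive enumeration with direct maximality checks."""
    n = len(s)
    found = set()
    for i in range(n):
        for q in range(i + 1, n):  # q = start of the right paired window
            for k in range(1, n):
                if i + k > q or q + k > n:
                    break
                if s[i : i + k] != revcomp(s[q : q + k]):
                    continue
                loop = q - i - k
                if loop < min_loop:
                    continue
                outer_ext = i > 0 and q + k < n and _COMP[s[i - 1]] == s[q + k]
                inner_ext = (
                    i + k < q - 1
                    and _COMP[s[i + k]] == s[q - 1]
                    and q - i - k - 2 >= min_loop
                )
                if not outer_ext and not inner_ext:
                    found.add((i, q, k))
    return found


def oracle_dimers(a, b):
    la, lb = len(a), len(b)
    found = set()
    for i in range(la):
        for j in range(lb):
            for k in range(1, min(la - i, lb - j) + 1):
                if a[i : i + k] != revcomp(b[j : j + k]):
                    continue
                left_ext = i > 0 and j + k < lb and a[i - 1] == _COMP[b[j + k]]
                right_ext = i + k < la and j > 0 and a[i + k] == _COMP[b[j - 1]]
                if not left_ext and not right_ext:
                    if a == b and i > j:
                        continue
                    found.add((i, j, k))
    return found


class TestHairpinScan:
    def test_panhandle_example(self):
        hits = hairpin_scan("GGGGAAAACCCC", min_loop=3)
        top = hits[0]
        assert top.stem == 4 and top.loop == 4

    def test_no_self_complementarity(self):
        assert hairpin_scan("AAAAAAAAAA") == []

    def test_short_random_has_no_long_stem(self, random_dna):
        s = random_dna(12, seed=7)
        assert all(h.stem < 4 for h in hairpin_scan(s))

    @given(st.text(alphabet="ACGT", min_size=8, max_size=30))
    def test_matches_bruteforce(self, s):
        got = {(h.positions[0], h.positions[1], h.stem) for h in hairpin_scan(s)}
        assert got == oracle_hairpins(s, 3)


class TestDimerScan:
    def test_perfect_duplex(self):
        a = "ACGTACGT"
        hits = dimer_scan(a, revcomp(a))
        assert hits[0].stem == 8 and hits[0].three_prime_anchored

    def test_bp_vs_gada_insp_clean(self):
        hits = dimer_scan(BP.seq, NSP_TRIPLES["gadA"][2].seq)
        assert not any(h.three_prime_anchored and h.stem > 4 for h in hits)

    def test_no_complementarity(self):
        assert dimer_scan("AAAA", "CCCC") == []

    def test_self_dimer_kind(self):
        hits = dimer_scan("ACGTACGT", "ACGTACGT")
        assert hits and all(h.kind == "self-dimer" for h in hits)

    @given(
        st.text(alphabet="ACGT", min_size=4, max_size=30),
        st.text(alphabet="ACGT", min_size=4, max_size=30),
    )
    def test_matches_bruteforce(self, a, b):
        got = {(h.positions[0], h.positions[1], h.stem) for h in dimer_scan(a, b)}
        assert got == oracle_dimers(a, b)


class TestTerminalInvertedRepeat:
    def test_constructed_panhandle(self, random_dna):
        x = random_dna(41, seed=9)
        assert terminal_inverted_repeat(x + "TTTTT" + revcomp(x)) >= 41

    def test_palindrome(self):
        assert terminal_inverted_repeat("ACGT") == 4

    def test_no_repeat(self):
        assert terminal_inverted_repeat("AAAAAA") == 0


class TestSevereHits:
    def test_hairpin_threshold(self):
        # 5-bp stem hairpin is severe at the default threshold
        stem = "GCGCG"
        seq = stem + "AAAA" + revcomp(stem)
        assert any(h.kind == "hairpin" for h in severe_hits(seq))

    def test_includes_self_dimer_branch(self):
        a = "ACGTACGTACGT"  # strongly self-complementary
        hits = severe_hits(a)
        assert any(h.kind == "self-dimer" for h in hits)
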