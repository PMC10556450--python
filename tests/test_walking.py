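"""Three-round walking simulation, suppression, virtual gel, verification."""

import pytest

from forkpcr.fixtures import make_fixture
from forkpcr.oligos import Oligo, revcomp
from forkpcr.thermo import terminal_inverted_repeat
from forkpcr.walking import (
    Amplicon,
    ProductPool,
    RoundOrderError,
    SimParams,
    simulate_primary,
    simulate_secondary,
    simulate_tertiary,
    verify_walk,
    virtual_gel,
)


class TestPrimaryRound:
    def test_recovers_exactly_one_target_of_truth_length(self, target_fixture, target_pools):
        fx, (p1, _, _) = target_fixture, target_pools
        targets = [a for a in p1.amplicons if a.category == "target"]
        truth = [e for e in fx.expected_round1 if e.category == "target"]
        assert len(targets) == len(truth) == 1
        assert targets[0].length == truth[0].length
        assert targets[0].left_primer == fx.nsp.onsp.name
        assert targets[0].right_primer == fx.fork.pfp.name

    def test_facing_pfp_half_sites_give_one_category_iii(self):
        fx = make_fixture(8000, 1500, ("III",), seed=5)
        p1 = simulate_primary(fx.genome_records(), fx.fork.pfp, fx.nsp.onsp)
        iii = [a for a in p1.amplicons if a.category == "III" and a.right_primer]
        assert len(iii) == 1
        assert iii[0].length == fx.expected_round1[0].length

    def test_no_pfp_site_warns_and_yields_no_target(self):
        fx = make_fixture(8000, 1500, ("target",), seed=3)
        genome = {"g": "AT" * 2000}  # no oNSP or PFP seed present
        pool = simulate_primary(genome, fx.fork.pfp, fx.nsp.onsp)
        assert not [a for a in pool.amplicons if a.category == "target"]
        assert any("warning" in n for n in pool.notes)

    def test_category_iii_has_panhandle_termini(self):
        fx = make_fixture(8000, 1500, ("III",), seed=5)
        p1 = simulate_primary(fx.genome_records(), fx.fork.pfp, fx.nsp.onsp)
        amp = next(a for a in p1.amplicons if a.category == "III" and a.right_primer)
        assert terminal_inverted_repeat(amp.seq) >= 41

    def test_exponential_products_have_exact_primer_ends(self, target_fixture, target_pools):
        fx, (p1, _, _) = target_fixture, target_pools
        for a in p1.exponential():
            assert a.seq.startswith(
                {fx.nsp.onsp.name: fx.nsp.onsp.seq, fx.fork.pfp.name: fx.fork.pfp.seq}[
                    a.left_primer
                ]
            )


class TestSecondaryRound:
    def test_single_target_amplified_with_mnsp_end(self, target_fixture, target_pools):
        fx, (_, p2, _) = target_fixture, target_pools
        exp = p2.exponential()
        assert len(exp) == 1
        amp = exp[0]
        assert amp.category == "target"
        assert amp.seq.startswith(fx.nsp.mnsp.seq)
        assert amp.seq.endswith(revcomp(fx.fork.bp.seq))
        assert amp.length == fx.expected_secondary_len

    def test_category_iii_suppressed(self):
        fx = make_fixture(8000, 1500, ("III",), seed=5)
        p1 = simulate_primary(fx.genome_records(), fx.fork.pfp, fx.nsp.onsp)
        p2 = simulate_secondary(p1, fx.fork.sfp, fx.fork.bp, fx.nsp.mnsp)
        assert p2.exponential() == []
        flagged = [a for a in p2.amplicons if a.suppressed]
        assert flagged and all(a.category == "III" for a in flagged)

    def test_category_i_is_diluted_carryover(self):
        fx = make_fixture(8000, 1500, ("I",), seed=7)
        p1 = simulate_primary(fx.genome_records(), fx.fork.pfp, fx.nsp.onsp)
        assert any(a.category == "I" and a.right_primer for a in p1.amplicons)
        p2 = simulate_secondary(p1, fx.fork.sfp, fx.fork.bp, fx.nsp.mnsp)
        assert p2.exponential() == []
        assert any(a.category == "carryover" for a in p2.amplicons)

    def test_wrong_round_pool_rejected(self, target_fixture, target_pools):
        fx, (_, p2, _) = target_fixture, target_pools
        with pytest.raises(RoundOrderError):
            simulate_secondary(p2, fx.fork.sfp, fx.fork.bp, fx.nsp.mnsp)


class TestTertiaryRound:
    def test_target_shrinks_by_nesting_offset(self, target_fixture, target_pools):
        fx, (_, p2, p3) = target_fixture, target_pools
        s = p2.exponential()[0]
        t = p3.exponential()[0]
        offset = fx.nsp.coords["iNSP"][0] - fx.nsp.coords["mNSP"][0]
        assert s.length - t.length == offset
        assert t.length == fx.expected_tertiary_len
        assert t.seq.startswith(fx.nsp.insp.seq)

    def test_empty_pool_stays_empty(self, target_fixture):
        fx = target_fixture
        empty = ProductPool(round=2)
        p3 = simulate_tertiary(empty, fx.fork.bp, fx.nsp.insp)
        assert p3.amplicons == []

    def test_carryover_only_pool_gives_no_exponential(self, target_fixture):
        fx = target_fixture
        pool = ProductPool(round=2)
        pool.add(
            Amplicon("ACGT" * 200, "x", None, "carryover", "linear", False, 2)
        )
        p3 = simulate_tertiary(pool, fx.fork.bp, fx.nsp.insp)
        assert p3.exponential() == []


class TestVirtualGel:
    def test_one_band_per_nested_lane(self, target_pools):
        p1, p2, p3 = target_pools
        gel = virtual_gel([p1, p2, p3])
        assert len(gel.lane(2)) == 1 and len(gel.lane(3)) == 1
        assert gel.lane(3)[0][0] < gel.lane(2)[0][0]

    def test_suppressed_products_leave_lane_empty(self):
        fx = make_fixture(8000, 1500, ("III",), seed=5)
        p1 = simulate_primary(fx.genome_records(), fx.fork.pfp, fx.nsp.onsp)
        p2 = simulate_secondary(p1, fx.fork.sfp, fx.fork.bp, fx.nsp.mnsp)
        assert virtual_gel([p2]).lane(2) == []

    def test_duplicate_lengths_merge_with_multiplicity(self):
        pool = ProductPool(round=2)
        pool.add(Amplicon("A" * 300, "a", "b", "target", "exponential", False, 2))
        pool.add(Amplicon("C" * 300, "c", "d", "target", "exponential", False, 2))
        assert virtual_gel([pool]).lane(2) == [(300, 2)]

    def test_requires_a_pool(self):
        with pytest.raises(ValueError):
            virtual_gel([])


class TestVerifyWalk:
    def test_tertiary_target_verifies(self, target_fixture, target_pools):
        fx, (_, _, p3) = target_fixture, target_pools
        assert verify_walk(p3.exponential()[0], fx.known_seq)

    def test_corrupted_junction_fails(self, target_fixture, target_pools):
        fx, (_, _, p3) = target_fixture, target_pools
        amp = p3.exponential()[0]
        bad = amp.seq[:30] + revcomp(amp.seq[30:60]) + amp.seq[60:]
        corrupted = Amplicon(bad, amp.left_primer, amp.right_primer, "target",
                             "exponential", False, 3)
        assert not verify_walk(corrupted, fx.known_seq)

    def test_too_short_fails_with_diagnostic(self, target_fixture):
        amp = Amplicon("ACGTACGT", "x", "y", "target", "exponential", False, 3)
        v = verify_walk(amp, target_fixture.known_seq)
        assert not v.ok and "anchor" in v.detail


class TestWalkProperties:
    SEEDS = range(20)

    def test_no_pfp_both_end_exponential_in_rounds_2_and_3(self):
        """Suppression invariant over seeded fixtures with all decoys."""
        for seed in self.SEEDS:
            fx = make_fixture(9000, 1200, ("target", "I", "II", "III"), seed=seed)
            p1 = simulate_primary(fx.genome_records(), fx.fork.pfp, fx.nsp.onsp)
            p2 = simulate_secondary(p1, fx.fork.sfp, fx.fork.bp, fx.nsp.mnsp)
            p3 = simulate_tertiary(p2, fx.fork.bp, fx.nsp.insp)
            pfp_like = {fx.fork.pfp.name}
            for pool in (p2, p3):
                for a in pool.exponential():
                    assert not (
                        a.left_primer in pfp_like and a.right_primer in pfp_like
                    ), f"seed {seed}: round {pool.round} has a PFP-only product"

    def test_nesting_monotonic_and_exact(self):
        for seed in (1, 4, 9):
            fx = make_fixture(8000, 800, ("target",), seed=seed)
            p1 = simulate_primary(fx.genome_records(), fx.fork.pfp, fx.nsp.onsp)
            p2 = simulate_secondary(p1, fx.fork.sfp, fx.fork.bp, fx.nsp.mnsp)
            p3 = simulate_tertiary(p2, fx.fork.bp, fx.nsp.insp)
            l1 = next(a.length for a in p1.exponential() if a.category == "target")
            l2 = p2.exponential()[0].length
            l3 = p3.exponential()[0].length
            assert l3 < l2 <= l1
            assert l2 == l1 - 40 and l3 == l2 - 40  # fixed NSP nesting offsets

    def test_loosening_low_stringency_keeps_the_target(self, target_fixture):
        from forkpcr.annealing import StringencyModel

        fx = target_fixture
        loose = SimParams(
            low_model=StringencyModel("low", min_three_prime_run=6, min_identity=0.5)
        )
        p1 = simulate_primary(fx.genome_records(), fx.fork.pfp, fx.nsp.onsp, loose)
        lengths = [a.length for a in p1.amplicons if a.category == "target"]
        truth = next(e.length for e in fx.expected_round1 if e.category == "target")
        assert truth in lengths
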