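import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribopool.codon_model import build_recognition_table
from ribopool.genetic_code import CODON_INDEX, SENSE_CODONS
from ribopool.resources import (
    AccountingError,
    RecyclingParams,
    ResourceState,
    allocate_trna,
    distance_scores,
    effective_demand,
    esdr,
    release_trna,
    rsdr,
)

from conftest import wc_rules


def make_state(table, G_tot=70_000, H_each=100):
    return ResourceState(
        G_tot, np.full(table.n_trna, H_each, dtype=np.int64), table
    )


class TestRSDR:
    def test_ratio(self, wc_table):
        st_ = make_state(wc_table)
        st_.init_demand = 7_000
        assert rsdr(st_) == 10.0

    def test_zero_demand_floored(self, wc_table):
        st_ = make_state(wc_table)
        assert rsdr(st_) == st_.G_free

    def test_zero_supply(self, wc_table):
        st_ = make_state(wc_table)
        st_.G_free = 0
        st_.init_demand = 5
        assert rsdr(st_) == 0.0


class TestEffectiveDemand:
    def test_single_codon(self, wc_table):
        st_ = make_state(wc_table)
        st_.codon_demand[CODON_INDEX["AAA"]] = 4
        assert effective_demand("t-AAA", st_, wc_table) == 4.0

    def test_alpha_weighted_sum(self):
        rules = wc_rules() + [("GGG", "t-GGA", "gu")]
        table = build_recognition_table(rules, {"gu": 0.5})
        st_ = make_state(table)
        st_.codon_demand[CODON_INDEX["GGA"]] = 4
        st_.codon_demand[CODON_INDEX["GGG"]] = 2
        assert effective_demand("t-GGA", st_, table) == 4.0 + 0.5 * 2

    def test_zero_demand(self, wc_table):
        st_ = make_state(wc_table)
        assert effective_demand("t-AAA", st_, wc_table) == 0.0

    def test_unknown_trna(self, wc_table):
        with pytest.raises(KeyError):
            effective_demand("nope", make_state(wc_table), wc_table)


class TestESDR:
    def test_zero_exponent_ignores_demand(self, wc_table):
        st_ = make_state(wc_table, H_each=100)
        st_.codon_demand[CODON_INDEX["AAA"]] = 50
        val = esdr("AAA", st_, wc_table, RecyclingParams.zero())
        assert val == 100.0

    def test_full_exponent_divides_by_demand(self, wc_table):
        st_ = make_state(wc_table, H_each=100)
        st_.codon_demand[CODON_INDEX["AAA"]] = 20
        rec = RecyclingParams(np.full(61, 1.0), w=1e9)  # exponent -> 1
        assert esdr("AAA", st_, wc_table, rec) == pytest.approx(5.0)

    def test_half_exponent_hand_value(self):
        # single decoder alpha=0.5, H=100, D=16, exponent 0.5 -> 12.5
        rules = [
            r if r[0] != "AGU" else ("AGU", "t-AGU", "gu")
            for r in wc_rules()
        ]
        table = build_recognition_table(rules, {"gu": 0.5})
        st_ = make_state(table, H_each=100)
        st_.codon_demand[CODON_INDEX["AGU"]] = 32  # D = 0.5*32 = 16
        d = np.zeros(61)
        d[CODON_INDEX["AGU"]] = np.log(2.0)  # 1 - exp(-1*ln2) = 0.5
        rec = RecyclingParams(d, w=1.0)
        assert esdr("AGU", st_, table, rec) == pytest.approx(0.5 * 100 / 4.0)

    def test_stop_codon_rejected(self, wc_table):
        with pytest.raises(ValueError):
            esdr("UAA", make_state(wc_table), wc_table, RecyclingParams.zero())

    def test_monotone_in_supply_and_demand(self, wc_table):
        st_ = make_state(wc_table, H_each=50)
        rec = RecyclingParams(np.full(61, 2.0), w=0.3)
        st_.codon_demand[CODON_INDEX["AAA"]] = 5
        base = esdr("AAA", st_, wc_table, rec)
        st_.H_free[wc_table.trna_index["t-AAA"]] += 10
        assert esdr("AAA", st_, wc_table, rec) > base
        st_.codon_demand[CODON_INDEX["AAA"]] = 50
        assert esdr("AAA", st_, wc_table, rec) < base + 10


class TestAllocateRelease:
    def test_single_decoder(self, wc_table):
        st_ = make_state(wc_table, H_each=10)
        rng = np.random.default_rng(0)
        j = allocate_trna("AAA", st_, wc_table, rng)
        assert j == "t-AAA"
        idx = wc_table.trna_index[j]
        assert st_.H_free[idx] == 9 and st_.bound_trna[idx] == 1

    def test_pick_frequency_proportional_to_alpha_h(self):
        rules = wc_rules() + [("GGG", "t-GGA", "gu")]
        table = build_recognition_table(rules, {"gu": 0.5})
        st_ = make_state(table, H_each=90)
        st_.H_free[table.trna_index["t-GGA"]] = 20  # 0.5*20 = 10 vs 90
        rng = np.random.default_rng(42)
        wins = 0
        for _ in range(10_000):
            pick = allocate_trna("GGG", st_, table, rng)
            if pick == "t-GGG":
                wins += 1
            release_trna(pick, st_)
        assert wins / 10_000 == pytest.approx(0.9, abs=0.01)

    def test_exhausted_returns_none(self, wc_table):
        st_ = make_state(wc_table, H_each=0)
        before = st_.H_free.copy()
        assert allocate_trna("AAA", st_, wc_table,
                             np.random.default_rng(0)) is None
        assert (st_.H_free == before).all()

    def test_release_never_allocated_errors(self, wc_table):
        with pytest.raises(AccountingError):
            release_trna("t-AAA", make_state(wc_table))

    @settings(max_examples=20, deadline=None)
    @given(codons=st.lists(st.integers(0, 60), min_size=1, max_size=50),
           seed=st.integers(0, 2**31 - 1))
    def test_conservation_under_random_traffic(self, codons, seed, wc_table):
        st_ = make_state(wc_table, H_each=5)
        rng = np.random.default_rng(seed)
        held = []
        for ci in codons:
            c = SENSE_CODONS[ci]
            if held and rng.random() < 0.4:
                release_trna(held.pop(), st_)
            else:
                j = allocate_trna(c, st_, wc_table, rng)
                if j is not None:
                    held.append(j)
            assert (st_.H_free + st_.bound_trna == st_.H_tot_per).all()

    def test_round_trip_restores_state(self, wc_table):
        st_ = make_state(wc_table, H_each=5)
        before = st_.H_free.copy()
        j = allocate_trna("UGG", st_, wc_table, np.random.default_rng(1))
        release_trna(j, st_)
        assert (st_.H_free == before).all()
        assert (st_.bound_trna == 0).all()


class TestDistanceScores:
    def test_homopolymer_distance_one(self, wc_table):
        orf = ["AAA"] * 10
        rec = distance_scores([(orf, 1.0)], wc_table)
        assert rec.d[CODON_INDEX["AAA"]] == 1.0

    def test_lone_codon_capped_at_orf_end(self, wc_table):
        orf = ["AAA", "GGG", "CCC", "UUU"]
        rec = distance_scores([(orf, 1.0)], wc_table)
        # GGG at position 2 of 4: no co-decoded codon downstream -> 4-2+1
        assert rec.d[CODON_INDEX["GGG"]] == 3.0

    def test_matches_brute_force_on_two_genes(self, wc_table):
        rng = np.random.default_rng(9)
        genes = [
            ([SENSE_CODONS[i] for i in rng.integers(0, 61, 30)], 2.0),
            ([SENSE_CODONS[i] for i in rng.integers(0, 61, 20)], 1.0),
        ]
        rec = distance_scores(genes, wc_table)

        # brute force: scan every occurrence for the nearest downstream
        # codon sharing a decoder (WC table: identical codon)
        dsum = np.zeros(61)
        wsum = np.zeros(61)
        for orf, copies in genes:
            L = len(orf)
            for p, c in enumerate(orf, start=1):
                dist = None
                for q in range(p + 1, L + 1):
                    if orf[q - 1] == c:
                        dist = q - p
                        break
                if dist is None:
                    dist = L - p + 1
                dsum[CODON_INDEX[c]] += copies * dist
                wsum[CODON_INDEX[c]] += copies
        seen = wsum > 0
        expect = np.zeros(61)
        expect[seen] = dsum[seen] / wsum[seen]
        assert rec.d[seen] == pytest.approx(expect[seen])

    def test_exponents_in_range_and_median(self, wc_table):
        rng = np.random.default_rng(4)
        orf = [SENSE_CODONS[i] for i in rng.integers(0, 61, 200)]
        rec = distance_scores([(orf, 1.0)], wc_table)
        ex = rec.exponents()
        assert ((ex >= 0) & (ex < 1)).all()
        seen = rec.d > 0
        assert np.median(ex[seen]) == pytest.approx(0.5, abs=0.05)

    def test_empty_transcriptome_errors(self, wc_table):
        with pytest.raises(ValueError):
            distance_scores([], wc_table)
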