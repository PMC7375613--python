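import numpy as np
import pytest

from ribopool.engine import (
    Cell,
    EngineConfig,
    MRNALattice,
    set_timer,
    step_elongation,
    step_initiation,
)
from ribopool.genetic_code import SENSE_CODONS
from ribopool.resources import RecyclingParams

from conftest import make_cell


class TestSetTimer:
    def test_hand_value(self):
        assert set_timer(10.0, 1.0, 0.05) == 2

    def test_monotone_in_sdr(self):
        t1 = set_timer(5.0, 1.0, 0.05)
        t2 = set_timer(10.0, 1.0, 0.05)
        assert t2 <= t1
        assert t2 == pytest.approx(t1 / 2, abs=1)

    def test_zero_sdr_finite(self):
        t = set_timer(0.0, 1.0, 0.05)
        assert 1 <= t < 2**32

    def test_cap(self):
        assert set_timer(0.0, 1.0, 0.05, max_wait_ticks=200) == 200


def uniform_wait_cfg(wc_table, k=2, H=10**6, dt=0.05):
    """Config in which every codon waits exactly k ticks (saturated pools,
    zero recycling exponent: ESDR == H_free of the single decoder)."""
    return EngineConfig(
        dt=dt, s=10, timer_scale_init=1.0,
        timer_scale_elong=k * dt * H, max_wait_ticks=10**6,
    )


class TestInitiation:
    def test_placement_after_local_time(self, wc_table):
        # neutral RSDR: one mRNA awaiting, G_free == timer_scale_init
        cfg = EngineConfig(dt=0.05, timer_scale_init=10.0)
        cell = make_cell([["AUG"] + ["AAA"] * 20], wc_table, G_tot=10,
                         cfg=cfg, init_times=[0.95])
        lat = cell.lattices[0]
        ticks = 0
        while not step_initiation(cell, lat):
            ticks += 1
            assert ticks < 100
        # 1 tick to enter the waiting state + round(0.95/0.05) countdown
        assert ticks == 19
        assert lat.g_i == 1 and cell.state.G_free == 9

    def test_no_free_ribosome_delays(self, wc_table):
        cfg = EngineConfig(dt=0.05, timer_scale_init=1.0, max_wait_ticks=5)
        cell = make_cell([["AUG"] + ["AAA"] * 20], wc_table, G_tot=1,
                         cfg=cfg)
        cell.state.G_free = 0
        lat = cell.lattices[0]
        for _ in range(50):
            assert not step_initiation(cell, lat)
        assert lat.g_i == 0
        cell.state.G_free = 1  # resource appears -> placed on next tick
        assert step_initiation(cell, lat)

    def test_occupied_entry_blocks_placement(self, wc_table):
        cfg = uniform_wait_cfg(wc_table, k=50)
        cell = make_cell([["AUG"] + ["AAA"] * 30], wc_table, G_tot=10,
                         cfg=cfg, init_times=[0.05])
        lat = cell.lattices[0]
        placed = 0
        for _ in range(40):
            placed += step_initiation(cell, lat)
        # first ribosome sits near codon 1 waiting ~50 ticks: entry blocked
        assert placed == 1
        assert lat.g_i == 1


class TestElongation:
    def test_single_particle_closed_form(self, wc_table):
        k, H = 3, 10**6
        cfg = uniform_wait_cfg(wc_table, k=k, H=H)
        rng = np.random.default_rng(0)
        for trial in range(5):
            L = int(rng.integers(5, 25))
            orf = [SENSE_CODONS[i] for i in rng.integers(0, 61, L)]
            cell = make_cell([orf], wc_table, G_tot=1, H_each=H, cfg=cfg,
                             init_times=[0.05], seed=trial)
            out = cell.run(20 + L * (k + 2))
            t_init = int(np.nonzero(out["inits"])[0][0])
            t_term = int(np.nonzero(out["terms"])[0][0])
            # closed form: L codon cycles of (k wait + 1 translocation)
            assert abs((t_term - t_init) - L * (k + 1)) <= 1

    def test_exclusion_boundary(self, wc_table):
        s = 4
        cfg = EngineConfig(dt=0.05, s=s, timer_scale_init=1.0,
                           timer_scale_elong=1e-6, max_wait_ticks=10**6)
        cell = make_cell([["AUG"] + ["AAA"] * 30], wc_table, G_tot=10,
                         H_each=10**6, cfg=cfg, init_times=[0.05])
        lat = cell.lattices[0]
        i = lat.index
        # hand-place two ribosomes at gap s: trailing one must not move
        cell.rib_pos[i, 0], cell.rib_pos[i, 1] = 9, 5
        cell.rib_state[i, :2] = 1  # ELONGATING
        cell.rib_timer[i, :2] = [10**6, 0]  # leader frozen
        cell.rib_n[i] = 2
        cell.state.G_free -= 2
        step_elongation(cell, lat)
        assert cell.rib_pos[i, 1] == 5  # gap s: blocked
        cell.rib_pos[i, 0] = 10  # gap s+1
        cell.rib_state[i, 1] = 1
        cell.rib_timer[i, 1] = 0
        step_elongation(cell, lat)
        assert cell.rib_pos[i, 1] == 6  # may advance

    def test_termination_frees_ribosome_same_tick(self, wc_table):
        cfg = uniform_wait_cfg(wc_table, k=1)
        cell = make_cell([["AUG", "AAA"]], wc_table, G_tot=5, H_each=10**6,
                         cfg=cfg, init_times=[0.05])
        lat = cell.lattices[0]
        for _ in range(100):
            g_before = cell.state.G_free
            n_before = lat.g_i
            if step_elongation(cell, lat):
                assert cell.state.G_free == g_before + 1
                assert lat.g_i == n_before - 1
                return
            step_initiation(cell, lat)
        pytest.fail("no termination observed")


class TestStepCell:
    def test_zero_lattices_noop(self, wc_table):
        cell = make_cell([], wc_table, G_tot=10)
        out = cell.run(5)
        assert (out["gfree"] == 10).all()
        assert (out["terms"] == 0).all()

    def test_visit_order_fair_between_two_mrnas(self, wc_table):
        # two identical mRNAs compete for a single free ribosome
        cfg = EngineConfig(dt=0.05, timer_scale_init=1.0)
        wins = [0, 0]
        for seed in range(200):
            cell = make_cell(
                [["AUG"] + ["AAA"] * 15] * 2, wc_table, G_tot=1,
                cfg=cfg, init_times=[0.05, 0.05], seed=seed,
            )
            cell.run(5)
            got = [cell.rib_n[0], cell.rib_n[1]]
            assert sum(got) == 1
            wins[int(np.argmax(got))] += 1
        assert abs(wins[0] - wins[1]) < 60  # ~50/50 over 200 seeds

    def test_conservation_sweep(self, toy_inputs):
        from ribopool.cell_sim import (
            CellConfig, instantiate_transcriptome, run_simulation,
            verify_conservation,
        )

        spec, orfs, levels, init_times, table, rec = toy_inputs
        cfg = CellConfig(n_mrna=spec.n_mrna, G_tot=1000, H_tot=10_000,
                         run_ticks=1_000, seed=3)
        rng = np.random.default_rng(3)
        lats = instantiate_transcriptome(levels, orfs, init_times, rng)
        res = run_simulation(cfg, lats, table, rec)
        verify_conservation(res)
        assert res.term_total.sum() > 0


class TestInvariants:
    def run_and_scan(self, seed, wc_table, n_mrna=6, ticks=300):
        cfg = EngineConfig(dt=0.05, s=5, timer_scale_init=1.0,
                           timer_scale_elong=100.0)
        rng = np.random.default_rng(seed)
        orfs = [
            [SENSE_CODONS[i] for i in rng.integers(0, 61, rng.integers(15, 40))]
            for _ in range(n_mrna)
        ]
        cell = make_cell(orfs, wc_table, G_tot=20, H_each=30, cfg=cfg,
                         init_times=[0.05] * n_mrna, seed=seed)
        for _ in range(ticks):
            cell.run(1)
            for i in range(n_mrna):
                n = int(cell.rib_n[i])
                pos = cell.rib_pos[i, :n]
                if n > 1:
                    gaps = pos[:-1] - pos[1:]
                    assert (gaps >= cfg.s).all(), (seed, i, pos)
        return cell

    def test_exclusion_and_order_over_seeds(self, wc_table):
        for seed in range(10):
            self.run_and_scan(seed, wc_table)

    def test_determinism_bit_identical(self, wc_table):
        outs = []
        for _ in range(2):
            cfg = EngineConfig(dt=0.05, timer_scale_elong=20.0)
            cell = make_cell(
                [["AUG"] + ["CCA"] * 25] * 4, wc_table, G_tot=6,
                H_each=40, cfg=cfg, init_times=[0.1] * 4, seed=99,
            )
            out = cell.run(400)
            outs.append(out)
        for key in ("gfree", "terms", "inits", "bound_trna"):
            assert (outs[0][key] == outs[1][key]).all()

    def test_starvation_monotonicity(self, wc_table):
        # an mRNA made solely of AAA codons cannot produce more protein
        # when the pool of its only decoder shrinks
        terms = []
        for h in (200, 5):
            cfg = EngineConfig(dt=0.05, timer_scale_init=1.0,
                               timer_scale_elong=10.0)
            cell = make_cell([["AUG"] + ["AAA"] * 20] * 3, wc_table,
                             G_tot=10, H_each=200, cfg=cfg,
                             init_times=[0.05] * 3, seed=5)
            idx = wc_table.trna_index["t-AAA"]
            cell.state.H_free[idx] = h
            cell.state.H_tot_per[idx] = h
            out = cell.run(1500)
            terms.append(int(out["terms"].sum()))
        assert terms[1] <= terms[0]
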