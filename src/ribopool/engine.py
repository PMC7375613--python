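"""Per-mRNA deterministic TASEP engine with codon state machines.

A :class:`Cell` packs a set of mRNA lattices, the shared resource pools
and the recognition table into flat arrays and drives them through the
compiled kernel one tick (``dt`` seconds) at a time.  Ribosomes have a
footprint of ``s`` codons: A-site positions on a lattice always differ by
at least ``s``, and a ribosome may advance only when the gap to its leader
is at least ``s + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .genetic_code import CODON_INDEX, to_rna
from .codon_model import RecognitionTable
from .resources import RecyclingParams, ResourceState


@dataclass
class EngineConfig:
    """Timestep, footprint and timer-scale parameters.

    ``timer_scale_init`` is the reference RSDR: when the live RSDR equals
    it, the realized initiation wait equals the mRNA's local initiation
    time.  ``timer_scale_elong`` maps ESDR to the expected per-codon wait
    in seconds (``wait = timer_scale_elong / ESDR``).
    """

    dt: float = 0.05
    s: int = 10
    timer_scale_init: float = 10.0
    timer_scale_elong: float = 50.0
    transloc_ticks: int = 1
    eps: float = 1e-9
    max_wait_ticks: int = 200

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.s < 1:
            raise ValueError("dt must be > 0 and s >= 1")
        if self.timer_scale_init <= 0 or self.timer_scale_elong <= 0:
            raise ValueError("timer scales must be positive")
        if self.transloc_ticks < 1:
            raise ValueError("transloc_ticks must be >= 1")
        if self.max_wait_ticks < 1:
            raise ValueError("max_wait_ticks must be >= 1")


def set_timer(
    sdr: float,
    scale: float,
    dt: float,
    eps: float = 1e-9,
    max_wait_ticks: int = _kernel._MAX_TICKS,
) -> int:
    """Tick count for an expected wait of ``scale / max(sdr, eps)`` seconds.

    Monotone nonincreasing in ``sdr``; floored at one tick and capped
    (waits must stay short relative to resource dynamics, so the engine
    caps them at ``max_wait_ticks`` and re-checks conditions on expiry).
    """
    if sdr < 0:
        raise ValueError("sdr must be nonnegative")
    seconds = scale / max(sdr, eps)
    ticks = int(np.floor(seconds / dt + 0.5))
    return max(1, min(ticks, max_wait_ticks))


@dataclass
class Ribosome:
    """Read-only view of one ribosome (A-site position, machine state)."""

    pos: int
    state: int
    timer: int
    a_site_trna: int  # species index, -1 if none
    e_site_trna: int


class MRNALattice:
    """One mRNA molecule: codon array plus live ribosome/machine state.

    Construct with the gene id, the ORF codons (start codon included,
    stop excluded) and the local initiation time in seconds; the live
    state becomes available once the lattice is packed into a
    :class:`Cell`.
    """

    def __init__(self, gene_id: str, codons: list[str], local_init_time: float):
        if local_init_time <= 0:
            raise ValueError("local_init_time must be positive")
        self.gene_id = gene_id
        self.codons = [to_rna(c) for c in codons]
        self.codon_ids = np.array(
            [CODON_INDEX[c] for c in self.codons], dtype=np.int64
        )
        if len(self.codons) == 0:
            raise ValueError("empty ORF")
        self.local_init_time = float(local_init_time)
        self.cell: "Cell | None" = None
        self.index: int = -1

    def __len__(self) -> int:
        return len(self.codons)

    # -- live views (valid after packing) --------------------------------
    def _check(self) -> None:
        if self.cell is None:
            raise RuntimeError("lattice is not attached to a Cell")

    @property
    def g_i(self) -> int:
        """Current number of ribosomes on this mRNA."""
        self._check()
        return int(self.cell.rib_n[self.index])

    @property
    def ribosomes(self) -> list[Ribosome]:
        """Ribosomes front (3'-most) to back."""
        self._check()
        c, i = self.cell, self.index
        return [
            Ribosome(
                int(c.rib_pos[i, k]), int(c.rib_state[i, k]),
                int(c.rib_timer[i, k]), int(c.rib_ta[i, k]),
                int(c.rib_te[i, k]),
            )
            for k in range(c.rib_n[i])
        ]

    @property
    def occupancy(self) -> np.ndarray:
        """Accumulated per-codon occupancy counts (A-site iterations)."""
        self._check()
        c, i = self.cell, self.index
        return c.occupancy[c.lat_off[i] : c.lat_off[i + 1]].copy()


class Cell:
    """Shared-resource container driving all lattices tick by tick."""

    def __init__(
        self,
        lattices: list[MRNALattice],
        state: ResourceState,
        table: RecognitionTable,
        rec: RecyclingParams,
        cfg: EngineConfig,
        seed: int = 0,
    ):
        self.lattices = lattices
        self.state = state
        self.table = table
        self.rec = rec
        self.cfg = cfg
        self.seed = int(seed)
        n = len(lattices)
        lens = np.array([len(l) for l in lattices], dtype=np.int64)
        self.lat_off = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(lens, out=self.lat_off[1:])
        self.lat_codons = (
            np.concatenate([l.codon_ids for l in lattices])
            if n else np.zeros(0, dtype=np.int64)
        )
        self.gene_ids = sorted({l.gene_id for l in lattices})
        gmap = {g: i for i, g in enumerate(self.gene_ids)}
        self.lat_gene = np.array(
            [gmap[l.gene_id] for l in lattices], dtype=np.int64
        )
        self.lat_init_sec = np.array(
            [l.local_init_time for l in lattices], dtype=np.float64
        )
        self.init_state = np.zeros(n, dtype=np.int8)
        self.init_timer = np.zeros(n, dtype=np.int64)
        max_rib = int(max((lens - 1) // cfg.s + 1, default=1)) if n else 1
        max_rib = max(max_rib, 1)
        self.rib_pos = np.zeros((n, max_rib), dtype=np.int64)
        self.rib_state = np.zeros((n, max_rib), dtype=np.int8)
        self.rib_timer = np.zeros((n, max_rib), dtype=np.int64)
        self.rib_ta = np.full((n, max_rib), -1, dtype=np.int64)
        self.rib_te = np.full((n, max_rib), -1, dtype=np.int64)
        self.rib_n = np.zeros(n, dtype=np.int64)
        self.occupancy = np.zeros(self.lat_codons.shape[0], dtype=np.int64)
        self.gene_term = np.zeros(len(self.gene_ids), dtype=np.int64)
        self.D = np.zeros(table.n_trna, dtype=np.float64)
        self.exp_c = rec.exponents()
        p = table.packed()
        self.c2t_off, self.c2t_j, self.c2t_a = (
            p["c2t_off"], p["c2t_j"], p["c2t_a"],
        )
        self.rng = np.array([seed], dtype=np.uint64)
        self.perm = np.arange(n, dtype=np.int64)
        self.tick_count = 0
        for lat, i in zip(lattices, range(n)):
            lat.cell = self
            lat.index = i

    # -- invariant checks -------------------------------------------------
    @property
    def bound_ribosomes(self) -> int:
        return int(self.rib_n.sum())

    def count_bound_trna(self) -> int:
        """Bound tRNAs counted from ribosome A/E slots (ledger-independent)."""
        total = 0
        for i in range(len(self.lattices)):
            for k in range(self.rib_n[i]):
                total += int(self.rib_ta[i, k] >= 0)
                total += int(self.rib_te[i, k] >= 0)
        return total

    def check_conservation(self) -> None:
        self.state.check_conservation(self.bound_ribosomes)

    # -- stepping ---------------------------------------------------------
    def _kernel_args(self):
        st = self.state
        return (
            self.lat_codons, self.lat_off, self.lat_gene, self.lat_init_sec,
            self.init_state, self.init_timer,
            self.rib_pos, self.rib_state, self.rib_timer,
            self.rib_ta, self.rib_te, self.rib_n,
            st._scal, st.H_free, st.bound_trna, st.codon_demand, self.D,
            self.c2t_off, self.c2t_j, self.c2t_a, self.exp_c,
            self.rng, self.perm,
            self.cfg.dt, self.cfg.s, self.cfg.timer_scale_init,
            self.cfg.timer_scale_elong, self.cfg.eps,
            self.cfg.transloc_ticks, self.cfg.max_wait_ticks,
        )

    def run(self, n_ticks: int, snap_every: int = 0, n_genes: int | None = None):
        """Advance ``n_ticks`` ticks; returns a dict of per-tick records.

        With ``snap_every > 0``, cumulative per-gene termination counts
        and per-species free-pool snapshots are recorded on that grid.
        """
        ng = len(self.gene_ids) if n_genes is None else n_genes
        n_snaps = (
            (self.tick_count + n_ticks) // snap_every if snap_every else 0
        )
        out = {
            "gfree": np.zeros(n_ticks, dtype=np.int64),
            "bound_rib": np.zeros(n_ticks, dtype=np.int64),
            "hfree_sum": np.zeros(n_ticks, dtype=np.int64),
            "bound_trna": np.zeros(n_ticks, dtype=np.int64),
            "inits": np.zeros(n_ticks, dtype=np.int64),
            "terms": np.zeros(n_ticks, dtype=np.int64),
            "esdr": np.zeros((n_ticks, 61), dtype=np.float64),
            "term_snap": np.zeros((n_snaps, ng), dtype=np.int64),
            "hfree_snap": np.zeros(
                (n_snaps, self.table.n_trna), dtype=np.int64
            ),
        }
        st = self.state
        _kernel.run_ticks(
            n_ticks, self.tick_count,
            self.lat_codons, self.lat_off, self.lat_gene, self.lat_init_sec,
            self.init_state, self.init_timer,
            self.rib_pos, self.rib_state, self.rib_timer,
            self.rib_ta, self.rib_te, self.rib_n,
            st._scal, st.H_free, st.bound_trna, st.codon_demand, self.D,
            self.c2t_off, self.c2t_j, self.c2t_a, self.exp_c,
            self.rng, self.perm,
            self.cfg.dt, self.cfg.s, self.cfg.timer_scale_init,
            self.cfg.timer_scale_elong, self.cfg.eps,
            self.cfg.transloc_ticks, self.cfg.max_wait_ticks,
            out["gfree"], out["bound_rib"], out["hfree_sum"],
            out["bound_trna"], out["inits"], out["terms"], out["esdr"],
            self.occupancy, self.gene_term,
            out["term_snap"], out["hfree_snap"],
            snap_every if snap_every else 0,
        )
        self.tick_count += n_ticks
        return out


# ---------------------------------------------------------------------------
# single-lattice wrappers (same compiled code paths as the full tick loop)
# ---------------------------------------------------------------------------


def step_initiation(cell: Cell, lat: MRNALattice) -> bool:
    """Run one tick of the initiation machine of ``lat``.

    Returns ``True`` when a ribosome was placed this tick."""
    st = cell.state
    placed = _kernel.step_init_lattice(
        lat.index,
        cell.lat_codons, cell.lat_off, cell.lat_init_sec,
        cell.init_state, cell.init_timer,
        cell.rib_pos, cell.rib_state, cell.rib_timer,
        cell.rib_ta, cell.rib_te, cell.rib_n,
        st._scal, st.H_free, st.bound_trna, st.codon_demand, cell.D,
        cell.c2t_off, cell.c2t_j, cell.c2t_a, cell.exp_c,
        cell.cfg.dt, cell.cfg.s, cell.cfg.timer_scale_init,
        cell.cfg.timer_scale_elong, cell.cfg.eps,
        cell.cfg.max_wait_ticks,
    )
    return bool(placed)


def step_elongation(cell: Cell, lat: MRNALattice) -> int:
    """Run one tick of every ribosome machine on ``lat``.

    Returns the number of termination events; the shared pools are
    updated in place."""
    st = cell.state
    terms = _kernel.step_elong_lattice(
        lat.index,
        cell.lat_codons, cell.lat_off,
        cell.rib_pos, cell.rib_state, cell.rib_timer,
        cell.rib_ta, cell.rib_te, cell.rib_n,
        st._scal, st.H_free, st.bound_trna, st.codon_demand, cell.D,
        cell.c2t_off, cell.c2t_j, cell.c2t_a, cell.exp_c,
        cell.rng,
        cell.cfg.dt, cell.cfg.s, cell.cfg.timer_scale_elong,
        cell.cfg.eps, cell.cfg.transloc_ticks, cell.cfg.max_wait_ticks,
    )
    if terms:
        cell.gene_term[cell.lat_gene[lat.index]] += terms
    return int(terms)


def step_cell(cell: Cell, n_ticks: int = 1):
    """Advance the whole cell by ``n_ticks`` (random mRNA order per tick)."""
    return cell.run(n_ticks)
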