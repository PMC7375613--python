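"""Whole-cell simulation orchestration and calibration.

Builds a transcriptome of mRNA lattices from per-gene copy levels
(fractional copies resolved by a seeded Bernoulli draw), runs the engine,
detects steady state on the free-ribosome trajectory and assembles the
outputs (termination counts/rates, occupancy, pool trajectories,
active-ribosome fraction, per-codon mean ESDR).  Also hosts the two
calibration procedures: global pool-size bisection to a target ribosomal
activity and multiplicative normalization of local initiation times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .codon_model import RecognitionTable
from .engine import Cell, EngineConfig, MRNALattice
from .resources import RecyclingParams, ResourceState


@dataclass
class CellConfig:
    """Run parameters for one whole-cell simulation."""

    n_mrna: float = 500.0          # target total mRNA molecule count N
    G_tot: int = 7_000
    H_tot: int = 65_000
    trna_fractions: np.ndarray | None = None  # per-species split of H_tot
    dt: float = 0.05
    s: int = 10
    mean_init_time: float = 0.95
    timer_scale_init: float = 10.0
    timer_scale_elong: float = 50.0
    max_wait_ticks: int = 200
    run_ticks: int = 3_000
    steady_window: int = 500
    steady_tol: float = 0.01
    snap_every: int = 100
    seed: int = 0

    def engine_config(self) -> EngineConfig:
        return EngineConfig(
            dt=self.dt, s=self.s,
            timer_scale_init=self.timer_scale_init,
            timer_scale_elong=self.timer_scale_elong,
            max_wait_ticks=self.max_wait_ticks,
        )


#: the full-cell parameter preset (E. coli scale)
FULL_CELL = CellConfig(
    n_mrna=5_100.0, G_tot=70_000, H_tot=650_407,
    run_ticks=10_000, steady_window=1_000,
)


@dataclass
class SimulationResult:
    gene_ids: list[str]
    copies: np.ndarray                 # molecules per gene
    term_total: np.ndarray             # per-gene termination counts
    term_steady: np.ndarray            # terminations after steady state
    rate: np.ndarray                   # per-gene terminations / second
    occupancy: dict[str, np.ndarray]   # per-gene per-codon counts (all copies)
    gfree_traj: np.ndarray
    bound_rib_traj: np.ndarray
    hfree_sum_traj: np.ndarray
    bound_trna_traj: np.ndarray
    hfree_snap: np.ndarray             # (n_snaps, n_trna)
    snap_every: int
    steady_tick: int | None            # None => never stabilized
    active_fraction: float
    esdr_mean: np.ndarray              # (61,) post-steady time average
    n_ticks: int
    seed: int
    G_tot: int
    H_tot: int

    @property
    def is_steady(self) -> bool:
        return self.steady_tick is not None

    def per_gene_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "copies": self.copies,
                "terminations_total": self.term_total,
                "terminations_steady": self.term_steady,
                "rate_per_s": self.rate,
            }
        )

    def pool_frame(self) -> pd.DataFrame:
        t = np.arange(1, self.n_ticks + 1)
        return pd.DataFrame(
            {
                "tick": t,
                "G_free": self.gfree_traj,
                "bound_ribosomes": self.bound_rib_traj,
                "H_free_total": self.hfree_sum_traj,
                "bound_trna_total": self.bound_trna_traj,
            }
        )


def instantiate_transcriptome(
    levels: dict[str, float],
    orfs: dict[str, list[str]],
    init_times: dict[str, float],
    rng: np.random.Generator,
) -> list[MRNALattice]:
    """Expand per-gene mRNA levels into individual molecules.

    Each gene contributes ``floor(level)`` full copies plus one extra copy
    with probability ``frac(level)`` (one seeded draw per gene, fixed for
    the whole run), which accounts for average levels below one.
    """
    lattices: list[MRNALattice] = []
    for gene in sorted(levels):
        lv = float(levels[gene])
        if lv < 0:
            raise ValueError(f"negative mRNA level for {gene}")
        n = int(np.floor(lv))
        if rng.random() < lv - n:
            n += 1
        for _ in range(n):
            lattices.append(
                MRNALattice(gene, orfs[gene], init_times[gene])
            )
    return lattices


def detect_steady_state(
    pool_trajectory: np.ndarray, window: int, tol: float
) -> int | None:
    """First 1-based tick from which the free-ribosome trajectory stays
    stable to the end of the run.

    A window of ``window`` ticks is stable when its range is at most
    ``tol`` of its mean (absolute floor 1).  The returned tick is the
    earliest ``t`` such that every trailing window ending at ``t`` or
    later is stable -- transient plateaus (e.g. full pool depletion at
    startup) do not qualify.  ``None`` if the last window is unstable."""
    traj = np.asarray(pool_trajectory, dtype=float)
    n = traj.shape[0]
    if n < window:
        return None
    stable = np.zeros(n + 1, dtype=bool)
    for t in range(window, n + 1):
        seg = traj[t - window : t]
        mean = abs(seg.mean())
        rng_ = seg.max() - seg.min()
        stable[t] = rng_ <= tol * max(mean, 1.0)
    if not stable[n]:
        return None
    t = n
    while t - 1 >= window and stable[t - 1]:
        t -= 1
    return t


def build_cell(
    cfg: CellConfig,
    lattices: list[MRNALattice],
    table: RecognitionTable,
    rec: RecyclingParams,
) -> Cell:
    fr = cfg.trna_fractions
    if fr is None:
        fr = np.full(table.n_trna, 1.0 / table.n_trna)
    fr = np.asarray(fr, dtype=float)
    from .synthdata import largest_remainder  # cycle-free: pure helper

    h_per = largest_remainder(fr, cfg.H_tot)
    state = ResourceState(cfg.G_tot, h_per, table)
    return Cell(lattices, state, table, rec, cfg.engine_config(), cfg.seed)


def run_simulation(
    cfg: CellConfig,
    lattices: list[MRNALattice],
    table: RecognitionTable,
    rec: RecyclingParams,
) -> SimulationResult:
    """Execute a full run and assemble a :class:`SimulationResult`.

    Post-steady termination counts are resolved on the snapshot grid
    (``cfg.snap_every`` ticks): the steady tick is rounded up to the next
    snapshot.
    """
    cell = build_cell(cfg, lattices, table, rec)
    out = cell.run(cfg.run_ticks, snap_every=cfg.snap_every)
    cell.check_conservation()
    return _assemble(cfg, cell, out)


def verify_conservation(result: SimulationResult) -> None:
    """Assert exact pool conservation at every recorded tick.

    Bound counts in the trajectories are tallied from the lattices
    themselves each tick, so this is an end-to-end check of the event
    accounting, not a restatement of the ledger.
    """
    rib = result.gfree_traj + result.bound_rib_traj
    if not np.all(rib == result.G_tot):
        bad = int(np.argmax(rib != result.G_tot))
        raise RuntimeError(
            f"ribosome conservation violated at tick {bad + 1}: "
            f"{rib[bad]} != {result.G_tot}"
        )
    trna = result.hfree_sum_traj + result.bound_trna_traj
    if not np.all(trna == result.H_tot):
        bad = int(np.argmax(trna != result.H_tot))
        raise RuntimeError(
            f"tRNA conservation violated at tick {bad + 1}: "
            f"{trna[bad]} != {result.H_tot}"
        )


def _assemble(cfg: CellConfig, cell: Cell, out: dict) -> SimulationResult:
    n_ticks = out["gfree"].shape[0]
    steady = detect_steady_state(
        out["gfree"], cfg.steady_window, cfg.steady_tol
    )
    genes = cell.gene_ids
    term_total = cell.gene_term.copy()
    if steady is not None and cfg.snap_every > 0:
        row = -(-steady // cfg.snap_every) - 1  # ceil to snapshot grid
        if row < out["term_snap"].shape[0]:
            base = out["term_snap"][row]
            count_from = (row + 1) * cfg.snap_every
        else:
            base, count_from = term_total, n_ticks
        term_steady = term_total - base
        duration_s = (n_ticks - count_from) * cfg.dt
    else:
        term_steady = np.zeros_like(term_total)
        duration_s = 0.0
    rate = (
        term_steady / duration_s if duration_s > 0
        else np.zeros_like(term_steady, dtype=float)
    )
    if steady is not None:
        post = slice(steady - 1, n_ticks)
    else:
        # never stabilized: average over the trailing half so the
        # warm-up transient does not contaminate %AR
        post = slice(n_ticks // 2, n_ticks)
    active = 1.0 - out["gfree"][post].mean() / cell.state.G_tot
    occ: dict[str, np.ndarray] = {}
    for lat in cell.lattices:
        arr = occ.setdefault(lat.gene_id, np.zeros(len(lat), dtype=np.int64))
        arr += lat.occupancy
    copies = np.array(
        [sum(1 for l in cell.lattices if l.gene_id == g) for g in genes]
    )
    return SimulationResult(
        gene_ids=genes,
        copies=copies,
        term_total=term_total,
        term_steady=term_steady,
        rate=rate,
        occupancy=occ,
        gfree_traj=out["gfree"],
        bound_rib_traj=out["bound_rib"],
        hfree_sum_traj=out["hfree_sum"],
        bound_trna_traj=out["bound_trna"],
        hfree_snap=out["hfree_snap"],
        snap_every=cfg.snap_every,
        steady_tick=steady,
        active_fraction=float(active),
        esdr_mean=out["esdr"][post].mean(axis=0),
        n_ticks=n_ticks,
        seed=cfg.seed,
        G_tot=cell.state.G_tot,
        H_tot=cell.state.H_tot,
    )


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


class CalibrationError(RuntimeError):
    pass


def _scaled_config(cfg: CellConfig, scale: float) -> CellConfig:
    return replace(
        cfg,
        G_tot=max(1, int(round(cfg.G_tot * scale))),
        H_tot=max(1, int(round(cfg.H_tot * scale))),
    )


def calibrate_pools(
    cfg: CellConfig,
    levels: dict[str, float],
    orfs: dict[str, list[str]],
    init_times: dict[str, float],
    table: RecognitionTable,
    rec: RecyclingParams,
    target_activity: float = 0.8,
    tol: float = 0.02,
    max_iter: int = 12,
    bracket: tuple[float, float] = (0.02, 4.0),
    eval_ticks: int | None = None,
) -> tuple[CellConfig, float, int]:
    """Bisect a global pool scale until the active-ribosome fraction hits
    ``target_activity``.

    The ribosome:tRNA ratio is held fixed (both pools share the scale).
    Activity is monotone nonincreasing in the scale, so a sign-bracketing
    bisection applies.  Returns ``(calibrated config, achieved activity,
    iterations used)``.
    """
    if not (0.0 < target_activity < 1.0):
        raise ValueError("target activity must be in (0, 1)")

    ticks = eval_ticks if eval_ticks is not None else cfg.run_ticks

    def activity(scale: float) -> float:
        c = replace(
            _scaled_config(cfg, scale),
            run_ticks=ticks,
            steady_window=min(cfg.steady_window, max(ticks // 4, 10)),
        )
        rng = np.random.default_rng(c.seed)
        lats = instantiate_transcriptome(levels, orfs, init_times, rng)
        return run_simulation(c, lats, table, rec).active_fraction

    lo, hi = bracket
    a_lo, a_hi = activity(lo), activity(hi)
    if not (a_hi - tol <= target_activity <= a_lo + tol):
        raise CalibrationError(
            f"target {target_activity} outside achievable bracket: "
            f"activity({lo})={a_lo:.3f}, activity({hi})={a_hi:.3f}"
        )
    best_scale, best_a = (lo, a_lo) if abs(a_lo - target_activity) < abs(
        a_hi - target_activity
    ) else (hi, a_hi)
    it = 0
    while it < max_iter and abs(best_a - target_activity) > tol:
        it += 1
        mid = 0.5 * (lo + hi)
        a_mid = activity(mid)
        if abs(a_mid - target_activity) < abs(best_a - target_activity):
            best_scale, best_a = mid, a_mid
        if a_mid > target_activity:  # too active -> grow pools
            lo = mid
        else:
            hi = mid
    return _scaled_config(cfg, best_scale), best_a, it


def calibrate_initiation(
    local_times: dict[str, float],
    mean_target: float = 0.95,
) -> dict[str, float]:
    """Multiplicatively normalize local initiation times so the
    transcriptome mean equals ``mean_target`` (order preserved)."""
    vals = np.array(list(local_times.values()), dtype=float)
    if (vals <= 0).any():
        raise ValueError("local initiation times must be positive")
    scale = mean_target / vals.mean()
    return {g: float(t * scale) for g, t in local_times.items()}


def ribosome_density(result: SimulationResult) -> float:
    """Mean ribosomes per codon over the post-steady run (pilot metric for
    initiation-time normalization)."""
    total_codons = sum(arr.shape[0] for arr in result.occupancy.values())
    if total_codons == 0 or result.n_ticks == 0:
        return 0.0
    return float(result.bound_rib_traj.mean() / max(total_codons, 1))
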