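"""Conserved ribosome/tRNA pools and the supply-demand statistics.

Counts are held in plain numpy arrays so the same storage can be shared
with the simulation kernel; the invariants are exact integer conservation:
``G_free + bound ribosomes == G_tot`` and, per species,
``H_free[j] + bound_tRNA[j] == H_tot_per[j]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genetic_code import CODON_INDEX, N_SENSE, SENSE_CODONS, is_sense, to_rna
from .codon_model import RecognitionTable


class AccountingError(RuntimeError):
    """Pool ledger inconsistency -- signals an engine bug."""


class ResourceState:
    """Free/bound ribosome and tRNA counts plus live demand counters.

    Parameters
    ----------
    G_tot
        Total ribosome pool size.
    H_tot_per
        Per-species total tRNA counts, ordered like ``table.trna_ids``.
    table
        Recognition table fixing the tRNA species ordering.
    """

    def __init__(
        self, G_tot: int, H_tot_per: np.ndarray, table: RecognitionTable
    ):
        if G_tot <= 0:
            raise ValueError("G_tot must be positive")
        H_tot_per = np.asarray(H_tot_per, dtype=np.int64)
        if len(H_tot_per) != table.n_trna or (H_tot_per < 0).any():
            raise ValueError("H_tot_per must be nonnegative, one per species")
        self.table = table
        self.G_tot = int(G_tot)
        self.H_tot_per = H_tot_per.copy()
        self.H_free = H_tot_per.copy()
        self.bound_trna = np.zeros_like(H_tot_per)
        self.codon_demand = np.zeros(N_SENSE, dtype=np.int64)
        # scalar counters packed so the kernel can mutate them in place:
        # [0] = G_free, [1] = init_demand
        self._scal = np.array([G_tot, 0], dtype=np.int64)

    # -- scalar counters --------------------------------------------------
    @property
    def G_free(self) -> int:
        return int(self._scal[0])

    @G_free.setter
    def G_free(self, v: int) -> None:
        self._scal[0] = v

    @property
    def init_demand(self) -> int:
        return int(self._scal[1])

    @init_demand.setter
    def init_demand(self, v: int) -> None:
        self._scal[1] = v

    @property
    def H_tot(self) -> int:
        return int(self.H_tot_per.sum())

    def codon_demand_of(self, codon: str) -> int:
        return int(self.codon_demand[CODON_INDEX[to_rna(codon)]])

    def check_conservation(self, bound_ribosomes: int) -> None:
        """Assert exact pool conservation; raises :class:`AccountingError`."""
        if self.G_free + bound_ribosomes != self.G_tot:
            raise AccountingError(
                f"ribosome leak: {self.G_free} free + {bound_ribosomes} "
                f"bound != {self.G_tot}"
            )
        bad = np.nonzero(self.H_free + self.bound_trna != self.H_tot_per)[0]
        if bad.size:
            j = int(bad[0])
            raise AccountingError(
                f"tRNA leak for species {self.table.trna_ids[j]}: "
                f"{self.H_free[j]} + {self.bound_trna[j]} != "
                f"{self.H_tot_per[j]}"
            )


@dataclass
class RecyclingParams:
    """Per-codon recycling distance scores and the exponent normalizer.

    The ESDR demand exponent for codon ``c`` is ``1 - exp(-w * d[c])``,
    always in ``[0, 1)``.
    """

    d: np.ndarray  # length 61, canonical codon order
    w: float

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=np.float64)
        if self.d.shape != (N_SENSE,) or (self.d < 0).any():
            raise ValueError("d must be 61 nonnegative distance scores")
        if self.w < 0:
            raise ValueError("w must be nonnegative")

    def exponents(self) -> np.ndarray:
        return 1.0 - np.exp(-self.w * self.d)

    @classmethod
    def zero(cls) -> "RecyclingParams":
        """No-recycling limit: exponent 0 for every codon."""
        return cls(np.zeros(N_SENSE), 0.0)


# ---------------------------------------------------------------------------
# supply-demand statistics
# ---------------------------------------------------------------------------


def rsdr(state: ResourceState) -> float:
    """Ribosomal supply-demand ratio: free ribosomes over mRNAs awaiting an
    initiation complex (demand floored at 1)."""
    return state.G_free / max(state.init_demand, 1)


def effective_demand(
    j: str, state: ResourceState, table: RecognitionTable
) -> float:
    """Alpha-weighted count of codons currently awaiting a tRNA decoded by
    species ``j``."""
    if j not in table.trna_index:
        raise KeyError(f"unknown tRNA id {j}")
    total = 0.0
    for c in SENSE_CODONS:
        for t, a in table.decoders(c):
            if t == j:
                total += a * state.codon_demand[CODON_INDEX[c]]
    return total


def esdr(
    c: str,
    state: ResourceState,
    table: RecognitionTable,
    rec: RecyclingParams,
) -> float:
    """Effective supply-demand ratio of codon ``c``.

    ``ESDR(c) = sum_{j in rt(c)} alpha(c,j) * H_free(j)
    / max(D_j, 1) ** (1 - exp(-w * d_c))``; the demand floor keeps the
    value finite at zero demand (and is exact when the exponent is 0).
    """
    c = to_rna(c)
    if not is_sense(c):
        raise ValueError(f"stop or invalid codon {c}")
    ex = float(rec.exponents()[CODON_INDEX[c]])
    total = 0.0
    for t, a in table.decoders(c):
        j = table.trna_index[t]
        d_j = max(effective_demand(t, state, table), 1.0)
        total += a * state.H_free[j] / d_j**ex
    return total


# ---------------------------------------------------------------------------
# tRNA allocation / release (reference implementations; the simulation
# kernel applies the same rules in compiled code)
# ---------------------------------------------------------------------------


def allocate_trna(
    c: str,
    state: ResourceState,
    table: RecognitionTable,
    rng: np.random.Generator,
) -> str | None:
    """Draw a decoder of ``c`` with probability proportional to
    ``alpha * H_free``; mutates the pools.  Returns ``None`` (no mutation)
    if every decoder is exhausted."""
    c = to_rna(c)
    if not is_sense(c):
        raise ValueError(f"stop or invalid codon {c}")
    cands = [
        (t, a) for t, a in table.decoders(c)
        if state.H_free[table.trna_index[t]] > 0
    ]
    if not cands:
        return None
    weights = np.array(
        [a * state.H_free[table.trna_index[t]] for t, a in cands]
    )
    pick = rng.choice(len(cands), p=weights / weights.sum())
    t = cands[int(pick)][0]
    j = table.trna_index[t]
    state.H_free[j] -= 1
    state.bound_trna[j] += 1
    return t


def release_trna(j: str, state: ResourceState) -> None:
    """Return one bound tRNA of species ``j`` to the free pool."""
    idx = state.table.trna_index[j]
    if state.bound_trna[idx] <= 0:
        raise AccountingError(f"release of never-allocated tRNA {j}")
    state.bound_trna[idx] -= 1
    state.H_free[idx] += 1


# ---------------------------------------------------------------------------
# recycling distance scores
# ---------------------------------------------------------------------------


def distance_scores(
    transcriptome: list[tuple[list[str], float]],
    table: RecognitionTable,
    target_median_exponent: float = 0.5,
) -> RecyclingParams:
    """Copy-weighted mean downstream distance to the nearest co-decoded
    codon, per codon type.

    For each occurrence of codon ``c`` at 1-based position ``p`` in an ORF
    of length ``L``, the distance is the smallest ``q - p`` over downstream
    positions ``q`` holding a codon that shares at least one decoding tRNA
    with ``c``, capped at ``L - p + 1`` (the distance to the ORF end) when
    no such codon exists.  ``w`` is set so the median exponent
    ``1 - exp(-w * d)`` over observed codons equals
    ``target_median_exponent``.
    """
    if not transcriptome:
        raise ValueError("empty transcriptome")
    dsum = np.zeros(N_SENSE)
    wsum = np.zeros(N_SENSE)
    n_trna = table.n_trna
    packed = table.packed()
    c2t_off, c2t_j = packed["c2t_off"], packed["c2t_j"]
    for orf, copies in transcriptome:
        if copies < 0:
            raise ValueError("negative copy count")
        ids = [CODON_INDEX[to_rna(c)] for c in orf]
        L = len(ids)
        # nearest downstream position (1-based) of a codon decoded by j
        last = np.full(n_trna, -1, dtype=np.int64)
        dists = np.empty(L)
        for p in range(L, 0, -1):
            cid = ids[p - 1]
            dec = c2t_j[c2t_off[cid] : c2t_off[cid + 1]]
            best = math.inf
            for j in dec:
                if last[j] > 0:
                    best = min(best, last[j] - p)
            dists[p - 1] = best if best < math.inf else L - p + 1
            for j in dec:
                last[j] = p
        for p in range(L):
            dsum[ids[p]] += copies * dists[p]
            wsum[ids[p]] += copies
    d = np.zeros(N_SENSE)
    seen = wsum > 0
    d[seen] = dsum[seen] / wsum[seen]
    med = float(np.median(d[seen])) if seen.any() else 0.0
    if med > 0 and 0 < target_median_exponent < 1:
        w = -math.log(1.0 - target_median_exponent) / med
    else:
        w = 0.0
    return RecyclingParams(d, w)
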