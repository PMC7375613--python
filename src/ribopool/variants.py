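"""Heterologous-gene insertion, synonymous variant generation and genome
randomization."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genetic_code import (
    CODON_TO_AA,
    SENSE_CODONS,
    SYNONYMS,
    to_rna,
    translate,
)
from .codon_model import CodonScores


@dataclass
class HeterologousConfig:
    """Payload insertion parameters.

    ``copy_fraction`` is the share of the *total* mRNA pool the payload
    should occupy after insertion; ``tau_h`` and ``c_h`` parameterize the
    folding-energy-dependent initiation time; ``FE`` (kcal/mol, typically
    negative) is supplied externally.
    """

    payload_orf: list[str]
    copy_fraction: float = 0.20
    tau_h: float = 0.95
    c_h: float = 10.0
    FE: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.copy_fraction < 1.0):
            raise ValueError("copy_fraction must be in (0, 1)")
        if self.tau_h <= 0 or self.c_h <= 0:
            raise ValueError("tau_h and c_h must be positive")


def heterologous_init_time(FE: float, tau_h: float, c_h: float) -> float:
    """Initiation time ``tau_h * exp(-FE / c_h)`` seconds.

    More negative folding energy (tighter 5' structure) gives slower
    initiation.
    """
    if c_h <= 0:
        raise ValueError("c_h must be positive")
    return tau_h * math.exp(-FE / c_h)


def insert_heterologous(
    levels: dict[str, float],
    cfg: HeterologousConfig,
    payload_id: str = "payload",
) -> dict[str, float]:
    """Add payload copies so the payload is ``copy_fraction`` of the new
    total molecule count; native levels are untouched."""
    if payload_id in levels:
        raise ValueError(f"gene id {payload_id!r} already present")
    f = cfg.copy_fraction
    native_total = float(sum(levels.values()))
    payload = round(f / (1.0 - f) * native_total)
    out = dict(levels)
    out[payload_id] = float(payload)
    return out


def variants_method1(orf: list[str], scores: CodonScores) -> list[str]:
    """One representative codon per amino acid: each codon is replaced by
    its highest-scoring synonym (ties broken lexicographically)."""
    best: dict[str, str] = {}
    for aa, family in SYNONYMS.items():
        best[aa] = max(family, key=lambda c: (scores[c], _neg(c)))
    return [best[CODON_TO_AA[to_rna(c)]] for c in orf]


def _neg(codon: str):
    # invert lexicographic order so max() prefers the smallest codon on ties
    return tuple(-ord(ch) for ch in codon)


def variants_method2(orf: list[str]) -> list[tuple[str, list[str], bool]]:
    """All 61 single-representative-codon variants.

    For each sense codon ``x``, every synonym of ``x``'s amino acid is
    replaced by ``x``; other amino acids are untouched.  Returns
    ``(codon, variant, degenerate)`` triples -- one per sense codon, where
    ``degenerate`` marks variants identical to the input (family absent or
    already uniform).
    """
    rna = [to_rna(c) for c in orf]
    out = []
    for x in SENSE_CODONS:
        aa = CODON_TO_AA[x]
        var = [x if CODON_TO_AA[c] == aa else c for c in rna]
        out.append((x, var, var == rna))
    return out


RANDOMIZATION_MODES = (
    "orf_shuffle", "genome_swap", "orf_resample", "genome_resample",
)


def randomize_genome(
    orfs: dict[str, list[str]],
    mode: str,
    rng: np.random.Generator,
) -> dict[str, list[str]]:
    """Synonymous randomization of a genome; amino-acid sequences are
    always preserved.

    orf_shuffle
        permute synonymous codons within each ORF (per-ORF codon multiset,
        hence per-ORF usage bias, preserved exactly)
    genome_swap
        permute synonymous codons across the whole genome (genome-level
        multiset preserved exactly, per-ORF bias not)
    orf_resample
        redraw each codon from its ORF's synonymous frequencies
    genome_resample
        redraw each codon from the genome-wide synonymous frequencies
    """
    if mode not in RANDOMIZATION_MODES:
        raise ValueError(
            f"unknown mode {mode!r}; expected one of {RANDOMIZATION_MODES}"
        )
    clean = {g: [to_rna(c) for c in o] for g, o in orfs.items()}
    out: dict[str, list[str]] = {g: list(o) for g, o in clean.items()}

    if mode == "orf_shuffle":
        for g, codons in out.items():
            _shuffle_within(codons, rng)
        return out

    if mode == "genome_swap":
        # flatten, shuffle within amino acid across the genome, scatter back
        slots: dict[str, list[tuple[str, int]]] = {}
        pool: dict[str, list[str]] = {}
        for g in sorted(clean):
            for i, c in enumerate(clean[g]):
                aa = CODON_TO_AA[c]
                slots.setdefault(aa, []).append((g, i))
                pool.setdefault(aa, []).append(c)
        for aa, codons in pool.items():
            perm = rng.permutation(len(codons))
            for (g, i), k in zip(slots[aa], perm):
                out[g][i] = codons[int(k)]
        return out

    # resampling modes
    if mode == "orf_resample":
        for g, codons in out.items():
            freqs = _family_freqs([codons])
            out[g] = [_draw(CODON_TO_AA[c], freqs, rng) for c in codons]
        return out

    freqs = _family_freqs(list(clean.values()))
    for g, codons in out.items():
        out[g] = [_draw(CODON_TO_AA[c], freqs, rng) for c in codons]
    return out


def _shuffle_within(codons: list[str], rng: np.random.Generator) -> None:
    groups: dict[str, list[int]] = {}
    for i, c in enumerate(codons):
        groups.setdefault(CODON_TO_AA[c], []).append(i)
    for aa, idx in groups.items():
        vals = [codons[i] for i in idx]
        perm = rng.permutation(len(idx))
        for i, k in zip(idx, perm):
            codons[i] = vals[int(k)]


def _family_freqs(orfs: list[list[str]]) -> dict[str, np.ndarray]:
    counts: dict[str, np.ndarray] = {
        aa: np.zeros(len(f)) for aa, f in SYNONYMS.items()
    }
    index = {
        c: (CODON_TO_AA[c], i)
        for aa, f in SYNONYMS.items()
        for i, c in enumerate(f)
    }
    for orf in orfs:
        for c in orf:
            aa, i = index[c]
            counts[aa][i] += 1
    return counts


def _draw(aa: str, freqs: dict[str, np.ndarray], rng) -> str:
    w = freqs[aa]
    p = w / w.sum()
    return SYNONYMS[aa][int(rng.choice(len(p), p=p))]
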