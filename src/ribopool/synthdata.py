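"""Synthetic input generation: ORFs, mRNA levels, tRNA pools, fixtures.

Every generator is a pure function of its spec plus a seed, emitting
exactly the formats the simulator consumes, so the full pipeline can be
exercised without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic_code import SENSE_CODONS, SYNONYMS, CODON_TO_AA

AMINO_ACIDS = tuple(sorted(SYNONYMS))


def largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` across ``fractions`` (which are
    normalized internally); counts sum to ``total`` exactly."""
    fr = np.asarray(fractions, dtype=float)
    if (fr < 0).any() or fr.sum() <= 0:
        raise ValueError("fractions must be nonnegative with positive sum")
    fr = fr / fr.sum()
    raw = fr * total
    base = np.floor(raw).astype(np.int64)
    short = int(total - base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def default_codon_bias(skew: float = 0.5) -> dict[str, float]:
    """A fixed synonymous-codon usage profile.

    Within each family, probabilities fall geometrically with factor
    ``skew`` over the canonical codon order, mimicking codon usage bias.
    """
    probs: dict[str, float] = {}
    for aa, family in SYNONYMS.items():
        w = np.array([skew**i for i in range(len(family))])
        w /= w.sum()
        for c, p in zip(family, w):
            probs[c] = float(p)
    return probs


@dataclass
class SynthSpec:
    """Specification of a synthetic cell's inputs."""

    n_genes: int = 50
    orf_len_range: tuple[int, int] = (30, 60)  # codons incl. start
    codon_bias: dict[str, float] = field(default_factory=default_codon_bias)
    n_mrna: float = 500.0          # target N (sum of levels)
    mrna_sigma: float = 1.0        # log-normal spread of levels
    G_tot: int = 7_000
    H_tot: int = 65_000
    trna_fractions: np.ndarray | None = None  # default: uniform
    init_sigma: float = 0.3        # log-normal spread of init times
    mean_init_time: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.orf_len_range[0] < 2:
            raise ValueError("need >= 1 gene and ORFs of >= 2 codons")
        for aa, family in SYNONYMS.items():
            tot = sum(self.codon_bias.get(c, 0.0) for c in family)
            if tot <= 0:
                raise ValueError(f"codon bias gives zero mass to {aa}")


def generate_orf(
    length: int, bias: dict[str, float], rng: np.random.Generator
) -> list[str]:
    """One ORF: AUG start, ``length - 1`` biased sense codons, no stop."""
    codons = ["AUG"]
    aas = rng.choice(len(AMINO_ACIDS), size=length - 1)
    for ai in aas:
        family = SYNONYMS[AMINO_ACIDS[int(ai)]]
        p = np.array([bias.get(c, 0.0) for c in family])
        p = p / p.sum()
        codons.append(family[int(rng.choice(len(family), p=p))])
    return codons


def generate_transcriptome(
    spec: SynthSpec,
) -> tuple[dict[str, list[str]], dict[str, float], dict[str, float]]:
    """ORFs, mRNA levels and local initiation times for a synthetic cell.

    Levels are log-normal, rescaled to sum to ``spec.n_mrna``; initiation
    times are log-normal around ``spec.mean_init_time`` and normalized to
    that mean.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.orf_len_range
    orfs: dict[str, list[str]] = {}
    for g in range(spec.n_genes):
        L = int(rng.integers(lo, hi + 1))
        orfs[f"g{g:04d}"] = generate_orf(L, spec.codon_bias, rng)
    raw = rng.lognormal(mean=0.0, sigma=spec.mrna_sigma, size=spec.n_genes)
    raw *= spec.n_mrna / raw.sum()
    levels = {g: float(v) for g, v in zip(sorted(orfs), raw)}
    t = rng.lognormal(
        mean=np.log(spec.mean_init_time), sigma=spec.init_sigma,
        size=spec.n_genes,
    )
    t *= spec.mean_init_time / t.mean()
    init_times = {g: float(v) for g, v in zip(sorted(orfs), t)}
    return orfs, levels, init_times


def generate_trna_pool(
    spec: SynthSpec, trna_ids: list[str]
) -> dict[str, int]:
    """Integer per-species tRNA counts summing exactly to ``spec.H_tot``."""
    fr = spec.trna_fractions
    if fr is None:
        fr = np.full(len(trna_ids), 1.0 / len(trna_ids))
    counts = largest_remainder(np.asarray(fr, float), spec.H_tot)
    return {t: int(c) for t, c in zip(trna_ids, counts)}


def payload_orf(length: int = 240, seed: int = 424242) -> list[str]:
    """The bundled synthetic payload ORF (GFP-sized, 240 codons)."""
    rng = np.random.default_rng(seed)
    return generate_orf(length, default_codon_bias(), rng)


def toy_cell(seed: int = 0, **overrides) -> SynthSpec:
    """The standard desk-scale fixture: 50 gene types, 500 molecules,
    pools at one tenth of the full-cell preset (ratio preserved)."""
    kw = dict(
        n_genes=50, n_mrna=500.0, G_tot=7_000, H_tot=65_000, seed=seed
    )
    kw.update(overrides)
    return SynthSpec(**kw)


def full_cell_spec(seed: int = 0, **overrides) -> SynthSpec:
    """Full-pool preset with short synthetic ORFs (5,100 molecules,
    G_tot 70,000, H_tot 650,407)."""
    kw = dict(
        n_genes=300, n_mrna=5_100.0, G_tot=70_000, H_tot=650_407, seed=seed
    )
    kw.update(overrides)
    return SynthSpec(**kw)


# ---------------------------------------------------------------------------
# regression fixture
# ---------------------------------------------------------------------------


def generate_regression_fixture(
    n_rows: int,
    n_features: int,
    planted: list[int],
    coefficients: list[float],
    noise_sd: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Feature table with a planted linear signal.

    ``y = X[:, planted] @ coefficients + N(0, noise_sd)``.  Returns the
    feature frame (columns ``f00..``), the objective vector and a
    ground-truth record for recovery tests.
    """
    if len(planted) != len(coefficients):
        raise ValueError("planted and coefficients must align")
    if any(p >= n_features for p in planted):
        raise ValueError("planted index out of range")
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_rows, n_features))
    beta = np.zeros(n_features)
    beta[list(planted)] = coefficients
    y = X @ beta + rng.normal(scale=noise_sd, size=n_rows)
    cols = [f"f{i:02d}" for i in range(n_features)]
    truth = {
        "planted": [cols[p] for p in planted],
        "coefficients": list(map(float, coefficients)),
        "noise_sd": noise_sd,
        "snr": float(np.std(X @ beta) / noise_sd) if noise_sd > 0 else np.inf,
    }
    return pd.DataFrame(X, columns=cols), y, truth


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------


def write_fasta(orfs: dict[str, list[str]], path, stop: str = "UAA") -> None:
    """ORFs as uncompressed FASTA (RNA alphabet, stop codon appended)."""
    with open(path, "w") as fh:
        for g in sorted(orfs):
            seq = "".join(orfs[g]) + stop
            fh.write(f">{g}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_levels(levels: dict[str, float], path) -> None:
    pd.DataFrame(
        {"gene_id": sorted(levels), "level": [levels[g] for g in sorted(levels)]}
    ).to_csv(path, sep="\t", index=False)


def write_init_times(times: dict[str, float], path) -> None:
    pd.DataFrame(
        {"gene_id": sorted(times), "init_time_s": [times[g] for g in sorted(times)]}
    ).to_csv(path, sep="\t", index=False)


def write_trna_pool(pool: dict[str, int], path) -> None:
    pd.DataFrame(
        {"trna_id": sorted(pool), "total_count": [pool[t] for t in sorted(pool)]}
    ).to_csv(path, sep="\t", index=False)
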