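"""Codon-tRNA recognition, interaction coefficients and codon indices.

The central object is :class:`RecognitionTable`, a sparse map of
interaction coefficients ``alpha(codon, tRNA)`` in ``(0, 1]`` describing
which tRNA species decode which codons and how well (1.0 for Watson-Crick
pairing, lower for wobble pairings).  On top of it sit the tAI-style codon
weights, sequence-level tAI/CAI scores and a grid search that fits the
wobble-class coefficients against external per-gene target values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genetic_code import (
    CODON_INDEX,
    CODON_TO_AA,
    N_SENSE,
    SENSE_CODONS,
    SYNONYMS,
    is_sense,
    to_rna,
)

# wobble pairing classes and their default coefficients.  WC pairs are 1.0
# by definition; wobble defaults follow the classic tAI constraint values
# (coefficient = 1 - s).
DEFAULT_CLASS_COEFFS: dict[str, float] = {
    "watson_crick": 1.0,
    "gu": 0.59,     # G34 anticodon reading a U-ending codon
    "ic": 0.72,     # inosine reading a C-ending codon
    "ia": 0.0001,   # inosine reading an A-ending codon
    "ug": 0.32,     # modified U34 reading a G-ending codon
}

WOBBLE_CLASSES = tuple(k for k in DEFAULT_CLASS_COEFFS if k != "watson_crick")


class RecognitionError(ValueError):
    """Raised when a recognition table fails validation."""


@dataclass
class RecognitionTable:
    """Sparse codon-tRNA interaction coefficients.

    Parameters
    ----------
    trna_ids
        Ordered tRNA species identifiers.
    alpha
        Map ``(codon, trna_id) -> coefficient`` with coefficients in
        ``(0, 1]``.  Codons are RNA trinucleotides.
    """

    trna_ids: list[str]
    alpha: dict[tuple[str, str], float]
    _packed: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.trna_index = {t: i for i, t in enumerate(self.trna_ids)}
        self._rt: dict[str, list[tuple[str, float]]] = {}
        for (c, t), a in self.alpha.items():
            if not is_sense(c):
                raise RecognitionError(f"codon {c} is not a sense codon")
            if t not in self.trna_index:
                raise RecognitionError(f"unknown tRNA id {t}")
            if not (0.0 < a <= 1.0):
                raise RecognitionError(
                    f"coefficient alpha({c},{t})={a} outside (0,1]"
                )
            self._rt.setdefault(c, []).append((t, a))
        for c in self._rt:
            self._rt[c].sort()
        missing = [c for c in SENSE_CODONS if c not in self._rt]
        if missing:
            raise RecognitionError(
                "sense codon(s) with no recognizing tRNA: " + ", ".join(missing)
            )

    # -- queries ---------------------------------------------------------
    def rt(self, codon: str) -> set[str]:
        """Set of tRNA ids recognizing ``codon``."""
        return {t for t, _ in self.decoders(codon)}

    def decoders(self, codon: str) -> list[tuple[str, float]]:
        """``(trna_id, alpha)`` pairs for ``codon`` (sorted by id)."""
        codon = to_rna(codon)
        if codon not in self._rt:
            raise RecognitionError(f"codon {codon} is not a sense codon")
        return list(self._rt[codon])

    @property
    def n_trna(self) -> int:
        return len(self.trna_ids)

    # -- packed representation for the simulation kernel -----------------
    def packed(self) -> dict:
        """Flat CSR-style arrays used by the numba kernel.

        Returns a dict with codon->tRNA arrays (``c2t_off``, ``c2t_j``,
        ``c2t_a``) indexed by the canonical sense-codon order.
        """
        if self._packed is None:
            off = np.zeros(N_SENSE + 1, dtype=np.int64)
            js: list[int] = []
            al: list[float] = []
            for i, c in enumerate(SENSE_CODONS):
                for t, a in self._rt[c]:
                    js.append(self.trna_index[t])
                    al.append(a)
                off[i + 1] = len(js)
            self._packed = {
                "c2t_off": off,
                "c2t_j": np.asarray(js, dtype=np.int64),
                "c2t_a": np.asarray(al, dtype=np.float64),
            }
        return self._packed

    # -- I/O -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"codon": c, "trna_id": t, "alpha": a}
            for (c, t), a in sorted(self.alpha.items())
        ]
        return pd.DataFrame(rows, columns=["codon", "trna_id", "alpha"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RecognitionTable":
        df = pd.read_csv(path, sep="\t", dtype={"codon": str, "trna_id": str})
        alpha = {
            (to_rna(r.codon), r.trna_id): float(r.alpha)
            for r in df.itertuples()
        }
        trna_ids = sorted({t for _, t in alpha})
        return cls(trna_ids, alpha)


def build_recognition_table(
    wobble_rules: list[tuple[str, str, str]],
    default_class_coeffs: dict[str, float] | None = None,
) -> RecognitionTable:
    """Build a :class:`RecognitionTable` from ``(codon, trna, class)`` rules.

    Each rule assigns ``alpha(codon, trna)`` to the coefficient of its
    pairing class.  Watson-Crick pairs get 1.0 unless the class map
    overrides it.  Validation fails (naming the codon) if any sense codon
    ends up with no decoder.
    """
    coeffs = dict(DEFAULT_CLASS_COEFFS)
    if default_class_coeffs:
        coeffs.update(default_class_coeffs)
    for k, v in coeffs.items():
        if not (0.0 < v <= 1.0):
            raise RecognitionError(f"class coefficient {k}={v} outside (0,1]")
    alpha: dict[tuple[str, str], float] = {}
    trna_ids: list[str] = []
    seen = set()
    for codon, trna, klass in wobble_rules:
        codon = to_rna(codon)
        if not is_sense(codon):
            raise RecognitionError(f"codon {codon} is not a sense codon")
        if klass not in coeffs:
            raise RecognitionError(f"unknown pairing class {klass!r}")
        alpha[(codon, trna)] = coeffs[klass]
        if trna not in seen:
            seen.add(trna)
            trna_ids.append(trna)
    return RecognitionTable(sorted(trna_ids), alpha)


def default_wobble_rules() -> list[tuple[str, str, str]]:
    """Rule list for a standard bacterial-style wobble decoding scheme.

    tRNA species are generated per codon box (first two nucleotides) and
    amino acid: a G34 species reads the C-ending codon (WC) and the
    U-ending codon (G:U wobble); a U34 species reads the A-ending codon
    (WC) and the G-ending codon of the same amino acid (modified-U
    wobble); amino acids represented only by a G-ending codon in the box
    (Met, Trp) get a dedicated C34 species.  The result covers all 61
    sense codons and is fully overridable from a TSV.
    """
    rules: list[tuple[str, str, str]] = []
    boxes: dict[tuple[str, str], list[str]] = {}
    for c in SENSE_CODONS:
        boxes.setdefault((c[:2], CODON_TO_AA[c]), []).append(c)
    comp = {"A": "U", "C": "G", "G": "C", "U": "A"}

    def anticodon(codon: str) -> str:
        return "".join(comp[n] for n in reversed(codon))

    for (_, aa), codons in sorted(boxes.items()):
        ends = {c[2]: c for c in codons}
        if "C" in ends or "U" in ends:
            wc = ends.get("C", ends.get("U"))
            tid = f"tRNA-{aa}-{anticodon(wc)}"
            if "C" in ends:
                rules.append((ends["C"], tid, "watson_crick"))
                if "U" in ends:
                    rules.append((ends["U"], tid, "gu"))
            else:
                rules.append((ends["U"], tid, "watson_crick"))
        if "A" in ends:
            tid = f"tRNA-{aa}-{anticodon(ends['A'])}"
            rules.append((ends["A"], tid, "watson_crick"))
            if "G" in ends:
                rules.append((ends["G"], tid, "ug"))
        elif "G" in ends:
            tid = f"tRNA-{aa}-{anticodon(ends['G'])}"
            rules.append((ends["G"], tid, "watson_crick"))
    return rules


def default_recognition_table(
    class_coeffs: dict[str, float] | None = None,
) -> RecognitionTable:
    """The built-in wobble-rule recognition table (see
    :func:`default_wobble_rules`)."""
    return build_recognition_table(default_wobble_rules(), class_coeffs)


# ---------------------------------------------------------------------------
# codon scores
# ---------------------------------------------------------------------------


@dataclass
class CodonScores:
    """Named per-codon real values over the 61 sense codons."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = [c for c in SENSE_CODONS if c not in self.values]
        if missing:
            raise ValueError(
                f"scores {self.name!r} missing codons: {missing[:5]}..."
            )

    def __getitem__(self, codon: str) -> float:
        return self.values[to_rna(codon)]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[c] for c in SENSE_CODONS])


def tai_weights(
    table: RecognitionTable, trna_levels: dict[str, float]
) -> CodonScores:
    """tAI-style codon weights from tRNA abundances.

    Raw weight ``W(c) = sum_j alpha(c,j) * level(j)`` over the decoders of
    ``c``, normalized by the maximum.  Codons whose decoders all have zero
    abundance take the geometric mean of the nonzero normalized weights
    (the standard tAI convention).
    """
    for t, lv in trna_levels.items():
        if lv < 0:
            raise ValueError(f"negative abundance for {t}")
    raw = {}
    for c in SENSE_CODONS:
        raw[c] = sum(a * trna_levels.get(t, 0.0) for t, a in table.decoders(c))
    wmax = max(raw.values())
    if wmax <= 0:
        raise ValueError("all tRNA levels are zero")
    w = {c: raw[c] / wmax for c in SENSE_CODONS}
    nonzero = [v for v in w.values() if v > 0]
    gm = math.exp(sum(math.log(v) for v in nonzero) / len(nonzero))
    for c in w:
        if w[c] == 0:
            w[c] = gm
    return CodonScores("tai", w)


def _geomean_weights(codons: list[str], weights: CodonScores) -> float:
    if not codons:
        raise ValueError("empty ORF")
    total = 0.0
    for pos, c in enumerate(codons):
        c = to_rna(c)
        if not is_sense(c):
            raise ValueError(f"stop or invalid codon {c} at position {pos + 1}")
        total += math.log(weights[c])
    return math.exp(total / len(codons))


def tai_of_sequence(orf: list[str], weights: CodonScores) -> float:
    """Geometric mean of tAI weights over the ORF (start codon included,
    stop excluded)."""
    return _geomean_weights(orf, weights)


def cai_reference_weights(reference_orfs: list[list[str]]) -> CodonScores:
    """CAI relative-adaptiveness weights from a reference ORF set.

    Within each amino-acid family the most frequent codon gets weight 1;
    others get count/max.  Codons unobserved in the reference take
    ``0.5/max`` (to keep the geometric mean finite).
    """
    counts = {c: 0 for c in SENSE_CODONS}
    for orf in reference_orfs:
        for c in orf:
            c = to_rna(c)
            if c in counts:
                counts[c] += 1
    w = {}
    for aa, family in SYNONYMS.items():
        mx = max(counts[c] for c in family)
        for c in family:
            if mx == 0:
                w[c] = 1.0
            else:
                w[c] = counts[c] / mx if counts[c] > 0 else 0.5 / mx
    return CodonScores("cai", w)


def cai_of_sequence(orf: list[str], cai_weights: CodonScores) -> float:
    """Geometric mean of CAI relative adaptiveness over the ORF."""
    return _geomean_weights(orf, cai_weights)


# ---------------------------------------------------------------------------
# wobble-coefficient optimization
# ---------------------------------------------------------------------------


def _objective(
    table: RecognitionTable,
    trna_levels: dict[str, float],
    orfs: list[list[str]],
    target_vectors: list[np.ndarray],
    kind: str,
) -> float:
    w = tai_weights(table, trna_levels)
    tai = np.array([tai_of_sequence(o, w) for o in orfs])
    corr = {"spearman": sps.spearmanr, "pearson": sps.pearsonr}[kind]
    return float(sum(corr(tai, y).statistic for y in target_vectors))


def optimize_interaction_coefficients(
    wobble_rules: list[tuple[str, str, str]],
    trna_levels: dict[str, float],
    orfs: list[list[str]],
    targets,
    objective: str = "spearman",
    grid_points: int = 20,
    n_sweeps: int = 2,
) -> tuple[RecognitionTable, dict[str, float], float]:
    """Fit wobble-class coefficients by coordinate grid search.

    ``targets`` is one per-gene vector or a list of vectors; the objective
    is the sum over vectors of the rank (or Pearson) correlation between
    per-gene tAI and the target.  Watson-Crick stays fixed at 1.  Returns
    ``(table, class_coeffs, achieved_objective)``.

    The search is exhaustive per class over ``grid_points`` values in
    ``(0, 1]`` with ``n_sweeps`` coordinate-refinement sweeps, so the
    result can be checked against a brute-force grid oracle.
    """
    if isinstance(targets, (list, tuple)) and np.ndim(targets[0]) > 0:
        tvecs = [np.asarray(t, dtype=float) for t in targets]
    else:
        tvecs = [np.asarray(targets, dtype=float)]
    if len(orfs) < 2:
        raise ValueError("need at least 2 genes to correlate")
    for y in tvecs:
        if len(y) != len(orfs):
            raise ValueError("targets length != number of ORFs")
        if not np.all(np.isfinite(y)):
            raise ValueError("targets must be finite")
        if np.ptp(y) == 0:
            raise ValueError("constant target vector: correlation undefined")

    classes = sorted({k for _, _, k in wobble_rules if k != "watson_crick"})
    grid = np.linspace(1.0 / grid_points, 1.0, grid_points)
    coeffs = {k: DEFAULT_CLASS_COEFFS.get(k, 0.5) for k in classes}
    best = None
    for _ in range(max(1, n_sweeps)):
        for k in classes:
            scores = []
            for g in grid:
                trial = dict(coeffs)
                trial[k] = float(g)
                table = build_recognition_table(wobble_rules, trial)
                scores.append(
                    _objective(table, trna_levels, orfs, tvecs, objective)
                )
            i = int(np.argmax(scores))
            coeffs[k] = float(grid[i])
            best = scores[i]
    table = build_recognition_table(wobble_rules, coeffs)
    if best is None:  # no free wobble classes
        best = _objective(table, trna_levels, orfs, tvecs, objective)
    return table, coeffs, float(best)


def grid_search_oracle(
    wobble_rules, trna_levels, orfs, targets, objective="spearman",
    grid_points=20,
):
    """Exhaustive full-grid search over all wobble-class combinations.

    Exponential in the number of classes; intended as a test oracle for
    :func:`optimize_interaction_coefficients` on <= 3 classes.
    """
    tvecs = (
        [np.asarray(t, float) for t in targets]
        if isinstance(targets, (list, tuple)) and np.ndim(targets[0]) > 0
        else [np.asarray(targets, float)]
    )
    classes = sorted({k for _, _, k in wobble_rules if k != "watson_crick"})
    grid = np.linspace(1.0 / grid_points, 1.0, grid_points)
    best, best_coeffs = -np.inf, {}
    for combo in itertools.product(grid, repeat=len(classes)):
        coeffs = dict(zip(classes, map(float, combo)))
        table = build_recognition_table(wobble_rules, coeffs)
        s = _objective(table, trna_levels, orfs, tvecs, objective)
        if s > best:
            best, best_coeffs = s, coeffs
    return best_coeffs, float(best)
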