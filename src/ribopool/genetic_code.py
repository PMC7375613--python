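"""Standard genetic code, codon indexing and translation helpers.

All internal sequence handling uses the RNA alphabet (``ACGU``); DNA input
is accepted everywhere and converted on the way in.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_rna_by_id[1]

#: map of the 61 sense codons to one-letter amino-acid symbols
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

#: the three stop codons
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: canonical (lexicographic) ordering of the 61 sense codons
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: codon -> position in :data:`SENSE_CODONS`
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

N_SENSE = len(SENSE_CODONS)

#: amino acid -> tuple of synonymous codons (canonical order)
SYNONYMS: dict[str, tuple[str, ...]] = {}
for _c in SENSE_CODONS:
    SYNONYMS.setdefault(CODON_TO_AA[_c], ())
    SYNONYMS[CODON_TO_AA[_c]] += (_c,)

assert N_SENSE == 61 and len(STOP_CODONS) == 3


def to_rna(seq: str) -> str:
    """Uppercase and convert T->U."""
    return seq.upper().replace("T", "U")


def is_sense(codon: str) -> bool:
    return codon in CODON_TO_AA


def split_codons(seq: str) -> list[str]:
    """Split an in-frame nucleotide string into codons.

    Raises ``ValueError`` if the length is not a multiple of 3 or a codon
    contains a non-ACGU character.
    """
    rna = to_rna(seq)
    if len(rna) % 3 != 0:
        raise ValueError(f"sequence length {len(rna)} is not a multiple of 3")
    codons = [rna[i : i + 3] for i in range(0, len(rna), 3)]
    for c in codons:
        if c not in CODON_TO_AA and c not in STOP_CODONS:
            raise ValueError(f"invalid codon {c!r}")
    return codons


def orf_codons(seq: str) -> list[str]:
    """Codons of an ORF excluding a trailing stop codon (if present).

    Internal stop codons raise ``ValueError``.
    """
    codons = split_codons(seq)
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    for pos, c in enumerate(codons):
        if c in STOP_CODONS:
            raise ValueError(f"internal stop codon {c} at codon {pos + 1}")
    return codons


def translate(codons: list[str]) -> str:
    """Translate a list of sense codons into a protein string."""
    return "".join(CODON_TO_AA[c] for c in codons)


def codon_ids(codons: list[str]) -> list[int]:
    """Map sense codons to integer ids in :data:`SENSE_CODONS` order."""
    try:
        return [CODON_INDEX[c] for c in codons]
    except KeyError as exc:  # pragma: no cover - message formatting
        raise ValueError(f"not a sense codon: {exc.args[0]}") from None
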