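import numpy as np
import pytest

from ribopool.codon_model import (
    RecognitionTable,
    build_recognition_table,
    default_recognition_table,
)
from ribopool.engine import Cell, EngineConfig, MRNALattice
from ribopool.genetic_code import SENSE_CODONS
from ribopool.resources import RecyclingParams, ResourceState


def wc_rules():
    """One dedicated Watson-Crick tRNA per sense codon (alpha = 1)."""
    return [(c, f"t-{c}", "watson_crick") for c in SENSE_CODONS]


@pytest.fixture(scope="session")
def wc_table() -> RecognitionTable:
    return build_recognition_table(wc_rules())


@pytest.fixture(scope="session")
def default_table() -> RecognitionTable:
    return default_recognition_table()


def make_cell(
    orfs,
    table,
    G_tot=100,
    H_each=1000,
    init_times=None,
    cfg=None,
    seed=0,
    rec=None,
):
    """Tiny cell from explicit codon lists; uniform per-species pools."""
    cfg = cfg or EngineConfig()
    rec = rec or RecyclingParams.zero()
    h = np.full(table.n_trna, H_each, dtype=np.int64)
    state = ResourceState(G_tot, h, table)
    if init_times is None:
        init_times = [0.95] * len(orfs)
    lats = [
        MRNALattice(f"g{i}", codons, t)
        for i, (codons, t) in enumerate(zip(orfs, init_times))
    ]
    return Cell(lats, state, table, rec, cfg, seed=seed)


@pytest.fixture
def toy_inputs():
    """Small synthetic transcriptome + default table + recycling params."""
    import ribopool.synthdata as sd
    from ribopool.resources import distance_scores

    spec = sd.toy_cell(seed=7, n_genes=20, n_mrna=100.0)
    orfs, levels, init_times = sd.generate_transcriptome(spec)
    table = default_recognition_table()
    rec = distance_scores(
        [(orfs[g], levels[g]) for g in sorted(orfs)], table
    )
    return spec, orfs, levels, init_times, table, rec
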