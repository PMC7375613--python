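# ribopool

Whole-cell, codon-resolution simulation of mRNA translation with finite,
conserved ribosome and tRNA pools.

Every mRNA molecule in the cell is a one-dimensional codon lattice on
which ribosomes (footprint `s` codons, no overlap, no overtaking) move
under a deterministic, timer-driven exclusion process.  Timers are set
from live supply-demand ratios:

- **RSDR** (initiation): free ribosomes / mRNAs awaiting an initiation
  complex;
- **ESDR** (elongation, per codon `c`):
  `sum_{j in rt(c)} alpha(c,j) * H_free(j) / max(D_j, 1)^(1 - exp(-w d_c))`,
  where `alpha(c,j) in (0,1]` are wobble-aware codon-tRNA interaction
  coefficients, `D_j` is the alpha-weighted demand for species `j`, and
  the `d_c`-dependent exponent discounts demand for codon types whose
  co-decoded neighbors are close (tRNA recycling).

Both pools are conserved exactly at every tick.  On top of the engine sit
pool-size and initiation-time calibration, heterologous payload insertion
with folding-energy-dependent initiation, two synonymous variant
generators, four genome randomization modes, tAI/CAI codon indices with a
wobble-coefficient optimizer, and a repeated train/test greedy
forward-selection regressor with SCR feature ranking.  A synthetic-data
module generates every input the simulator reads, so the full pipeline
runs without external data.

## Library quick start

```python
import numpy as np
import ribopool as rp
import ribopool.synthdata as sd

spec = sd.toy_cell(seed=1)                      # 500 molecules, pools /10
orfs, levels, init_times = sd.generate_transcriptome(spec)
table = rp.default_recognition_table()
rec = rp.distance_scores([(orfs[g], levels[g]) for g in sorted(orfs)], table)

cfg = rp.CellConfig(seed=1, run_ticks=3000)
lats = rp.instantiate_transcriptome(levels, orfs, init_times,
                                    np.random.default_rng(1))
res = rp.run_simulation(cfg, lats, table, rec)
rp.verify_conservation(res)                     # exact, every tick
print(res.steady_tick, res.active_fraction, res.per_gene_frame().head())
```

The full-cell preset (`rp.FULL_CELL`) carries the reference parameters
N = 5,100 molecules, G_tot = 70,000 ribosomes, H_tot = 650,407 tRNAs and
a 0.95 s mean initiation time; `rp.calibrate_pools` bisects a global pool
scale (ribosome:tRNA ratio fixed) to a target active-ribosome fraction
(default 80%), and `rp.calibrate_initiation` normalizes local initiation
times to the target mean.

## CLI

One executable with subcommands; structured settings come from a YAML
config, `--seed`/`--outdir` override scalars, and every run writes a
`manifest.json` sufficient to re-run bit-identically.

```sh
ribopool synth --seed 1 --outdir inputs/          # FASTA + TSV input set
ribopool simulate --config run.yaml --seed 1 --outdir out/
ribopool calibrate --config run.yaml --target-activity 0.8 --outdir cal/
ribopool variants --method 2 --outdir var/        # 61 synonymous variants
ribopool randomize --mode orf_shuffle --fasta inputs/orfs.fasta --outdir rnd/
ribopool regress --table features.tsv --objective y --outdir reg/
```

`run.yaml` names the input files and the cell parameters:

```yaml
inputs:
  orfs: inputs/orfs.fasta
  levels: inputs/levels.tsv
  init_times: inputs/init_times.tsv
  trna_pool: inputs/trna_pool.tsv
  recognition: inputs/recognition.tsv   # optional; built-in rules otherwise
cell:
  n_mrna: 500
  G_tot: 7000
  run_ticks: 3000
```

## Layout

| module | contents |
| --- | --- |
| `ribopool.genetic_code` | genetic code tables, codon indexing, translation |
| `ribopool.codon_model` | recognition table, interaction coefficients, tAI/CAI, coefficient optimizer |
| `ribopool.resources` | conserved pools, demand counters, RSDR/ESDR, recycling distances |
| `ribopool.engine` | per-mRNA exclusion process, codon state machines, compiled tick loop (`_kernel`) |
| `ribopool.cell_sim` | transcriptome instantiation, steady-state detection, calibration, result assembly |
| `ribopool.variants` | heterologous insertion, variant methods 1/2, genome randomizations |
| `ribopool.stats` | OLS, forward selection + SCR, ranked evaluation, partial Spearman |
| `ribopool.synthdata` | seeded generators for all inputs and regression fixtures |
| `ribopool.cli` | `ribopool` executable |
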