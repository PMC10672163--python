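# neuromirnet

Analysis toolkit for cell-type-specific miRNA–mRNA regulatory networks in
neuroinflammatory disease models. The package covers the full path from raw
count matrices to a ranked, tiered miRNA–target network, plus the statistics
for the wet-lab assays used to validate such networks:

1. **Differential expression** of small-RNA and mRNA count data with a
   negative-binomial Wald test (median-of-ratios normalization, dispersion
   trend with empirical-Bayes shrinkage, Benjamini–Hochberg FDR).
2. **Cross-cohort consensus**: miRNA candidates must be significant, in the
   same direction, in every independent cohort; candidates are ranked by
   their best FDR across cohorts.
3. **Target integration**: TargetScan-style cumulative weighted context++
   scores (CWCS) are collapsed to gene level, tiered by confidence
   (CWCS < −0.4 high, < −0.2 moderate, otherwise dropped), and intersected
   with up-regulated miRNAs and down-regulated mRNAs to form a bipartite
   regulatory network.
4. **Seed-site scanning** of 3′UTRs for canonical 8mer / 7mer-m8 / 7mer-A1 /
   6mer matches to a miRNA seed (nucleotides 2–8).
5. **Enrichment** of gene lists against GMT gene-set collections via the
   hypergeometric test.
6. **Assay statistics**: 2^−ΔΔCt relative quantification for qPCR,
   baseline-anchored viability normalization, dual-luciferase RLU ratios,
   and clinical-score analysis (exclusion, imputation, per-animal trapezoid
   AUC, exact Mann–Whitney U).

A seeded simulator (`neuromirnet.simulate`) generates synthetic studies with
known ground truth — planted miRNA fold changes, silenced target genes,
CWCS tables, 3′UTRs with planted seed sites, and assay read-outs — so every
stage of the pipeline can be validated end to end.

## Worked example

A complete synthetic study, from counts to the regulatory network:

```python
from neuromirnet.simulate import (
    SimulationConfig, simulate_mirna_cohorts, simulate_mrna_with_targets,
)
from neuromirnet.diffexp import qc_filter_samples, wald_test, call_de
from neuromirnet.consensus import consensus_candidates
from neuromirnet.target_integration import (
    gene_level_predictions, tier_predictions, integrate,
)
from neuromirnet.network import build_network, network_summary

cfg = SimulationConfig(seed=42)          # two cohorts, 24 planted miRNAs
cohorts, truth = simulate_mirna_cohorts(cfg)

results = []
for matrix, sheet in cohorts:
    matrix, sheet, excluded = qc_filter_samples(matrix, sheet)
    results.append(wald_test(matrix, sheet))

consensus = consensus_candidates(results)
print(f"consensus candidates: {len(consensus)}")
print(consensus.head(3)[["mirna", "rank", "rank_score", "direction"]])

up = set(consensus.loc[consensus["direction"] == "up", "mirna"])
(mrna, mrna_sheet), predictions, truth = simulate_mrna_with_targets(cfg, truth)
down = call_de(wald_test(mrna, mrna_sheet)).down
tiered = tier_predictions(gene_level_predictions(predictions))
edges = integrate(up, tiered, down)

recovered = {(e.mirna_id, e.gene_id) for e in edges}
tp = len(recovered & truth.true_edges)
print(f"edges: {len(edges)}, precision {tp/len(recovered):.3f}, "
      f"recall {tp/len(truth.true_edges):.3f}")
print(network_summary(build_network(edges))["edges_per_tier"])
```

Output:

```
consensus candidates: 24
         mirna  rank  rank_score direction
0  miR-sim-120     1   26.908354        up
1  miR-sim-220     2   25.033227        up
2  miR-sim-229     3   23.440931      down
edges: 478, precision 1.000, recall 0.996
{'high': 375, 'moderate': 103}
```

All 24 planted miRNAs are recovered as consensus candidates; the integrated
network recovers the planted miRNA–target edges with precision 1.000 and
recall 0.996.

Seed-site scanning and qPCR quantification:

```python
from neuromirnet.target_integration import scan_sites, seed_of
from neuromirnet.assays import CtRecord, ddct

seed = seed_of("UAUUGCACUUGUCCCGGCCUGU")   # miR-92a-3p -> "AUUGCAC"
for s in scan_sites("AAGUGCAAUAAA", seed):
    print(s.start, s.site_type)            # -> 3 8mer

records = [
    CtRecord("c1", "control", "Mkx", (25.1, 25.0, 24.9)),
    CtRecord("c1", "control", "U6",  (20.0, 20.1, 19.9)),
    CtRecord("t1", "treated", "Mkx", (24.0, 24.1, 23.9)),
    CtRecord("t1", "treated", "U6",  (20.0, 20.0, 20.0)),
]
print(ddct(records, "U6", "control"))
```

```
3 8mer
  sample_id    group  dct  ddct   rq
0        c1  control  5.0   0.0  1.0
1        t1  treated  4.0  -1.0  2.0
```

## Command-line interface

Every stage is also exposed through the `neuromirnet` CLI:

```bash
neuromirnet simulate --seed 1 --outdir study/       # synthetic study + truth
neuromirnet de --counts c1.tsv --samples c1.samples.tsv --out de1.tsv
neuromirnet consensus --de de1.tsv --de de2.tsv --out consensus.tsv
neuromirnet integrate --candidates consensus.tsv --predictions ts.tsv \
    --mrna-de mrna_de.tsv --out edges.tsv
neuromirnet scan --utrs utrs.fa --seed AUUGCAC --out sites.tsv
neuromirnet network --edges edges.tsv --out network.graphml
neuromirnet ora --query genes.txt --gmt sets.gmt --universe universe.txt --out ora.tsv
```

Run `neuromirnet --help` (or any subcommand with `--help`) for the full set
of commands, including `convert`, `validate`, `ddct`, `viability`, `rlu`,
and `eae`.

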