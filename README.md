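# refstab

Reference-gene stability evaluation for high-throughput RT-qPCR panels.

## The problem

Relative quantification by qPCR is only as reliable as its normalization:
target-gene quantification cycles (Cq) are divided by the signal of one or
more *reference genes* (RG) assumed to be stably expressed across all
samples and conditions. Genes picked for their "housekeeping" reputation
(*Actb*, *Gapdh*, *B2m*, *Tbp*, ...) are often not stable in a given tissue
or disease model, and normalizing against an unstable reference can erase —
or fabricate — group differences. With array-scale platforms running a
hundred assays per sample, the stable references can instead be *searched
for* empirically, across the whole panel.

`refstab` implements that search as a tested, reusable pipeline for
replicate-level Cq panels with a group label per sample (e.g. control vs
infected animals):

1. **QC** — replicates are averaged per gene × sample cell; any gene with a
   cell in which no replicate amplified is excluded (all downstream
   statistics need a complete matrix).
2. **Four stability algorithms** —
   * *geNorm*: M value = mean over partner genes of SD of the pairwise
     log₂-ratio; stepwise elimination of the worst gene; V(n/n+1) curve for
     the number of references needed (thresholds M < 0.5, V < 0.15);
   * *NormFinder*: model-based stability
     ρᵢ = (1/G) Σ_g (|d̃ᵢg| + √(σ̂²ᵢg/n_g)) combining a shrunk intergroup
     deviation with the intragroup standard error;
   * *BestKeeper*: SD and CV% of raw Cq plus correlation with the
     per-sample geometric-mean index;
   * *comparative ΔCt*: mean over partners of SD of pairwise Cq
     differences.
3. **Consensus** — per-gene ranks from the four methods are combined by
   geometric mean (RefFinder-style), and top-n lists can be intersected
   across algorithms and cohorts.
4. **Evaluation** — targets are normalized by a chosen RG set
   (NF_s = geometric mean of the references' relative quantities,
   NRQ = RQ/NF) and groups are compared with the two-sided Mann–Whitney U
   test, demonstrating how RG choice changes fold changes and significance
   calls.

A synthetic-data module generates panels with known ground truth —
per-sample loading offsets, per-gene biological noise, planted group
effects and replicate dropout — including a fixed study-scale scenario
(112 assays × 47 samples × 3 replicates with 1516 failed reactions across
41 genes) that exercises every stage at realistic dimensions.

## Worked example

```python
from refstab import *

panel = study_scenario()                      # fixed synthetic study panel
cq, report = run_qc(panel)                    # replicate aggregation + filtering
log2rq = to_log2_rq(cq)                       # relative quantities, base 2

gn = rank_genorm(log2rq)
comp = aggregate([
    gn.stability_table(),
    normfinder(log2rq).stability_table(),
    bestkeeper(cq).stability_table(),
    delta_ct(cq).stability_table(),
])
rep = compare_groups(normalize(log2rq, ["Il2rg", "Itgb2"],
                               ["Cxcl10", "Ifng", "Tnf"]))
```

which prints (via the report objects):

```
QC: 71/112 genes retained; 1516/15792 reactions missing (9.6%)
geNorm top 5:          Il2rg, Itgb2, Myd88, Stat6, Il10ra
recommended n: 2  (V(2/3) = 0.0597 < 0.15)
comprehensive top 5:   Itgb2, Myd88, Il2rg, Stat6, Il10rb
normalized with Il2rg+Itgb2 (infected vs control):
  Cxcl10  fold change 6.65  U =     0  p = 4.54e-09  **
  Ifng    fold change 4.09  U =     7  p = 1.10e-08  **
  Tnf     fold change 2.55  U =    10  p = 1.60e-08  **
```

Reading it: 41 genes had at least one sample with no amplification in any
replicate and were dropped. Among the 71 complete genes, the designed-
stable block (including *Il2rg* and *Itgb2*) tops both the geNorm and the
four-method consensus rankings, and the V-curve says two references
suffice. Normalizing the three induced cytokines against *Il2rg*+*Itgb2*
recovers their planted up-regulation with strong significance
(`**` = p < 0.01, `*` = p < 0.05).

The same analysis is available from the shell:

```bash
refstab fixture --out panel.csv
refstab qc --input panel.csv
refstab reffinder --input panel.csv --cohort control
refstab evaluate --input panel.csv --rg Il2rg,Itgb2 --targets Cxcl10,Ifng,Tnf
refstab run --out results/   # full multi-cohort pipeline + manifest
```

## Layout

* `src/refstab/` — `panel` (containers), `cq_io` (long/wide CSV, report
  writers), `qc`, `expression`, `genorm`, `normfinder`, `simple`
  (BestKeeper + ΔCt), `tables`, `reffinder`, `evaluate`, `synthetic`,
  `pipeline`, `plots`, `cli`.
* `tests/` — unit, property and end-to-end suites (pytest + hypothesis).
* `docs/methods.md` — model definitions, defaults and design notes.
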