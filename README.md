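# txdyn

Time-course transcriptome dynamics toolkit for multi-timepoint RNA studies
with one pooled library per timepoint — the design used to profile mouse
testis development weekly from puberty to adulthood across four RNA classes
(mRNA, lncRNA, circRNA, miRNA).

Given gene × timepoint count tables, `txdyn` runs the full downstream
analysis:

- **quantify** — CPM / TPM / FPKM, median-of-ratios size factors,
  seven-category abundance profiling, library summary rates, PCA and sample
  correlation.
- **de** — differential expression between each pair of *adjacent*
  timepoints under a no-replicate negative-binomial model: blind dispersion
  with a fitted `alpha(mu) = a0/mu + a1` trend, and a two-sided NB exact
  test conditioning on the normalized pair sum. A gene is called
  U (up: log2FC > 1, p < 0.05), D (down) or M (maintained) per interval.
- **trajectory** — each gene's dynamics become a U/D/M string over the k
  intervals (3^k possible patterns; 6,561 for nine timepoints), with ranked
  frequency tables and pattern-space coverage statistics.
- **ppi** — confidence-filtered interaction graphs (STRING-style scores,
  threshold 0.400 inclusive) and MCODE-style dense-module extraction with
  k-core vertex weighting and top-5 preliminary hubs.
- **hubs** — twelve topological centralities (MCC, DMNC, MNC, Degree, EPC,
  BottleNeck, EcCentricity, Closeness, Radiality, Betweenness, Stress,
  Clustering Coefficient) and a top-k consensus hub rule.
- **cerna** — competing-endogenous-RNA networks: differential
  lncRNA/circRNA and mRNA joined through shared differential miRNAs into
  triples and circRNA–miRNA–lncRNA–mRNA quadruples.
- **enrich** — hypergeometric over-representation of any gene list (or
  pattern-wise gene groups) against user-supplied GMT collections.
- **simulate** — every input above with planted ground truth: NB counts
  with planted U/D/M trajectories, planted-partition interaction graphs,
  and miRNA-target tables with planted shared-miRNA triples.

The model details and design choices are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate a small nine-timepoint study with three planted dynamic genes and
run the core pipeline:

```python
from txdyn import (coverage_of, deg_table, encode_trajectories,
                   pattern_frequency, simulate_counts, test_all_adjacent)
from txdyn.simulate import SimConfig

patterns = {**{f"gene{i:02d}": "MMMMMMMM" for i in range(12)},
            "Prm1like": "UMMMMMMM", "earlyoff": "DMMMMMMM", "midpeak": "MMMUDMMM"}
cfg = SimConfig(pattern_assignments=patterns,
                baseline_means={g: 300.0 for g in patterns},
                dispersion=0.01, fold_step=8.0, seed=7)

counts, truth = simulate_counts(cfg)
records = test_all_adjacent(counts)          # NB exact test, 8 intervals
traj = encode_trajectories(records)          # U/D/M string per gene

print(pattern_frequency(traj).to_string(index=False))
print(coverage_of(traj))
print(deg_table(records).to_string())
```

Output:

```text
 rank  pattern  count  percentage
    1 MMMMMMMM     12       80.00
    2 DMMMMMMM      1        6.67
    3 MMMUDMMM      1        6.67
    4 UMMMMMMM      1        6.67
{'n_unique': 4, 'space_size': 6561, 'coverage_pct': 0.06}
          up  down  total
interval
3w-4w      1     1      2
4w-5w      0     0      0
5w-6w      0     0      0
6w-7w      1     0      1
7w-8w      0     1      1
8w-9w      0     0      0
9w-10w     0     0      0
10w-11w    0     0      0
all        2     2      4
```

All three planted trajectories are recovered exactly: the frequency table
ranks the all-maintained pattern first (12 of 15 genes, 80.00%), the four
observed patterns cover 0.06% of the 6,561-string pattern space, and the
interval table shows the planted U/D calls in the intervals where they were
planted (the MMMUDMMM gene contributes one up-call in 6w-7w and one
down-call in 7w-8w).

The same stages are available from the shell:

```sh
txdyn simulate counts --config cfg.yaml --seed 7 --out sim/
txdyn de --counts sim/counts.tsv --out de.tsv
txdyn trajectory --de de.tsv --out-prefix traj
txdyn ppi --graph string_edges.tsv --min-score 0.400 --out-prefix mods
txdyn hubs --graph module1_edges.tsv --top 5 --seed 7 --out-prefix hubs
txdyn cerna --de de.tsv --interval 3w-4w --mrna-pairs mrna.tsv \
            --lnc-pairs lnc.tsv --circ-pairs circ.tsv --out-prefix net
txdyn enrich --query degs.txt --gmt sets.gmt --out ora.tsv
```

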