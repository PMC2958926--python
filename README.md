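# ebca

Expert-based cooperative analysis toolkit: a formal prior knowledge base of
if-then rules that guides two analysis engines, plus the interpretation and
validation tools that close the iterative expert-elicitation loop.

- **`ebca.rules`** — rule grammar (strictly parenthesised and/or, intervals,
  sets, negation), Kleene three-valued evaluation over records with missing
  cells, first-match partitioning, KB versioning and diffs.
- **`ebca.data`** — mixed-type tables (CSV + YAML/JSON metadata sidecar),
  descriptive summaries with Tukey-fence outlier flags, redundancy
  (correlation) reports, and per-cell stochastic specifications
  (uniform / triangular / point-mass).
- **`ebca.dea`** — Monte-Carlo data envelopment analysis: envelopment-form
  LPs (input/output orientation, constant/variable returns to scale),
  monotone-decreasing transforms for non-standard variables, block-mean
  convergence, four-tier efficiency classification with a binary collapse,
  and scenario enumeration with correlation pruning.
- **`ebca.clbr`** — clustering based on rules: rule classes condensed into
  mass-weighted prototypes, reciprocal-nearest-neighbour Ward agglomeration
  under a block-weighted mixed (numeric + categorical) dissimilarity, and
  Calinski-Harabasz cut selection. Rule classes are guaranteed to land
  intact in one final class.
- **`ebca.interpret`** — per-variable significance screening (ANOVA /
  Kruskal-Wallis / chi-square with BH adjustment), class panel graphs,
  characteristic-cell marking by adjusted standardized residuals, and
  bimodality / variance-inflation inconsistency detection.
- **`ebca.agreement`** — diagnostic metrics with Wilson and log-method CIs,
  Cohen's kappa, two-way consistency ICC with F-based CIs, optimal partition
  alignment, adjusted Rand index.
- **`ebca.synth`** — seeded generators for small-health-area I/O tables
  (with a shipped care-model fixture of uniform bounds), patient tables with
  planted mixed-type clusters, and noisy expert rating matrices.
- **`ebca.pipeline`** — the iterative loop: run an engine under the current
  KB, write artifacts + inconsistency report, repeat with updated KB files;
  agreement comparison against expert labels.

## CLI

```sh
# synthetic fixtures
ebca synth patients --n 300 --seed 1 --out data/
ebca synth sha --seed 1 --out data/

# rule-guided clustering
ebca clbr run --table data/patients.csv --meta data/patients_meta.yaml \
    --kb rules.txt --out run/

# Monte-Carlo DEA
ebca dea run --table data/sha.csv --meta data/sha_meta.yaml \
    --spec data/sha_spec.yaml --annotations ann.yaml --scenario sc.yaml \
    --orientation input --rts constant --seed 1 --out run/

# agreement with expert labels
ebca validate --pred run/pred.csv --ref expert.csv
```

Rule files are plain text, one rule per line:

```
# and/or may not be mixed at one level without parentheses
r1: if ((GAFCLA < 40) or (GAFSOCIAL < 40)) and ((MAXECFOS_A > 15) and (MAXECFOS_B = Every_Day)) then severely-ill
r2: if (INGRESE = WORK) and ((GAFCLA > 70) or (GAFSOCIAL > 70)) then good-condition
```

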