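# symptomnet

Network analysis of binary symptom comorbidity data: estimate an Ising
network over disorder symptoms with nodewise L1-penalized logistic
regression and extended-BIC model selection, detect symptom communities with
walktrap, score bridge symptoms (strength / betweenness / closeness), and
quantify edge-weight accuracy with a nonparametric bootstrap. A calibrated
two-disorder synthetic cohort generator makes every step testable
end-to-end against known ground truth.

## Modules

| module | what it does |
| --- | --- |
| `symptomnet.data_prep` | screening-item selection, CUDIT dichotomization, listwise deletion, zero-variance column exclusion, KR-20 / Spearman–Brown reliability |
| `symptomnet.ising` | {0,1} Ising model: exact enumeration, exact & Gibbs sampling, conditional logits, study-like cohort generator with threshold calibration |
| `symptomnet.elasso` | nodewise L1 logistic regression paths (coordinate descent, warm starts), EBIC selection, AND/OR symmetrization into a weighted network |
| `symptomnet.communities` | walktrap community detection (absolute-weight walks, max-modularity cut) and modularity |
| `symptomnet.bridge` | bridge strength / betweenness / closeness on 1/abs-weight shortest paths |
| `symptomnet.stability` | case-resampling bootstrap: 95% percentile CIs per edge, CI-overlap summary |
| `symptomnet.pipeline` | orchestration, between-disorder edge arithmetic, JSON/CSV/GraphML artifacts, run report |

## Python API

```python
import symptomnet as sn

# synthetic study-like cohort (21 symptoms, two disorder clusters)
frame, truth = sn.generate_cohort(sn.GeneratorConfig(n=1559, seed=0))

data, log = sn.prepare_matrix(frame)          # listwise deletion + exclusions
graph, params = sn.estimate_network(data)     # eLasso, gamma=0.25, AND rule
partition = sn.walktrap(graph)                # symptom communities
table = sn.bridge_table(graph, data.cluster_labels)
summary = sn.bootstrap_edges(data, B=1000, seed=0)
pos, neg, possible, pct = sn.count_between_cluster(graph, data.cluster_labels)
```

## Command line

```bash
symptomnet generate --seed 0 --n 1559 --out cohort.csv --truth-out truth.json
symptomnet estimate --input cohort.csv --out-dir run/
symptomnet communities --adjacency run/adjacency.csv --out run/partition.json
symptomnet bridge --adjacency run/adjacency.csv --out run/bridge.csv
symptomnet bootstrap --input cohort.csv -B 1000 --seed 0 --out run/ci.csv
symptomnet run --generate 0 --out-dir run/      # full pipeline + report.json
symptomnet report --run-dir run/                # recompute report from artifacts
```

`symptomnet run --config config.json` reads a single JSON configuration;
command-line flags override config keys. Exit codes: 2 config error, 3 data
error, 4 estimation error, 5 convergence failure.

## Data formats

Input: respondent-by-symptom CSV, header row of symptom labels (`A1..A11`,
`C1..C10`), values 0/1, empty cells or `NA` for missing. Outputs: labeled
adjacency CSV, edge-list CSV, GraphML, JSON (thresholds, partition,
bootstrap overlap, preparation log, run report), bridge and CI tables as
CSV.
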