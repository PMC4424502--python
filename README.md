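# loopmotif

Discovery of miRNA–TF–gene **closed loop-motifs** from short two-group
expression time series, and their integration into regulatory networks.

## The problem

Transcription factors (TFs) and microRNAs (miRs) regulate gene expression at
the transcriptional and post-transcriptional level, and they frequently act
together: a miRNA targets a TF while both regulate a common gene. When an
insult such as ischemia–reperfusion perturbs a tissue, the perturbation
propagates through exactly these tripartite patterns. `loopmotif` finds
them from data a typical injury time-course study produces:

* mRNA and miRNA expression matrices for sham and injured groups sampled at
  several reperfusion time points (the two platforms need not share the
  same time grid);
* interaction catalogs — miR→gene, miR→TF and TF→gene pair lists from
  target databases, taken as a **union** across catalogs;
* optionally, promoter sequences plus position weight matrices for de-novo
  TF→gene prediction, and gene→biological-process annotations exported from
  enrichment tools.

## The method

For each reperfusion time point:

1. **Differential expression.** Per entity, log2 fold change
   Δ = mean(injured) − mean(sham) with a two-sided Welch *t*-test and
   Benjamini–Hochberg correction; an entity is retained when |Δ| ≥ 1
   (two-fold) and adjusted p ≤ 0.05 (both inclusive). mRNA-platform
   entities are split into TFs and plain mRNAs by a TF identifier list.
2. **Catalog restriction.** Interaction pairs survive only if both
   endpoints are differentially expressed at the time point; each pair is
   typed miR→TF, miR→gene or TF→gene from the endpoint classes.
3. **Matched profiles.** Per-time-point fold-change profiles are aligned on
   the union time grid; the sparser mRNA platform is completed by an
   ordinary-least-squares line v = a + b·t per entity ("temporal
   imputation").
4. **Edge testing.** Every candidate edge is scored with Pearson's
   ρ(X,Y) = cov(X,Y)/(σ_X σ_Y) (two-sided *t* p-value) **and** distance
   correlation (dCor), computed from double-centered pairwise distance
   matrices; dCor = 0 iff the variables are independent. The dCor p-value
   is an exact permutation test when n! is small (all 120 pairings at
   n = 5), Monte-Carlo otherwise. An edge is significant when either test
   has p ≤ 0.05 (an AND rule and a positive-correlation-only filter are
   available).
5. **Loop inference.** Candidates are all triples (m, f, g) with pairs
   m→f, m→g and f→g — the topology where the miR targets a TF and both
   co-regulate a gene; a loop is kept when all three edges are significant.
6. **Networks.** Kept loops merge into an undirected typed graph; node
   degree (distinct neighbors) ranks hub regulators; loop sets from
   different time points or different biological processes are compared by
   Venn-style accounting; networks export to GraphML/TSV.

A synthetic-study generator (`loopmotif.synthetic_data`) emulates the whole
data model with planted loops and known ground truth, so the entire chain
is testable without any external database.

## Worked example

```python
from loopmotif import (SimulationConfig, simulate_study, analyze_timepoint,
                       evaluate_recovery, integrate, degree_ranking, loop_report)

cfg = SimulationConfig(noise_sd=0.3, peak_time_h=168.0, seed=1)
study = simulate_study(cfg)
res = analyze_timepoint(study.mrna, study.mirna, study.catalogs,
                        study.tf_ids, time_h=168.0, seed=2)
print("candidate loops:", res.n_candidates)
print("significant loops:", res.n_loops,
      f"({100*res.fraction_significant:.1f}% of candidates)")
print(loop_report({168.0: res.loops}).to_string(index=False))
sens, fdf = evaluate_recovery(res.loops, study.truth)
print(f"sensitivity={sens:.2f} false_discovery_fraction={fdf:.2f}")
net = integrate(res.loops)
print("network:", net.number_of_nodes(), "nodes,", net.number_of_edges(), "edges")
print(degree_ranking(net, top_k=3)["TF"].to_string(index=False))
```

prints

```
candidate loops: 10
significant loops: 10 (100.0% of candidates)
 time_h  loops  mRNA  TFs  miRs
  168.0     10    10    3    10
sensitivity=1.00 false_discovery_fraction=0.00
network: 23 nodes, 30 edges
 node cls  degree
TF-01  TF       8
TF-02  TF       6
TF-03  TF       6
```

All ten planted loops pass the three-edge correlation filter
(100% of candidates significant), no decoy loop is reported, and the three
planted TFs emerge as the network hubs — TF-01 sits in four loops, hence 4
miR plus 4 gene neighbors and degree 8.

The same stages are scriptable from a shell via the `loopmotif` CLI
(`simulate`, `de`, `scan`, `impute`, `correlate`, `loops`, `network`,
`compare`, `subnets`); `loopmotif --help` lists them.

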