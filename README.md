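# cortexflow

Single-cell time-course analysis of hormone-driven root cortex elongation.

A plant root elongates when cortex cells leaving the meristem switch on a
cell-wall remodeling program under brassinosteroid (BL) control. Given a
UMI count time course (0, 0.5, 1, 2, 4, 8 h of BL treatment) with cell-type
and developmental-stage annotations, cortexflow answers, with tested and
reusable code, the questions that define that analysis:

* **Which cells respond?** A bin-matched cell-wall signature score per
  cell; cortex cells with score ≥ 1 are *responsive cortex cells*.
* **Where do they come from?** Growth-adjusted entropic optimal transport
  between adjacent time points (log-domain unbalanced Sinkhorn:
  ⟨Π,C⟩ − ε·H(Π) + λ₁·KL(Π1∥p) + λ₂·KL(Πᵀ1∥q)), plan composition,
  ancestor/descendant fate probabilities anchored at a 2 h reference, and
  ternary-plot coordinates.
* **Which genes?** Context-resolved pseudobulk NB Wald tests per cell type
  × stage (DEG: fold change > 1.5, FDR < 0.05), probability-weighted
  trajectory DE with a permutation null, and the three-way core set: BL-up
  in the cortex ∩ down in the receptor-null cortex ∩ varying along the
  wild-type cortex trajectory.
* **Which regulators?** Prior-restricted bagged ridge GRNs per (cell type,
  stage, time point) context, TF prioritization by out-degree centrality,
  subnetwork extraction, and edge-overlap comparison between networks.

A fully ground-truthed synthetic generator (`synthetic_data`) emulates the
study design — NB counts, planted induction module, responsive/
non-responsive competence, stage-wise growth rates, and a planted hub-TF
network — so every claim the package makes about itself is checked against
known truth. `docs/methods.md` describes the models and their assumptions.

## Worked example

```python
from cortexflow import (PipelineConfig, run_pipeline)

report = run_pipeline(PipelineConfig(seed=1, outdir="out"))
s = report["stages"]
print("responsive precision/recall:",
      s["signature"]["responsive_precision"],
      s["signature"]["responsive_recall"])
print("ancestor predisposition (transition vs proliferation at t=0):",
      round(s["fate"]["transition_mean_p_responsive"], 3), "vs",
      round(s["fate"]["proliferation_mean_p_responsive"], 3))
print("core-set Jaccard vs truth:",
      s["core_set"]["core_jaccard_vs_truth"])
print("hub TF out-degree rank:", s["grn"]["hub_rank_by_out_degree"])
```

prints, for seed 1:

```
responsive precision/recall: 1.0 1.0
ancestor predisposition (transition vs proliferation at t=0): 0.789 vs 0.022
core-set Jaccard vs truth: 1.0
hub TF out-degree rank: 1
```

meaning: at 2 h every planted induction-competent cortex cell — and no
other cell — is classified responsive; transition-domain cortex cells at
t = 0 are strongly predisposed toward the responsive fate while
proliferation-domain cells are not; the three-way intersection recovers
exactly the planted core gene set; and the planted hub transcription factor
tops the out-degree ranking of the cortex-elongation 2 h network. The same
stages can be run individually (`simulate_timecourse`, `score_cells`,
`sinkhorn_unbalanced`, `fate_probabilities`, `de_test`, `fit_grn`, …) on
your own matrices; 10x Matrix Market triplet directories, metadata TSVs and
GMT gene-set files are the on-disk formats. A thin CLI wraps the same
library: `cortexflow simulate --outdir data`, `cortexflow run-all --seed 1
--outdir out`.

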