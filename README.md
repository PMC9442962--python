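# modalfuse

Single-cell RNA sequencing quantifies two coupled views of every cell's
transcriptome: mature (spliced) mRNA and nascent (unspliced) pre-mRNA.
Their per-gene relationship carries temporal information — RNA velocity,
`v = βu − γs`, predicts where a cell's expression state is heading.
`modalfuse` treats these paired measurements as two *modalities over the
same cells* and asks a practical question for analysts: **does integrating
them produce better cell graphs than the conventional spliced-only
analysis**, as judged by two downstream tasks — trajectory inference and
semi-supervised cell-state classification?

The package provides:

* a typed container (`ModalityBundle`) for paired cells × genes layers
  (spliced, unspliced, k-NN moments, velocity) with MatrixMarket, loom and
  h5ad readers/writers;
* a simulator of paired counts with known splicing kinetics
  (`du/dt = α − βu`, `ds/dt = βu − γs` along a milestone trajectory),
  capture-efficiency noise, batch effects and condition labels — every
  downstream stage is testable against exact ground truth;
* preprocessing (joint QC, size-factor normalization, highly-variable-gene
  selection, geometric sketching) and joint batch correction of both
  layers via the summed-log / spliced-ratio decomposition
  `M = log(S+U+1)`, `R = S/(S+U)`, `S_c = exp(M_c∘R) − 1`,
  `U_c = exp(M_c∘(1−R)) − 1`, with kBET, LISI and phase-space-preservation
  quality metrics;
* k-NN moment smoothing and a steady-state velocity estimator
  (`γ̂` from the extreme quantiles of the phase plot, `V = Mu − γ̂ Ms`);
* **ten integration strategies**, each emitting a k-NN graph (k = 10) over
  the cells: spliced-only baseline, concatenation `[X¹‖X²]`, element-wise
  sum, Markov blending of expression and velocity transition operators
  `P = λP_v + (1−λ)P_s`, principal-vector subspace alignment (plus its
  consensus variant), similarity network fusion with a Laplacian spectral
  embedding, Grassmann joint embedding
  `L_mod = Σ L_n^m − α Σ U^m U^{m⊤}`, alternating diffusion
  `P_j = P_1^{t_1} P_2^{t_2}` with spectral-entropy time selection, a
  shared-factor model `X^m = Z W^{m⊤} + ε^m` fitted by alternating least
  squares, and per-cell weighted nearest neighbors;
* evaluation: PAGA-like cluster connectivity + diffusion pseudotime →
  predicted trajectories, scored against a reference by the Spearman
  correlation of geodesic cell distances (`C_corr`), the correlation of
  random-forest feature-importance profiles (`F_corr`) and their harmonic
  mean `TI_corr = 2·C_corr·F_corr/(C_corr+F_corr)`; label propagation
  `y′ ← D⁻¹W y′` with clamped training labels, scored by F1, balanced
  accuracy and rank-based AUC; cross-dataset min–max-scaled aggregate
  ranking.

## Worked example

```python
import numpy as np
from modalfuse.simulate import complementary_signal_bundle
from modalfuse.benchmark import BenchmarkConfig, run_benchmark
from modalfuse.class_eval import aggregate_scores

# perturbation dataset whose class signal sits mostly in the unspliced layer
bundle = complementary_signal_bundle(seed=0)
config = BenchmarkConfig(
    methods=["unintegrated", "concat", "sum"],
    tasks=["classification"], seeds=[0], n_replicates=5,
)
table = run_benchmark(config, bundle)
print(table.groupby("method")["value"].median().round(3))
print(aggregate_scores(table)[["method", "metric", "score", "rank"]])
```

Output:

```
method
concat          0.915
sum             0.940
unintegrated    0.724
Name: value, dtype: float64
         method metric     score  rank
0           sum    AUC  1.000000     1
1        concat    AUC  0.902778     2
2  unintegrated    AUC  0.000000     3
3           sum     F1  1.000000     1
4        concat     F1  0.914869     2
5  unintegrated     F1  0.000000     3
6           sum  acc_b  1.000000     1
7        concat  acc_b  0.938776     2
8  unintegrated  acc_b  0.000000     3
```

The medians are label-propagation scores per strategy (AUC, F1 and
balanced accuracy pooled): because half of the perturbation response lives
in the nascent transcripts, the spliced-only baseline reaches a median of only 0.72 while either integration recovers ~0.92-0.94; the aggregate view min–max
scales the medians and ranks the methods.

The same pipeline runs from the shell:

```bash
modalfuse simulate --out data/ --seed 1
modalfuse preprocess --in data/ --out prep/
modalfuse benchmark --in prep/ --config bench.yaml --out-dir results/
```

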