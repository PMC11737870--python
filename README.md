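# splenotrain

Transcriptomic analysis of **trained immunity** in the spleen. After a
priming exposure such as intraperitoneal BCG, innate immune cells acquire an
antigen-agnostic functional memory; its transcriptional fingerprint is a
STAT1-driven interferon program (Gbp2, Cxcl9, Ly6a, Irg1, …) appearing in
specific myeloid subsets and persisting for weeks. This package provides the
downstream analyses such a study needs, as a tested, reusable pipeline:

* **Single cell** — UMI-matrix QC (cells < 200 UMIs removed), median
  library-size normalization with log10 transform, mean–CV noise-model
  selection of the 425 most variable genes, PCA (40 PCs), Euclidean KNN
  graph (k = 20), Louvain community detection, and marker-panel cluster
  annotation (default mouse splenic myeloid panel included).
* **Bulk kinetics** — time courses at days 3/14/30/45/60 post vaccination
  are normalized, log2-transformed and floored; for each gene *g* the
  training statistic is the difference of areas under the replicate-averaged
  trajectories,

  ```
  D_g = ∫ trained_g(t) dt − ∫ control_g(t) dt        [log2·days]
  ```

  (trapezoidal rule over observed days). Fitting a normal N(μ̂, σ̂²) to D
  across all genes gives an empirical null; genes with D > μ̂ + 3σ̂ are
  called **up-regulated due to training**.
* **Differential expression** — two-sided t-tests (pooled variance) and
  one-way ANOVA per gene with Benjamini–Hochberg FDR and fold-change
  filters, plus multi-contrast unions.
* **Enrichment** — hypergeometric over-representation of DEG lists in GMT
  gene-set collections.
* **Synthetic data** — generators for both modalities with planted ground
  truth (cell types, a condition-restricted training program, responsive
  genes with early-transient / sustained / delayed profiles), so the whole
  pipeline is testable end to end without any downloads.

See `docs/methods.md` for models, parameter defaults and numerical choices.

## Worked example

Simulate a vaccination time course (5000 genes, 5% training-responsive,
3 replicates per condition × day) and call training genes:

```python
import splenotrain as st

sim = st.simulate_bulk_timecourse(st.BulkSimSpec(rng_seed=1))
avg = st.average_replicates(sim.timecourse)
D = st.integral_difference(avg, treated="trained", control="control")
calls = st.call_training_genes(D, sd_multiplier=3.0)
print(f"null fit: mean={calls.null_mean:.2f}, sd={calls.null_sd:.2f} log2*days")
print(f"threshold: {calls.threshold:.2f}; genes called up-regulated: {len(calls.upregulated)}")
```

prints

```
null fit: mean=4.60, sd=23.41 log2*days
threshold: 74.84; genes called up-regulated: 94
sustained planted genes recovered: 83/83
```

(the third line comes from comparing `calls.upregulated` with
`sim.truth.responsive_genes`). All 83 planted *sustained* responders are
recovered; *early-transient* and *delayed* profiles integrate to smaller
areas and mostly sit below the 3-SD threshold — the area statistic is
deliberately biased toward persistent induction.

The same flows are available from a shell:

```sh
splenotrain simulate-sc  --seed 1 --out-dir sim_sc
splenotrain sc-cluster   --counts sim_sc/counts.mtx --markers sim_sc/truth.markers.tsv --out-dir clust
splenotrain simulate-bulk --seed 1 --out-dir sim_bulk
splenotrain kinetics     --counts sim_bulk/counts.tsv --metadata sim_bulk/metadata.tsv --out-dir kin
```

Every run writes a `manifest.json` with the resolved configuration and input
checksums.

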