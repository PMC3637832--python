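# gmmfilt — adaptive gene filtering by Gaussian mixture decomposition

In two-group expression studies (bulk microarray or anything producing an
RMA-style log2 genes × samples matrix) the number of genes dwarfs the
number of samples, and multiple-testing correction at a fixed FDR
constraint costs sensitivity. A standard remedy is *nonspecific
filtering*: remove genes that look non-informative — low mean or low
variance across **all** samples, never using the class labels — before
testing, so the correction is paid only over the retained pool. The open
question is *how much* to remove: fixed rules (e.g. drop the lowest 50%)
ignore that datasets differ in their non-informative fraction.

`gmmfilt` implements an adaptive answer. The per-gene filter signal
(mean of log2 expression `S`, log variance on the original scale `V`, or
log variance on the log2 scale `LV`) is decomposed into a mixture of K
Gaussian components

    f(x) = Σ_k α_k 𝒩(x; μ_k, σ_k),   Σ_k α_k = 1,

fitted by EM, with K chosen by minimizing BIC = −2 logL + (3K−1) ln N
over K = 1…15. Each gene is MAP-assigned to a component, and whole
components are then dropped: either everything below the top three
components by mean (**top3**), or the lower of two clusters obtained by
2-means clustering of the component triples (μ_k, σ_k, α_k)
(**k-means**). The filter threshold thus adapts to the observed signal
distribution. Downstream, the retained genes get an equal-variance
two-sample t-test and Storey–Tibshirani q-value correction, with calls at
q ≤ 0.05. A simulation benchmark with known DEG truth (independent or
clumpy-dependent genes) and ROC/F1/AUC scoring machinery is included for
method comparison.

See `docs/methods.md` for the full model, defaults, and limitations.

## Worked example

Simulate a clumpy-dependence benchmark dataset (10,000 genes, two groups
of five, 15% true DEGs) and compare no filtering, the fixed 50% mean
filter, and the adaptive mean filter:

```python
import gmmfilt as gf
from gmmfilt.simulate import labels_for

ds = gf.simulate(gf.SimConfig(n_genes=10_000, prop_eeg=0.85,
                              dependence="clumpy", seed=7))
labels = labels_for(ds)
for name in ("NF", "S_50", "AS"):
    cfg = gf.standard_methods([name])[0]
    mask, deg, report = gf.run_pipeline(ds.matrix, labels, cfg)
    met = gf.evaluate(deg.p_values, ds.truth, mask, deg)
    print(f"{name:5s} K={report.get('K','-'):>2} removed={mask.removed_fraction:5.1%} "
          f"rejections={deg.n_rejections:4d} sens@5%FDR={met.sensitivity_at_fdr:5.1f}% "
          f"F1={met.f1:.3f} AUC={met.auc:.2f}")
```

prints

```
NF    K= - removed= 0.0% rejections= 807 sens@5%FDR= 54.5% F1=0.693 AUC=12.19
S_50  K= - removed=50.0% rejections=1017 sens@5%FDR= 66.0% F1=0.779 AUC=14.53
AS    K= 2 removed=77.7% rejections=1176 sens@5%FDR= 69.7% F1=0.804 AUC=14.73
```

Unfiltered testing finds 807 DEGs at the 5% FDR constraint and recovers
54.5% of the 1,500 true DEGs at 5% realized FDR. The fixed filter removes
exactly half the genes and improves both. The adaptive filter decomposes
the mean signal into K=2 components, recognizes that ~78% of genes sit in
the low (unexpressed) component, removes them, and does best on every
index — its threshold was chosen by the data, not by convention.

The same pipeline runs from the shell on your own files:

```sh
gmmfilt filter --matrix expr.tsv --method S --rule kmeans2 --seed 17 --out mask.tsv
gmmfilt degs --matrix expr.tsv --labels labels.tsv --mask mask.tsv --out degs.tsv
gmmfilt benchmark --methods NF,S_50,AS --n-genes 10000 --n-replicates 20 --out bench.csv
```

Matrices are TSV/CSV (first column gene ids, header row sample ids) or
GCT; labels are a two-column TSV (sample id, group).

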