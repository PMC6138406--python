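# elmcc

Molecular subtyping of tumors from bulk expression profiles by
**random-projection dimension reduction** — an extreme learning machine
(ELM) with a deliberately tiny hidden layer — followed by k-means
clustering, with the classical consensus-clustering workflow as a
baseline and a full statistical evaluation layer (gap statistic,
silhouette widths, SigClust, Kaplan–Meier / log-rank survival
association, cross-cohort ELM classification).

It is aimed at computational biologists who have an already-normalized
genes × samples expression matrix (log2-TPM RNA-Seq or microarray
intensities) plus, optionally, a clinical table, and want reproducible
subtype calls with honest significance assessment.

## The method in brief

Given expression vectors x_j ∈ ℝⁿ (one per sample) that survive a
median-absolute-deviation variability filter, draw random weights
w_i ~ U(−1, 1)ⁿ and biases b_i, i = 1..Ñ (default Ñ = 3), and form the
feature matrix

    F[j, i] = w_i · x_j + b_i          (N × Ñ)

F is a random projection of the cohort into Ñ dimensions; k-means on F
yields the subtypes, with k chosen by the gap statistic

    Gap(k) = (1/B) Σ_b log W*_kb − log W_k .

The ELM's output weights β = H⁺T (Moore–Penrose pseudoinverse; targets =
inputs for regression, one-hot subtype indicators with a hard-limit
hidden layer for classification) let the same machinery train a
classifier on one cohort and project subtype calls onto an independent
one. Subtype quality is quantified by average silhouette width, pairwise
SigClust Monte-Carlo tests, and log-rank association with survival.
See `docs/methods.md` for the full model description and design choices.

## Worked example

Everything below runs from scratch in a few seconds on a synthetic
cohort with a known answer (4 subtypes, 200 samples, signature genes
shifted by 4 noise-SDs, subtype-linked exponential survival):

```bash
elmcc simulate   --out-dir demo --seed 5 --n-samples 200
elmcc preprocess --expr demo/expression.tsv --out demo/filtered.tsv --mad-threshold 0.5
elmcc features   --expr demo/filtered.tsv --out demo/features.tsv --n-hidden 3 --seed 5
elmcc gapstat    --features demo/features.tsv --out demo/gap.tsv --k-range 2:6 --seed 5
elmcc cluster    --features demo/features.tsv --out demo/assignment.tsv --k 4 --seed 5
elmcc survival   --clinical demo/clinical.tsv --assignment demo/assignment.tsv --out demo/survival.json
elmcc concordance --assignment demo/assignment.tsv --reference demo/truth.tsv --out demo/concordance.json
```

which prints:

```
simulated 1200 genes x 200 samples, k_true=4 -> demo
kept 200 / 1200 genes (MAD > 0.5) -> demo/filtered.tsv
wrote 200 x 3 feature matrix -> demo/features.tsv
gap statistic chose k=4 (global_max) -> demo/gap.tsv
assigned 200 samples to k=4 classes -> demo/assignment.tsv
log-rank chi2=49.84 (df=3), p=8.623e-11 -> demo/survival.json
ARI = 0.9601 -> demo/concordance.json
```

Reading the numbers: the MAD filter keeps exactly the 200 subtype
signature genes and discards the 1000 low-variability fillers; the gap
statistic recovers the true k = 4 from the 3-D feature space; the
clustering agrees with the generating labels (adjusted Rand index 0.96);
and the recovered subtypes separate survival strongly (log-rank
χ² = 49.8 on 3 df). Because the features are a *random* projection,
results depend on the weight seed — some seeds fuse two subtypes (see
the limitations section of `docs/methods.md`); inspect the 3-D scatter
from `elmcc report` before trusting any single projection.

The same steps work on real data: point `--expr` at any TSV with sample
IDs in the header and gene symbols in the first column (use
`--rsem` during preprocessing to convert RSEM scaled estimates to
log2-TPM), and `elmcc consensus` / `elmcc sigclust` / `elmcc classify`
cover the baseline comparison, significance testing, and cross-cohort
validation.

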