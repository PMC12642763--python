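# whitemap

De-individualization pipeline for parcellated task-fMRI time series.

Given parent scans (region × time BOLD matrices with labeled task blocks),
`whitemap` supports three ways of comparing the task scans extracted from
them:

- **Raw Frobenius distance** between task scans — dominated by per-subject,
  per-region mean offsets, so it groups scans by *individual*;
- **Bures distance** between Pearson-correlation functional connectomes —
  sensitive to subject-specific inter-region correlation structure, so it
  also groups scans by *individual* while ignoring mean/scale differences;
- **dM dissimilarity** — each parent scan is row de-meaned and Mahalanobis
  whitened against its own covariance *before* task extraction, then task
  scans are compared with the Frobenius distance. This removes both sources
  of individual-identifying structure and groups scans by *task*. (dM can
  break the triangle inequality; it is a dissimilarity, not a metric.)

Pairwise distances are embedded with Isomap (kNN graph → graph geodesics →
double-centered Gram matrix → spectral coordinates; an optional seeded UMAP
backend delegates to `umap-learn`), clustered with k-means, and scored
against subject/task labels with the adjusted Rand score (ARS) and adjusted
mutual information (AMI).

A synthetic-cohort generator (`whitemap.synthetic_data`) produces parent
scans with controllable subject mean offsets, subject correlation structure
and shared task activation patterns, plus a task-order-permuted "retest"
session, so the full pipeline is testable without any imaging data.

## CLI

Conventions everywhere: matrices are rows = regions, columns = time; time
indices are 0-based; annotation intervals are half-open `[start, end)` and
listed as JSON `{"start": ..., "end": ..., "label": ...}` records. Cue and
rest periods are simply absent from the interval list.

```sh
# generate a synthetic cohort (matrix TSVs + annotation JSONs + manifest)
whitemap simulate --subjects 20 --tasks 8 --regions 30 --tp-per-task 60 \
    --seed 0 --session test --out cohort/

# pairwise distances over all task scans in the manifest
whitemap distances --manifest cohort/manifest.tsv --metric dm --out dm.tsv
# metrics: frobenius_raw | bures | dm   (--ridge adds covariance ridging)

# Isomap (or --backend umap) embedding of a distance matrix
whitemap embed --dist dm.tsv --k 10 --dim 20 --seed 0 --out coords.tsv

# k-means + ARS/AMI against subject and task labels
whitemap evaluate --coords coords.tsv --labels cohort/labels.tsv --seed 0
```

## Package layout

| module | contents |
| --- | --- |
| `whitemap.io_core` | `ParentScan`/`TaskScan`/`TaskAnnotation`/`DistanceMatrix` types, text I/O, task extraction |
| `whitemap.whitening` | row de-meaning, row covariance, symmetric inverse-square-root whitening |
| `whitemap.geometry` | connectomes, `psd_sqrt`, fidelity, Bures/Frobenius/dM distances, pairwise assembly |
| `whitemap.embedding` | kNN graph, graph geodesics, Isomap embedding, optional UMAP backend |
| `whitemap.evaluation` | k-means wrapper, ARS, AMI (hypergeometric expected-MI), score tables |
| `whitemap.synthetic_data` | seeded cohort generator and retest sessions |
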