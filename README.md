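# mitoscreen

Analysis toolkit for pooled single-cell CRISPR screens that read out
mitochondrial genetics: per-cell guide-RNA assignment, mitochondrial
heteroplasmy calling from linked SNVs, relative mtDNA copy-number estimation
from coverage, and a simulation/statistical framework for deciding whether
changes in heteroplasmy **variance** are real biology or a read-depth
sampling bottleneck.

## The problem

In heteroplasmic cells, a pathogenic mtDNA variant is carried by only a
fraction *h* of the cell's mitochondrial genomes. Single-cell multiome
screens can perturb nuclear genes and read out, per cell: the guide RNA
(from the transcriptome), heteroplasmy and mtDNA copy number (from ATAC-seq
reads on the mitochondrial genome). But sequencing samples only *n* reads of
the ~10³ mtDNA molecules per cell, so the observed heteroplasmy is a
binomial draw around the truth:

    Var(ĥ) = Var(h) + E[h(1-h)] · E[1/n]

A perturbation that depletes mtDNA copy number also reduces read depth *n*,
inflating the observed variance with no change in the underlying
heteroplasmy distribution. Deciding whether a perturbed group's variance
needs a biological explanation therefore requires depth-aware nulls, which
this package provides:

* **Guide assignment** — MAPQ ≥ 30 filter, ≥ 2 deduplicated reads per cell,
  and a strict > 2/3 dominance rule for the most abundant guide.
* **Heteroplasmy calling** — pooling ref/alt counts across linked SNVs
  (cis sites contribute alt counts, trans sites ref counts), with
  correlation-based cis/trans inference and long-read linkage checks.
* **Copy number** — mean deduplicated mtDNA coverage per cell (deliberately
  not normalized to total ATAC signal), Welch t-tests between groups.
* **Bottleneck null** — for a perturbed group, control cells are resampled
  without replacement, assigned depths drawn from the perturbed group, and
  re-observed through Binomial(depth, h); 5,000 such simulations give a
  two-sided empirical p for the observed variance.
* **Depth-variance model** — equal-count depth bins and quantile regression
  (exact pinball-loss fits at the 5th/95th percentiles) of
  Variance = β₀ + β₁/depth, with bootstrap confidence bands.
* **Response statistics** — per-gene OLS residualization on mtDNA copy
  number, PCA of top-variable residuals, rank-based PC1 group tests,
  chi-squared cell-cycle phase composition contrasts.
* **Synthetic cohorts** — a fully seeded generator of guide reads, allele
  counts, coverage and expression tables with known ground truth.

## Worked example

```python
import numpy as np
from mitoscreen import (generate_cohort, combined_heteroplasmy,
                        simulate_bottleneck_null, holm_adjust)

cohort = generate_cohort(n_cells=3000, seed=55)   # Tfam/Polg/Opa1 depleted
calls = combined_heteroplasmy(cohort.allele_counts, cohort.panel)
merged = calls.merge(cohort.truth[["cell_barcode", "target_gene"]],
                     on="cell_barcode")
control = merged[~merged.target_gene.isin(["Tfam", "Polg", "Opa1"])]

pvals = []
for gene in ("Tfam", "Polg", "Opa1"):
    kd = merged[merged.target_gene == gene]
    null = simulate_bottleneck_null(
        control.heteroplasmy.to_numpy(), kd.combined_depth.to_numpy(),
        n_kd=len(kd), observed_variance=float(kd.heteroplasmy.var(ddof=1)),
        n_sims=5000, seed=56)
    pvals.append(null.p_empirical)
print(dict(zip(("Tfam", "Polg", "Opa1"), np.round(holm_adjust(pvals), 3))))
```

Output (`python examples/04_bottleneck_variance.py` prints the full table):

```
{'Tfam': 0.585, 'Polg': 0.18, 'Opa1': 0.963}
```

All three depleted groups were simulated with an *unchanged* true
heteroplasmy distribution; their raw variances are elevated (e.g. Tfam
0.0159 vs the control's 0.0131) yet all adjusted p-values are
non-significant — the inflation is fully explained by the depth-matched
binomial null. Rerunning with `het_sd_inflation={"Tfam": 2.0}` makes the
Tfam p-value collapse below 0.001: the null distinguishes genuine variance
changes from bottleneck artifacts.

The `examples/` directory has one short script per capability; each prints
the numbers it computes and a line on what they mean. A thin CLI wraps the
same functions:

```bash
mitoscreen simulate-cohort --cells 3000 --seed 7 --outdir sim/
mitoscreen assign-guides --reads sim/guide_reads.tsv --out assign.tsv
mitoscreen call-heteroplasmy --counts sim/allele_counts.tsv \
    --panel sim/panel.tsv --min-depth 20 --out calls.tsv
mitoscreen run-all --cells 3000 --seed 7 --outdir run/
```

## Documentation

`docs/methods.md` describes the models, their assumptions, parameter
defaults, the synthetic-data generator's scope, and numerical choices.
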