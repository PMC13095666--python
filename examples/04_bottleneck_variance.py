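"""Is a perturbed group's heteroplasmy variance explained by its read depth?

Sequencing at reduced depth is a sampling bottleneck that inflates observed
heteroplasmy variance even when the underlying biology is unchanged. The
depth-matched binomial resampling null answers whether an observed variance
needs any explanation beyond depth.
"""

import numpy as np

from mitoscreen import (
    combined_heteroplasmy,
    expected_sampled_variance,
    generate_cohort,
    holm_adjust,
    simulate_bottleneck_null,
)

# depleted group with UNCHANGED true heteroplasmy distribution
cohort = generate_cohort(n_cells=3000, seed=55)
calls = combined_heteroplasmy(cohort.allele_counts, cohort.panel)
merged = calls.merge(cohort.truth[["cell_barcode", "target_gene"]], on="cell_barcode")

control = merged[~merged["target_gene"].isin(["Tfam", "Polg", "Opa1"])]
pvals, rows = [], []
for gene in ("Tfam", "Polg", "Opa1"):
    kd = merged[merged["target_gene"] == gene]
    null = simulate_bottleneck_null(
        control["heteroplasmy"].to_numpy(),
        kd["combined_depth"].to_numpy(),
        n_kd=len(kd),
        observed_variance=float(kd["heteroplasmy"].var(ddof=1)),
        n_sims=5000,
        seed=56,
    )
    closed_form = expected_sampled_variance(
        float(control["heteroplasmy"].var(ddof=1)),
        float(control["heteroplasmy"].mean()),
        kd["combined_depth"].to_numpy(),
    )
    pvals.append(null.p_empirical)
    rows.append((gene, len(kd), null.observed_variance,
                 float(null.null_variances.mean()), closed_form))

adjusted = holm_adjust(pvals)
print(f"{'group':>6} {'cells':>5} {'observed var':>12} {'null mean':>10} "
      f"{'closed form':>11} {'adj. p':>7}")
for (gene, n, obs, null_mean, cf), p in zip(rows, adjusted):
    print(f"{gene:>6} {n:>5} {obs:>12.5f} {null_mean:>10.5f} {cf:>11.5f} {p:>7.3f}")

# all three groups were simulated with the same true heteroplasmy s.d., so
# their elevated variances are fully explained by depth: adjusted p ~ 1
print("\nVariances sit inside the depth-matched null: the apparent variance")
print("inflation in depleted groups is a sequencing bottleneck, not biology.")
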