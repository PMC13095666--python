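"""Synthetic perturbation-screen cohorts with known ground truth.

Every pipeline stage consumes plain tables, so a fully synthetic cohort —
guide reads, per-site allele counts, coverage profiles, metadata and a truth
table — makes the whole analysis testable without any external data. The
generator emulates the structure the analysis assumes:

* true heteroplasmy ~ Normal(0.582, 0.113) clipped to [0, 1], identical in
  expectation across perturbation groups (perturbations deplete mtDNA, not
  heteroplasmy);
* per-cell mtDNA copy number = 1,750 x a per-gene depletion factor x
  lognormal noise, rising linearly through cell-cycle pseudotime (relaxed
  replication);
* read depth proportional to copy number: per-base coverage averages ~60x
  for undepleted cells with heavy lognormal dispersion, and the combined
  depth over the seven-SNV panel is the per-base coverage times the panel
  size (so depleted groups land in the low-depth, bottlenecked regime);
* per-site alternate counts ~ Binomial(site depth, oriented heteroplasmy);
* guide reads per cell ~ Poisson, plus ambient reads of random guides and a
  controllable sub-threshold MAPQ fraction.

All randomness flows from one seed through named substreams, so individual
stages regenerate independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .guides import GuideReadRecord
from .heteroplasmy import (
    MOUSE_MT_GENOME_LENGTH,
    HaplotypePanel,
    VariantSite,
)

__all__ = [
    "default_panel",
    "default_guide_library",
    "DEFAULT_DEPLETION_MAP",
    "Cohort",
    "generate_cohort",
    "generate_guide_reads",
    "generate_longreads",
    "generate_expression",
]

#: the seven linked heteroplasmic SNVs of the mouse tRNA-Ala model:
#: m.5024C>T (focal, pathogenic) and m.13715C>T share one haplotype (cis);
#: the remaining five mark the opposing haplotype (trans).
_PANEL_SITES = (
    VariantSite(5024, "C", "T", "cis"),
    VariantSite(13715, "C", "T", "cis"),
    VariantSite(1781, "C", "T", "trans"),
    VariantSite(1866, "A", "G", "trans"),
    VariantSite(3009, "G", "T", "trans"),
    VariantSite(3823, "T", "C", "trans"),
    VariantSite(13614, "C", "T", "trans"),
)

TARGET_GENES = (
    "Akap1", "Atg5", "Dnm1l", "Mtfp1", "Nnt", "Oma1", "Opa1",
    "Pink1", "Polg", "Ppargc1a", "Prkn", "Snx9", "Tfam",
)
CONTROL_GENES = ("Ctrl1", "Ctrl2", "Ctrl3", "Ctrl4", "Ctrl5", "Ctrl6")

#: mtDNA-depletion factors for the three maintenance genes whose knockdown
#: reduces copy number (most severe for Tfam, then Polg, then Opa1).
DEFAULT_DEPLETION_MAP: dict[str, float] = {"Tfam": 0.2, "Polg": 0.3, "Opa1": 0.4}

#: per-base coverage (x) for an undepleted cell at the base copy number
DEFAULT_COVERAGE_PER_CN = 60.0 / 1750.0

#: fixed multinomial weights splitting combined depth across the 7 sites
_SITE_WEIGHTS = np.array([1.1, 1.0, 0.95, 1.05, 0.9, 1.0, 1.0])
_SITE_WEIGHTS = _SITE_WEIGHTS / _SITE_WEIGHTS.sum()


def default_panel() -> HaplotypePanel:
    """Seven-SNV haplotype panel with the m.5024 site as focal."""
    return HaplotypePanel(_PANEL_SITES, focal_position=5024,
                          genome_length=MOUSE_MT_GENOME_LENGTH)


def default_guide_library() -> dict[str, str]:
    """60-guide library: 3 guides per gene for 13 targets + 6 controls, 3 NT."""
    lib: dict[str, str] = {}
    for gene in TARGET_GENES + CONTROL_GENES:
        for i in range(1, 4):
            lib[f"{gene}-g{i}"] = gene
    for i in range(1, 4):
        lib[f"NT-g{i}"] = "NT"
    return lib


@dataclass(frozen=True)
class Cohort:
    allele_counts: pd.DataFrame   # cell_barcode, position, ref_count, alt_count
    coverage: pd.DataFrame        # cell_barcode, total_mt_bases, nuclear_fragments, mean_coverage
    metadata: pd.DataFrame        # cell_barcode, guide_id, target_gene, phase, pseudotime
    truth: pd.DataFrame           # + true_h, true_cn, depletion_factor, isr_activation
    panel: HaplotypePanel


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _phase_from_pseudotime(t: np.ndarray) -> np.ndarray:
    """G1 for the first half-turn, S next ~30%, G2M the rest."""
    phase = np.full(t.shape, "G2M", dtype=object)
    phase[t < np.pi] = "G1"
    phase[(t >= np.pi) & (t < 1.6 * np.pi)] = "S"
    return phase


def generate_cohort(
    n_cells: int,
    guide_library: Optional[Mapping[str, str]] = None,
    depletion_map: Optional[Mapping[str, float]] = None,
    het_mean: float = 0.582,
    het_sd: float = 0.113,
    base_cn: int = 1750,
    panel: Optional[HaplotypePanel] = None,
    coverage_per_cn: float = DEFAULT_COVERAGE_PER_CN,
    cn_noise_sigma: float = 0.25,
    coverage_dispersion: float = 0.6,
    het_sd_inflation: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> Cohort:
    """Generate a synthetic screen cohort with known per-cell ground truth.

    Guides are drawn uniformly from the library; genes in ``depletion_map``
    have their copy number multiplied by the given factor. ``het_sd_inflation``
    optionally multiplies the true heteroplasmy s.d. for chosen target genes
    (to inject genuine variance changes on top of the depth bottleneck).
    """
    if guide_library is None:
        guide_library = default_guide_library()
    if depletion_map is None:
        depletion_map = DEFAULT_DEPLETION_MAP
    if panel is None:
        panel = default_panel()
    genes = set(guide_library.values())
    unknown = set(depletion_map) - genes
    if unknown:
        raise ValueError(f"depletion_map genes not in guide library: {sorted(unknown)}")
    if het_sd_inflation:
        unknown = set(het_sd_inflation) - genes
        if unknown:
            raise ValueError(f"het_sd_inflation genes not in guide library: {sorted(unknown)}")

    rng_guide, rng_cycle, rng_cn, rng_het, rng_depth, rng_cov = _substreams(seed, 6)

    barcodes = np.array([f"CELL{i:06d}" for i in range(n_cells)])
    guide_ids = np.array(sorted(guide_library))
    guides = rng_guide.choice(guide_ids, size=n_cells)
    targets = np.array([guide_library[g] for g in guides])
    depletion = np.array([depletion_map.get(t, 1.0) for t in targets])

    pseudotime = rng_cycle.uniform(0.0, 2.0 * np.pi, size=n_cells)
    phase = _phase_from_pseudotime(pseudotime)
    # relaxed replication: copy number rises linearly through the cycle
    cycle_factor = 0.75 + 0.5 * pseudotime / (2.0 * np.pi)

    cn_noise = rng_cn.lognormal(-cn_noise_sigma**2 / 2.0, cn_noise_sigma, size=n_cells)
    true_cn = base_cn * depletion * cycle_factor * cn_noise

    sd = np.full(n_cells, het_sd)
    if het_sd_inflation:
        for gene, factor in het_sd_inflation.items():
            sd[targets == gene] = het_sd * factor
    true_h = np.clip(rng_het.normal(het_mean, sd), 0.0, 1.0)

    cov_noise = rng_cov.lognormal(-coverage_dispersion**2 / 2.0, coverage_dispersion,
                                  size=n_cells)
    per_base_cov = true_cn * coverage_per_cn * cov_noise
    total_mt_bases = np.rint(per_base_cov * panel.genome_length).astype(np.int64)
    nuclear_fragments = rng_cov.poisson(20_000 * cycle_factor)

    n_sites = len(panel.sites)
    combined_depth = rng_depth.poisson(n_sites * per_base_cov)
    weights = _SITE_WEIGHTS if n_sites == len(_SITE_WEIGHTS) else np.full(n_sites, 1.0 / n_sites)
    site_depths = rng_depth.multinomial(combined_depth, weights)
    positions = np.array([s.position for s in panel.sites])
    is_cis = np.array([s.orientation == "cis" for s in panel.sites])
    alt_prob = np.where(is_cis[None, :], true_h[:, None], 1.0 - true_h[:, None])
    alt = rng_depth.binomial(site_depths, alt_prob)
    ref = site_depths - alt

    allele_counts = pd.DataFrame(
        {
            "cell_barcode": np.repeat(barcodes, n_sites),
            "position": np.tile(positions, n_cells),
            "ref_count": ref.ravel(),
            "alt_count": alt.ravel(),
        }
    )
    coverage = pd.DataFrame(
        {
            "cell_barcode": barcodes,
            "total_mt_bases": total_mt_bases,
            "nuclear_fragments": nuclear_fragments,
            "mean_coverage": total_mt_bases / panel.genome_length,
        }
    )
    metadata = pd.DataFrame(
        {
            "cell_barcode": barcodes,
            "guide_id": guides,
            "target_gene": targets,
            "phase": phase,
            "pseudotime": pseudotime,
        }
    )
    truth = metadata.assign(
        true_h=true_h,
        true_cn=true_cn,
        depletion_factor=depletion,
        isr_activation=1.0 - depletion,
    )
    return Cohort(allele_counts, coverage, metadata, truth, panel)


def generate_guide_reads(
    metadata: pd.DataFrame,
    reads_per_cell_mean: float = 5.0,
    ambient_rate: float = 0.1,
    mapq_distribution: Optional[Sequence[int]] = None,
    guide_library: Optional[Mapping[str, str]] = None,
    seed: int = 0,
) -> list[GuideReadRecord]:
    """Barcoded guide reads for each cell, with ambient contamination.

    Each cell receives Poisson(mean * (1 - ambient_rate)) reads of its true
    guide plus Poisson(mean * ambient_rate) ambient reads with uniformly
    random guide identity. MAPQ values are drawn uniformly from
    ``mapq_distribution`` (default: 90% at 60, 10% at 10, i.e. a tenth of
    reads fall below the MAPQ 30 threshold).
    """
    if not 0.0 <= ambient_rate < 1.0:
        raise ValueError("ambient_rate must lie in [0, 1)")
    if mapq_distribution is None:
        mapq_distribution = [60] * 9 + [10]
    mapqs = np.asarray(mapq_distribution, dtype=np.int64)
    if guide_library is None:
        guide_library = default_guide_library()
    all_guides = np.array(sorted(guide_library))
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    records: list[GuideReadRecord] = []
    n_true = rng.poisson(reads_per_cell_mean * (1.0 - ambient_rate), size=len(metadata))
    n_amb = rng.poisson(reads_per_cell_mean * ambient_rate, size=len(metadata))
    counter = 0
    for (row, k_true, k_amb) in zip(metadata.itertuples(index=False), n_true, n_amb):
        guides = [row.guide_id] * int(k_true) + list(rng.choice(all_guides, size=int(k_amb)))
        for g in guides:
            records.append(
                GuideReadRecord(
                    cell_barcode=row.cell_barcode,
                    guide_id=str(g),
                    mapq=int(rng.choice(mapqs)),
                    read_id=f"read{counter:08d}",
                    umi=f"UMI{counter:08d}",
                )
            )
            counter += 1
    return records


def generate_longreads(
    n_reads: int,
    true_h: float,
    panel: Optional[HaplotypePanel] = None,
    recombination_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-read allele table emulating long-read haplotype sequencing.

    Each read is a full mutant haplotype with probability ``true_h`` (1 at
    every cis site, 0 at every trans site... encoded on the *allele* scale:
    allele=1 means the site's alternate base is present). Each position is
    then independently flipped with ``recombination_rate``.
    """
    if not 0.0 <= true_h <= 1.0 or not 0.0 <= recombination_rate <= 1.0:
        raise ValueError("rates must lie in [0, 1]")
    if panel is None:
        panel = default_panel()
    rng = np.random.default_rng(seed)
    positions = np.array([s.position for s in panel.sites])
    is_cis = np.array([s.orientation == "cis" for s in panel.sites])
    if n_reads == 0:
        return pd.DataFrame(columns=["read_id", "position", "allele"])
    mutant = rng.random(n_reads) < true_h
    # mutant haplotype carries alt at cis sites and ref at trans sites
    alleles = np.where(mutant[:, None], is_cis[None, :], ~is_cis[None, :]).astype(int)
    flips = rng.random((n_reads, len(positions))) < recombination_rate
    alleles = np.where(flips, 1 - alleles, alleles)
    return pd.DataFrame(
        {
            "read_id": np.repeat([f"LR{i:06d}" for i in range(n_reads)], len(positions)),
            "position": np.tile(positions, n_reads),
            "allele": alleles.ravel(),
        }
    )


def generate_expression(
    truth: pd.DataFrame,
    coverage: pd.DataFrame,
    n_genes: int = 300,
    n_isr_genes: int = 30,
    n_cn_genes: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Log-normalized expression with a stress-response module and CN coupling.

    A negative-binomial baseline (gamma-Poisson) is modulated by two gene
    modules: stress-response genes scale up with the cell's mitochondrial
    stress activation (stronger in depleted cells) and a second module tracks
    mtDNA coverage directly. Counts are depth-normalized to 10,000 and
    log1p-transformed. Gene names: ISRxxx, CNGxxx, Gxxx.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    n_cells = len(truth)
    names = (
        [f"ISR{i:04d}" for i in range(n_isr_genes)]
        + [f"CNG{i:04d}" for i in range(n_cn_genes)]
        + [f"G{i:04d}" for i in range(n_genes - n_isr_genes - n_cn_genes)]
    )
    base_mean = rng.lognormal(0.0, 1.0, size=n_genes) + 0.1
    isr = truth["isr_activation"].to_numpy()
    cov = coverage.set_index("cell_barcode").loc[truth["cell_barcode"], "mean_coverage"]
    cov_z = (cov - cov.mean()) / (cov.std(ddof=1) + 1e-12)

    log_mu = np.log(base_mean)[None, :] * np.ones((n_cells, 1))
    log_mu[:, :n_isr_genes] += 1.5 * isr[:, None]
    log_mu[:, n_isr_genes:n_isr_genes + n_cn_genes] += 0.5 * cov_z.to_numpy()[:, None]
    mu = np.exp(log_mu)
    dispersion = 2.0  # gamma shape; moderate overdispersion
    lam = rng.gamma(dispersion, mu / dispersion)
    counts = rng.poisson(lam)
    libsize = counts.sum(axis=1, keepdims=True)
    libsize[libsize == 0] = 1
    norm = np.log1p(counts / libsize * 1e4)
    return pd.DataFrame(norm, index=truth["cell_barcode"].to_numpy(), columns=names)
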