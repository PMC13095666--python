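"""Per-cell heteroplasmy from linked mitochondrial SNVs.

Heteroplasmy is the fraction of a cell's mtDNA molecules carrying a variant
haplotype. When several SNVs are linked on the same two haplotypes, the read
depth at each site is an independent observation of the same underlying
fraction, so counts can be pooled across sites to increase effective
coverage. Sites whose alternate allele rides on the *same* haplotype as the
focal pathogenic variant are *cis*; sites whose alternate allele marks the
opposing haplotype are *trans* and contribute their reference counts to the
focal-haplotype tally instead.

Coordinates are 1-based positions on the circular mitochondrial genome
(mouse mtDNA, 16,299 bp by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "VariantSite",
    "HaplotypePanel",
    "site_heteroplasmy",
    "infer_orientations",
    "combined_heteroplasmy",
    "filter_by_combined_depth",
    "longread_haplotype_concordance",
]

MOUSE_MT_GENOME_LENGTH = 16_299


@dataclass(frozen=True)
class VariantSite:
    position: int
    ref_allele: str
    alt_allele: str
    orientation: str = "unknown"  # cis | trans | unknown

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("positions are 1-based; got %d" % self.position)
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.orientation not in ("cis", "trans", "unknown"):
            raise ValueError(f"bad orientation {self.orientation!r}")


@dataclass(frozen=True)
class HaplotypePanel:
    """A set of linked heteroplasmic SNVs around a focal pathogenic site."""

    sites: tuple[VariantSite, ...]
    focal_position: int
    genome_length: int = MOUSE_MT_GENOME_LENGTH

    def __post_init__(self) -> None:
        positions = [s.position for s in self.sites]
        if len(set(positions)) != len(positions):
            raise ValueError("panel positions must be unique")
        if self.focal_position not in positions:
            raise ValueError("focal site must be part of the panel")
        if any(s.position > self.genome_length for s in self.sites):
            raise ValueError("site position beyond genome length")
        if self.focal_site.orientation != "cis":
            raise ValueError("the focal site defines the haplotype and must be cis")

    @property
    def focal_site(self) -> VariantSite:
        return next(s for s in self.sites if s.position == self.focal_position)

    def oriented_sites(self) -> tuple[VariantSite, ...]:
        """Sites usable for combined calling (orientation resolved)."""
        return tuple(s for s in self.sites if s.orientation in ("cis", "trans"))

    def site(self, position: int) -> VariantSite:
        for s in self.sites:
            if s.position == position:
                return s
        raise KeyError(position)

    def with_orientation(self, position: int, orientation: str) -> "HaplotypePanel":
        new_sites = tuple(
            replace(s, orientation=orientation) if s.position == position else s
            for s in self.sites
        )
        return HaplotypePanel(new_sites, self.focal_position, self.genome_length)


def site_heteroplasmy(ref_count: int, alt_count: int) -> float:
    """Alternate-allele fraction at a single site; NaN at zero depth."""
    if ref_count < 0 or alt_count < 0:
        raise ValueError("allele counts must be non-negative")
    depth = ref_count + alt_count
    if depth == 0:
        return math.nan
    return alt_count / depth


def _site_fraction_table(counts: pd.DataFrame) -> pd.DataFrame:
    """cell x position matrices of site heteroplasmy and depth."""
    depth = counts["ref_count"] + counts["alt_count"]
    frac = counts["alt_count"] / depth.where(depth > 0)
    wide_f = frac.groupby([counts["cell_barcode"], counts["position"]]).first().unstack()
    wide_d = depth.groupby([counts["cell_barcode"], counts["position"]]).first().unstack()
    return wide_f, wide_d


def infer_orientations(
    counts: pd.DataFrame,
    panel: HaplotypePanel,
    min_site_depth: int = 5,
    min_abs_r: float = 0.3,
    min_cells: int = 10,
) -> HaplotypePanel:
    """Set cis/trans orientation of each non-focal site from per-cell correlation.

    For each non-focal site, the Pearson correlation of its per-cell
    heteroplasmy with the focal site's is computed across cells where both
    sites have depth >= ``min_site_depth``. r >= +``min_abs_r`` marks the site
    cis, r <= -``min_abs_r`` trans; otherwise (or with fewer than
    ``min_cells`` qualifying cells) the site stays unknown and is excluded
    from combined calling.
    """
    frac, depth = _site_fraction_table(counts)
    focal = panel.focal_position
    if focal not in frac.columns:
        raise ValueError(f"no counts for focal site at position {focal}")
    out = panel
    for site in panel.sites:
        if site.position == focal:
            continue
        if site.position not in frac.columns:
            logger.warning("site %d has no counts; orientation left unknown", site.position)
            out = out.with_orientation(site.position, "unknown")
            continue
        ok = (depth[focal] >= min_site_depth) & (depth[site.position] >= min_site_depth)
        x = frac.loc[ok, focal]
        y = frac.loc[ok, site.position]
        if ok.sum() < min_cells:
            logger.warning(
                "site %d: only %d cells pass depth >= %d at both sites; orientation unknown",
                site.position, int(ok.sum()), min_site_depth,
            )
            out = out.with_orientation(site.position, "unknown")
            continue
        if x.std() == 0 or y.std() == 0:
            logger.warning("site %d: degenerate fractions; orientation unknown", site.position)
            out = out.with_orientation(site.position, "unknown")
            continue
        r = stats.pearsonr(x, y).statistic
        if r >= min_abs_r:
            out = out.with_orientation(site.position, "cis")
        elif r <= -min_abs_r:
            out = out.with_orientation(site.position, "trans")
        else:
            logger.warning(
                "site %d: |r| = %.3f below %.2f; excluded from combined calling",
                site.position, abs(r), min_abs_r,
            )
            out = out.with_orientation(site.position, "unknown")
    return out


def combined_heteroplasmy(counts: pd.DataFrame, panel: HaplotypePanel) -> pd.DataFrame:
    """Pool oriented allele counts across panel sites into one call per cell.

    h = (sum of focal-haplotype counts) / (sum of total counts), where the
    focal-haplotype count at a cis site is its alt count and at a trans site
    its ref count. Cells with zero combined depth are omitted.

    Returns a DataFrame with columns ``cell_barcode``, ``heteroplasmy``,
    ``combined_depth``.
    """
    oriented = {s.position: s.orientation for s in panel.sites}
    unknown_positions = {p for p, o in oriented.items() if o == "unknown"}
    extra = set(counts["position"]) - set(oriented)
    if extra:
        raise ValueError(f"counts contain positions absent from the panel: {sorted(extra)}")
    usable = counts[~counts["position"].isin(unknown_positions)]
    if (usable[["ref_count", "alt_count"]] < 0).any().any():
        raise ValueError("allele counts must be non-negative")

    is_cis = usable["position"].map(oriented) == "cis"
    focal_count = usable["alt_count"].where(is_cis, usable["ref_count"])
    depth = usable["ref_count"] + usable["alt_count"]
    grouped = pd.DataFrame(
        {"cell_barcode": usable["cell_barcode"], "focal": focal_count, "depth": depth}
    ).groupby("cell_barcode", sort=True).sum()
    grouped = grouped[grouped["depth"] > 0]
    return pd.DataFrame(
        {
            "cell_barcode": grouped.index,
            "heteroplasmy": (grouped["focal"] / grouped["depth"]).to_numpy(),
            "combined_depth": grouped["depth"].astype(int).to_numpy(),
        }
    ).reset_index(drop=True)


def filter_by_combined_depth(calls: pd.DataFrame, min_depth: int = 20) -> pd.DataFrame:
    """Keep cells with combined panel depth >= ``min_depth`` (inclusive)."""
    return calls[calls["combined_depth"] >= min_depth].reset_index(drop=True)


def longread_haplotype_concordance(
    read_alleles: pd.DataFrame, panel: Optional[HaplotypePanel] = None
) -> pd.DataFrame:
    """Pairwise haplotype concordance between panel positions on long reads.

    ``read_alleles`` has columns ``read_id``, ``position``, ``allele``
    (1 = mutant allele at that site, 0 = wild-type). If a panel is given,
    trans-site alleles are flipped so that 1 always denotes the focal
    haplotype. For every position pair, the fraction of reads covering both
    positions whose oriented alleles agree is reported as a percentage.
    Reads covering fewer than two positions contribute to no pair.
    """
    alleles = read_alleles.copy()
    if panel is not None:
        orient = {s.position: s.orientation for s in panel.sites}
        flip = alleles["position"].map(orient) == "trans"
        alleles.loc[flip, "allele"] = 1 - alleles.loc[flip, "allele"]
    wide = alleles.pivot_table(index="read_id", columns="position", values="allele")
    rows = []
    for p1, p2 in combinations(sorted(wide.columns), 2):
        both = wide[[p1, p2]].dropna()
        if len(both) == 0:
            continue
        agree = (both[p1] == both[p2]).mean()
        rows.append(
            {
                "position_1": p1,
                "position_2": p2,
                "n_reads": len(both),
                "concordance_pct": 100.0 * agree,
            }
        )
    return pd.DataFrame(rows, columns=["position_1", "position_2", "n_reads", "concordance_pct"])
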