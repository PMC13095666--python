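"""Linked-SNV heteroplasmy calling: orientation, pooling, depth filtering, long reads."""

import math

import numpy as np
import pandas as pd
import pytest

from mitoscreen import (
    HaplotypePanel,
    VariantSite,
    combined_heteroplasmy,
    filter_by_combined_depth,
    infer_orientations,
    longread_haplotype_concordance,
    site_heteroplasmy,
)


def counts_frame(rows):
    return pd.DataFrame(rows, columns=["cell_barcode", "position", "ref_count", "alt_count"])


class TestSiteHeteroplasmy:
    @pytest.mark.parametrize("ref,alt,expected", [(3, 1, 0.25), (0, 7, 1.0), (5, 0, 0.0)])
    def test_fraction(self, ref, alt, expected):
        assert site_heteroplasmy(ref, alt) == expected

    def test_zero_depth_undefined(self):
        assert math.isnan(site_heteroplasmy(0, 0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            site_heteroplasmy(-1, 2)


class TestCombined:
    def test_worked_example(self, small_panel):
        rows = [
            ("cell1", 100, 2, 8),   # cis: contributes alt 8 of 10
            ("cell1", 500, 1, 4),   # cis: alt 4 of 5
            ("cell1", 900, 6, 4),   # trans: ref 6 of 10
        ]
        calls = combined_heteroplasmy(counts_frame(rows), small_panel)
        assert calls.loc[0, "heteroplasmy"] == pytest.approx((8 + 4 + 6) / 25)
        assert calls.loc[0, "combined_depth"] == 25

    def test_all_cis_pure_alt(self):
        panel = HaplotypePanel(
            (VariantSite(1, "A", "G", "cis"), VariantSite(2, "C", "T", "cis")),
            focal_position=1,
        )
        calls = combined_heteroplasmy(
            counts_frame([("c", 1, 0, 9), ("c", 2, 0, 6)]), panel
        )
        assert calls.loc[0, "heteroplasmy"] == 1.0

    def test_single_cis_site_reduces_to_site_fraction(self):
        panel = HaplotypePanel((VariantSite(7, "A", "G", "cis"),), focal_position=7)
        calls = combined_heteroplasmy(counts_frame([("c", 7, 3, 1)]), panel)
        assert calls.loc[0, "heteroplasmy"] == site_heteroplasmy(3, 1)

    def test_unknown_position_rejected(self, small_panel):
        with pytest.raises(ValueError, match="absent from the panel"):
            combined_heteroplasmy(counts_frame([("c", 4242, 1, 1)]), small_panel)

    def test_zero_depth_cells_omitted(self, small_panel):
        calls = combined_heteroplasmy(counts_frame([("c", 100, 0, 0)]), small_panel)
        assert len(calls) == 0

    def test_zero_depth_site_does_not_change_h(self, small_panel):
        base = counts_frame([("c", 100, 2, 8), ("c", 900, 6, 4)])
        plus = counts_frame([("c", 100, 2, 8), ("c", 900, 6, 4), ("c", 500, 0, 0)])
        h1 = combined_heteroplasmy(base, small_panel).loc[0, "heteroplasmy"]
        h2 = combined_heteroplasmy(plus, small_panel).loc[0, "heteroplasmy"]
        assert h1 == h2

    def test_flipping_every_orientation_flips_h(self):
        """Relabeling which haplotype is focal maps h to exactly 1 - h."""
        panel = HaplotypePanel(
            (VariantSite(1, "A", "G", "cis"), VariantSite(2, "C", "T", "trans")),
            focal_position=1,
        )
        flipped = HaplotypePanel(
            (VariantSite(1, "A", "G", "trans"), VariantSite(2, "C", "T", "cis")),
            focal_position=2,
        )
        rows = counts_frame([("c", 1, 3, 9), ("c", 2, 5, 2)])
        h = combined_heteroplasmy(rows, panel).loc[0, "heteroplasmy"]
        h_flip = combined_heteroplasmy(rows, flipped).loc[0, "heteroplasmy"]
        assert h + h_flip == pytest.approx(1.0)

    def test_equals_depth_weighted_site_average(self, small_panel, rng):
        rows = []
        for cell in range(20):
            for site in small_panel.sites:
                d = int(rng.integers(1, 40))
                a = int(rng.integers(0, d + 1))
                rows.append((f"c{cell}", site.position, d - a, a))
        counts = counts_frame(rows)
        calls = combined_heteroplasmy(counts, small_panel).set_index("cell_barcode")
        orient = {s.position: s.orientation for s in small_panel.sites}
        for cell, sub in counts.groupby("cell_barcode"):
            depth = sub["ref_count"] + sub["alt_count"]
            frac = np.where(
                sub["position"].map(orient) == "cis",
                sub["alt_count"] / depth,
                sub["ref_count"] / depth,
            )
            weighted = float((frac * depth).sum() / depth.sum())
            assert calls.loc[cell, "heteroplasmy"] == pytest.approx(weighted)


class TestOrientationInference:
    def build(self, focal_frac, site_frac, depth=50):
        rows = []
        for i, (f, s) in enumerate(zip(focal_frac, site_frac)):
            rows.append((f"c{i}", 100, round(depth * (1 - f)), round(depth * f)))
            rows.append((f"c{i}", 500, round(depth * (1 - s)), round(depth * s)))
            rows.append((f"c{i}", 900, 25, 25))
        return counts_frame(rows)

    def test_perfect_correlation_is_cis(self, small_panel, rng):
        f = rng.uniform(0.2, 0.8, 30)
        panel = infer_orientations(self.build(f, f), small_panel)
        assert panel.site(500).orientation == "cis"

    def test_perfect_anticorrelation_is_trans(self, small_panel, rng):
        f = rng.uniform(0.2, 0.8, 30)
        panel = infer_orientations(self.build(f, 1 - f), small_panel)
        assert panel.site(500).orientation == "trans"

    def test_independent_noise_is_unknown(self, small_panel, rng):
        f = rng.uniform(0.0, 1.0, 200)
        s = rng.uniform(0.0, 1.0, 200)
        panel = infer_orientations(self.build(f, s), small_panel)
        assert panel.site(500).orientation == "unknown"

    def test_too_few_cells_is_unknown(self, small_panel, rng):
        f = rng.uniform(0.2, 0.8, 5)
        panel = infer_orientations(self.build(f, f), small_panel)
        assert panel.site(500).orientation == "unknown"


class TestDepthFilter:
    def make_calls(self, depths):
        return pd.DataFrame(
            {
                "cell_barcode": [f"c{i}" for i in range(len(depths))],
                "heteroplasmy": [0.5] * len(depths),
                "combined_depth": depths,
            }
        )

    def test_threshold_inclusive(self):
        assert len(filter_by_combined_depth(self.make_calls([5, 20, 35]), 20)) == 2

    def test_zero_threshold_is_identity(self):
        calls = self.make_calls([1, 2, 3])
        assert filter_by_combined_depth(calls, 0).equals(calls)

    def test_boundary_exclusion(self):
        assert len(filter_by_combined_depth(self.make_calls([19, 19]), 20)) == 0


class TestLongReads:
    def table(self, reads):
        rows = []
        for rid, alleles in reads.items():
            for pos, a in alleles.items():
                rows.append({"read_id": rid, "position": pos, "allele": a})
        return pd.DataFrame(rows)

    def test_perfect_linkage(self):
        reads = {
            "m1": {1: 1, 2: 1}, "m2": {1: 1, 2: 1},
            "w1": {1: 0, 2: 0}, "w2": {1: 0, 2: 0},
        }
        out = longread_haplotype_concordance(self.table(reads))
        assert out["concordance_pct"].tolist() == [100.0]

    def test_one_discordant_read(self):
        reads = {
            "m1": {1: 1, 2: 1}, "m2": {1: 1, 2: 1},
            "w1": {1: 0, 2: 0}, "w2": {1: 0, 2: 0},
            "x": {1: 1, 2: 0},
        }
        out = longread_haplotype_concordance(self.table(reads))
        assert out["concordance_pct"].tolist() == [80.0]

    def test_trans_sites_oriented_before_comparison(self, small_panel):
        # a pure focal-haplotype read: alt at cis sites, ref at trans site
        reads = {"m": {100: 1, 900: 0}, "w": {100: 0, 900: 1}}
        out = longread_haplotype_concordance(self.table(reads), panel=small_panel)
        assert out["concordance_pct"].tolist() == [100.0]

    def test_independent_alleles_match_closed_form(self, rng):
        n = 4000
        q1, q2 = 0.7, 0.4
        df = pd.DataFrame(
            {
                "read_id": np.repeat([f"r{i}" for i in range(n)], 2),
                "position": np.tile([1, 2], n),
                "allele": np.concatenate(
                    [np.stack([rng.random(n) < q1, rng.random(n) < q2], axis=1).astype(int).ravel()]
                ),
            }
        )
        out = longread_haplotype_concordance(df)
        expected = 100 * (q1 * q2 + (1 - q1) * (1 - q2))
        assert out.loc[0, "concordance_pct"] == pytest.approx(expected, abs=2.5)

    def test_single_position_read_contributes_nothing(self):
        reads = {"solo": {1: 1}, "m": {1: 1, 2: 1}, "w": {1: 0, 2: 0}}
        out = longread_haplotype_concordance(self.table(reads))
        assert out.loc[0, "n_reads"] == 2


def test_rmse_decreases_with_depth(rng):
    """The read-depth bottleneck: pooled calls sharpen as total depth grows."""
    panel = HaplotypePanel((VariantSite(1, "A", "G", "cis"),), focal_position=1)
    true_h = rng.uniform(0.3, 0.8, 400)

    def rmse(depth):
        alt = rng.binomial(depth, true_h)
        rows = pd.DataFrame(
            {
                "cell_barcode": [f"c{i}" for i in range(len(true_h))],
                "position": 1,
                "ref_count": depth - alt,
                "alt_count": alt,
            }
        )
        calls = combined_heteroplasmy(rows, panel)
        return float(np.sqrt(np.mean((calls["heteroplasmy"].to_numpy() - true_h) ** 2)))

    assert rmse(100) < rmse(5)
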