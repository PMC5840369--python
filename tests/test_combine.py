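"""Stouffer combination, q-values, region calling, consistency, annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_panel
from domescan.combine import (
    RegionRecord, annotate_regions, call_regions, class_distribution_test,
    haplotype_consistency, qvalues, storey_pi0, stouffer_combine, top_flk_snps,
)
from domescan.io import GeneTrack


# ---------------------------------------------------------------------------
# Stouffer
# ---------------------------------------------------------------------------

def test_stouffer_fixed_points_and_symmetry():
    assert stouffer_combine([0.5], [0.5])[0] == pytest.approx(0.5)
    assert stouffer_combine([0.3], [0.7])[0] == pytest.approx(0.5)  # z cancel


def test_stouffer_two_nominal_pvalues():
    # z = 1.6449 each -> combined p = sf(2 * 1.6449 / sqrt(2)) ~ 0.0100
    got = stouffer_combine([0.05], [0.05])[0]
    z = stats.norm.isf(0.05)
    assert got == pytest.approx(stats.norm.sf(2 * z / np.sqrt(2)), rel=1e-12)
    assert got == pytest.approx(0.0100, abs=2e-4)


def test_stouffer_accumulates_evidence():
    for p in (0.3, 0.1, 0.01):
        assert stouffer_combine([p], [p])[0] < p


def test_stouffer_clamps_boundary_pvalues():
    out = stouffer_combine([0.0], [1.0])
    assert np.isfinite(out).all()


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------

def test_qvalues_all_ones_stay_one():
    assert np.all(qvalues(np.ones(10)) == 1.0)


def test_qvalues_bh_hand_computation():
    q = qvalues(np.array([0.01, 0.02, 0.03, 0.04]), pi0=1.0)
    np.testing.assert_allclose(q, 0.04)


def test_qvalues_preserve_pvalue_order():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=500)
    q = qvalues(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-15)
    assert np.all((q >= 0) & (q <= 1))


def test_storey_pi0_estimates():
    rng = np.random.default_rng(1)
    assert storey_pi0(np.full(100, 0.1)) == 0.0           # all p <= lambda
    u = rng.uniform(size=10_000)
    assert storey_pi0(u) == pytest.approx(1.0, abs=0.05)
    mix = np.concatenate([np.zeros(5000), rng.uniform(size=5000)])
    assert storey_pi0(mix) == pytest.approx(0.5, abs=0.05)


# ---------------------------------------------------------------------------
# region calling
# ---------------------------------------------------------------------------

def _scan(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "q"])


def test_snps_within_50kb_merge_into_one_region():
    regions = call_regions(_scan([("1", 100_000, 1e-3), ("1", 149_999, 1e-3)]))
    assert len(regions) == 1
    assert (regions[0].start, regions[0].end) == (100_000, 149_999)


def test_snps_at_50kb_or_more_split():
    regions = call_regions(_scan([("1", 100_000, 1e-3), ("1", 150_001, 1e-3)]))
    assert len(regions) == 2
    assert all(r.singleton for r in regions)


def test_no_significant_snps_gives_empty_list():
    assert call_regions(_scan([("1", 1000, 0.5)])) == []


def test_q_threshold_is_strict():
    assert call_regions(_scan([("1", 1000, 1e-2)]), q_max=1e-2) == []


def test_region_calling_partitions_retained_snps():
    rng = np.random.default_rng(2)
    pos = np.sort(rng.choice(10_000_000, size=300, replace=False))
    q = rng.uniform(0, 0.02, size=300)
    regions = call_regions(_scan([("1", int(p), float(x)) for p, x in zip(pos, q)]))
    member = sorted(p for r in regions for p in r.snp_pos)
    retained = sorted(int(p) for p, x in zip(pos, q) if x < 1e-2)
    assert member == retained  # every retained SNP in exactly one region


def test_top_snp_breaks_ties_by_position():
    regions = call_regions(_scan([("1", 2000, 1e-3), ("1", 1000, 1e-3)]))
    assert regions[0].top_pos == 1000


def test_top_flk_snps_strict_threshold():
    reg = RegionRecord("r", "1", 1000, 3000, [1000, 2000, 3000],
                       [1e-3] * 3, 1000, 1e-3)
    tbl = pd.DataFrame({
        "chrom": ["1"] * 3, "pos": [1000, 2000, 3000],
        "flk_comb_p": [1e-4, 9.9e-5, 0.5],
    })
    assert top_flk_snps(reg, tbl) == [2000]  # exactly 1e-4 excluded


# ---------------------------------------------------------------------------
# haplotype consistency
# ---------------------------------------------------------------------------

def _consistency_panel(domestic_same=True, seed=0):
    rng = np.random.default_rng(seed)
    n_sites = 20
    hapA = (rng.random(n_sites) < 0.5).astype(np.int8)
    hapB = hapA if domestic_same else 1 - hapA
    g = np.empty((n_sites, 26, 2), dtype=np.int8)
    for i in range(8):                       # wild: random haplotypes
        g[:, i, 0] = rng.random(n_sites) < 0.5
        g[:, i, 1] = rng.random(n_sites) < 0.5
    g[:, 8:17, :] = hapA[:, None, None]      # domestic_A fixed
    g[:, 17:26, :] = hapB[:, None, None]     # domestic_B fixed
    return make_panel(g, [("W", "wild", 8), ("A", "domestic_A", 9),
                          ("B", "domestic_B", 9)])


def test_shared_domestic_haplotype_passes():
    panel = _consistency_panel(domestic_same=True)
    reg = RegionRecord("r", "1", 1, 30_000, [1000], [1e-3], 1000, 1e-3)
    status, nwk = haplotype_consistency(reg, panel)
    assert status == "pass"
    assert nwk.endswith(";")


def test_discordant_domestic_haplotypes_fail():
    panel = _consistency_panel(domestic_same=False)
    reg = RegionRecord("r", "1", 1, 30_000, [1000], [1e-3], 1000, 1e-3)
    status, _ = haplotype_consistency(reg, panel)
    assert status == "fail"


def test_single_snp_region_is_indeterminate():
    panel = _consistency_panel()
    reg = RegionRecord("r", "1", 900, 1100, [1000], [1e-3], 1000, 1e-3)
    status, nwk = haplotype_consistency(reg, panel)
    assert status == "indeterminate" and nwk is None


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def _track(gene_start, gene_end, name="G"):
    return GeneTrack(pd.DataFrame(
        [{"chrom": "1", "start": gene_start, "end": gene_end,
          "strand": "+", "name": name}]
    ))


def test_gene_within_combined_flank_is_assigned():
    reg = RegionRecord("r", "1", 100_000, 200_000, [150_000], [1e-3], 150_000, 1e-3)
    # gene begins 54,999 bp beyond region end: inside 50k + 5k combined flank
    track = _track(254_999, 260_000)
    annotate_regions([reg], track)
    assert reg.genes == ["G"]


def test_gene_beyond_combined_flank_is_not_assigned():
    reg = RegionRecord("r", "1", 100_000, 200_000, [150_000], [1e-3], 150_000, 1e-3)
    track = _track(255_001, 260_000)
    annotate_regions([reg], track)
    assert reg.genes == []


def test_gene_containing_top_snp_is_closest():
    reg = RegionRecord("r", "1", 100_000, 200_000, [150_000], [1e-3], 150_000, 1e-3)
    track = GeneTrack(pd.DataFrame([
        {"chrom": "1", "start": 140_000, "end": 160_000, "strand": "+", "name": "IN"},
        {"chrom": "1", "start": 190_000, "end": 210_000, "strand": "+", "name": "NEAR"},
    ]))
    annotate_regions([reg], track)
    assert reg.closest_gene == "IN"
    assert set(reg.genes) == {"IN", "NEAR"}


# ---------------------------------------------------------------------------
# SNP-class distribution test
# ---------------------------------------------------------------------------

def test_identical_class_proportions_give_zero_statistic():
    stat, p = class_distribution_test(
        {"intergenic": 50, "intronic": 30, "exonic": 20},
        {"intergenic": 500, "intronic": 300, "exonic": 200},
    )
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_two_category_hand_chi2():
    # obs 30/70 vs background 50/50 (n=100): chi2 = 400/50 + 400/50 = 16
    stat, p = class_distribution_test({"a": 30, "b": 70}, {"a": 50, "b": 50})
    assert stat == pytest.approx(16.0)
    assert p == pytest.approx(stats.chi2.sf(16, 1), rel=1e-12)


def test_doubling_counts_doubles_statistic():
    s1, _ = class_distribution_test({"a": 30, "b": 70}, {"a": 50, "b": 50})
    s2, _ = class_distribution_test({"a": 60, "b": 140}, {"a": 50, "b": 50})
    assert s2 == pytest.approx(2 * s1)
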