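"""Delta-pi classification and conservation-weighted genetic load."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_panel
from domescan.combine import RegionRecord
from domescan.io import GeneTrack
from domescan.load import (
    CLASS_DIRECTIONAL, CLASS_RELAXATION, delta_pi, gene_load_test,
    individual_load, load_inbreeding_correlation,
)
from domescan.popgen import inbreeding_coefficient


# ---------------------------------------------------------------------------
# delta-pi
# ---------------------------------------------------------------------------

def _region(start=1, end=10_000):
    return RegionRecord("r", "1", start, end, [start], [1e-3], start, 1e-3)


def test_delta_pi_stated_formula_arithmetic():
    # stated formula with an explicit genome-wide term:
    # delta_pi = (pi_wild - pi_dom)_region - genomewide_term
    g = np.zeros((4, 6, 2), dtype=np.int8)
    # wild: 2 ind (4 haps) with 2 ALT at sites 0-2 -> pi = 4/6 per site
    g[0:3, 0, :] = 1
    panel = make_panel(
        g, [("W", "wild", 2), ("A", "domestic_A", 2), ("B", "domestic_B", 2)]
    )
    rec = delta_pi(_region(1, 4000), panel, genomewide_term=0.05)
    pi_w = 4 / 6 * 3 / 4  # three polymorphic sites of four
    assert rec.pi_wild_region == pytest.approx(pi_w)
    assert rec.pi_dom_region == 0.0
    assert rec.delta_pi == pytest.approx(pi_w - 0.0 - 0.05)
    assert rec.classification == CLASS_DIRECTIONAL


def test_delta_pi_zero_when_all_terms_equal():
    g = np.zeros((5, 6, 2), dtype=np.int8)
    g[:, ::2, 0] = 1  # same genotypes in every group
    panel = make_panel(
        g, [("W", "wild", 2), ("A", "domestic_A", 2), ("B", "domestic_B", 2)]
    )
    rec = delta_pi(_region(1, 5000), panel)
    assert rec.delta_pi == pytest.approx(0.0)


def test_negative_delta_pi_classified_as_relaxation():
    g = np.zeros((4, 6, 2), dtype=np.int8)
    g[:, 2, 0] = 1  # domestic_A polymorphic, wild monomorphic
    panel = make_panel(
        g, [("W", "wild", 2), ("A", "domestic_A", 2), ("B", "domestic_B", 2)]
    )
    rec = delta_pi(_region(1, 4000), panel, genomewide_term=0.0)
    assert rec.delta_pi < 0
    assert rec.classification == CLASS_RELAXATION


# ---------------------------------------------------------------------------
# individual load
# ---------------------------------------------------------------------------

def _load_panel():
    """6 individuals, 5 sites; scores make sites 0,1 constrained."""
    g = np.zeros((5, 6, 2), dtype=np.int8)
    g[0, 0, :] = 1          # ind 0 hom-ALT at constrained site 0 (score 2.0)
    g[1, 0, :] = 1          # ind 0 hom-ALT at constrained site 1 (score 3.0)
    g[0, 1, 0] = 1          # ind 1 het at site 0 -> no load
    g[2, 2, :] = 1          # ind 2 hom-ALT at non-constrained site
    panel = make_panel(
        g, [("W", "wild", 3), ("A", "domestic_A", 2), ("B", "domestic_B", 1)]
    )
    cons = pd.DataFrame({
        "chrom": "1", "pos": panel.sites["pos"],
        "score": [2.0, 3.0, 1.0, -0.5, 1.4],
    })
    return panel, cons


def test_load_sums_scores_at_homozygous_constrained_sites():
    panel, cons = _load_panel()
    table = individual_load(panel, cons)
    assert table.n_analyzed == 2
    # two qualifying sites, scores 2+3, over 2 analyzed positions
    assert table.per_individual["total_load"].iloc[0] == pytest.approx(2.5)
    assert table.per_individual["n_hom_mutated"].iloc[0] == 2


def test_heterozygous_only_individual_has_zero_load():
    panel, cons = _load_panel()
    table = individual_load(panel, cons)
    assert table.per_individual["total_load"].iloc[1] == 0.0


def test_homozygosity_at_unconstrained_sites_does_not_count():
    panel, cons = _load_panel()
    table = individual_load(panel, cons)
    assert table.per_individual["total_load"].iloc[2] == 0.0


def test_load_additive_over_disjoint_site_sets():
    rng = np.random.default_rng(0)
    g = (rng.random((40, 8, 2)) < 0.4).astype(np.int8)
    panel = make_panel(g, [("W", "wild", 4), ("A", "domestic_A", 2),
                           ("B", "domestic_B", 2)])
    scores = rng.uniform(-2, 4, 40)
    cons = pd.DataFrame({"chrom": "1", "pos": panel.sites["pos"], "score": scores})
    full = individual_load(panel, cons)
    half1 = individual_load(panel, cons.iloc[:20])
    half2 = individual_load(panel, cons.iloc[20:])
    total = (full.per_individual["total_load"] * full.n_analyzed)
    part = (half1.per_individual["total_load"] * half1.n_analyzed
            + half2.per_individual["total_load"] * half2.n_analyzed)
    np.testing.assert_allclose(total, part)


def test_lowering_constraint_threshold_never_decreases_raw_load():
    rng = np.random.default_rng(1)
    g = (rng.random((60, 6, 2)) < 0.4).astype(np.int8)
    panel = make_panel(g, [("W", "wild", 2), ("A", "domestic_A", 2),
                           ("B", "domestic_B", 2)])
    scores = rng.uniform(0, 4, 60)
    cons = pd.DataFrame({"chrom": "1", "pos": panel.sites["pos"], "score": scores})
    hi = individual_load(panel, cons, constraint_min=2.5)
    lo = individual_load(panel, cons, constraint_min=1.5)
    raw_hi = hi.per_individual["total_load"] * hi.n_analyzed
    raw_lo = lo.per_individual["total_load"] * lo.n_analyzed
    assert np.all(raw_lo >= raw_hi - 1e-12)


def test_no_constrained_sites_warns_and_zeroes():
    panel, cons = _load_panel()
    table = individual_load(panel, cons, constraint_min=10.0)
    assert (table.per_individual["total_load"] == 0).all()


# ---------------------------------------------------------------------------
# gene load test
# ---------------------------------------------------------------------------

def _gene_load_panels(shifted, seed=0):
    rng = np.random.default_rng(seed)
    n_sites, n_w, n_d = 200, 15, 20
    g = (rng.random((n_sites, n_w + n_d, 2)) < 0.3).astype(np.int8)
    if shifted:
        # plant extra hom-ALT for domestics in the first 2 genes (sites 0-19)
        extra = rng.random((20, n_d)) < 0.5
        rows, cols = np.nonzero(extra)
        g[rows, n_w + cols, :] = 1
    panel = make_panel(g, [("W", "wild", n_w), ("A", "domestic_A", n_d // 2),
                           ("B", "domestic_B", n_d - n_d // 2)])
    cons = pd.DataFrame({"chrom": "1", "pos": panel.sites["pos"],
                         "score": rng.uniform(1.6, 4.0, n_sites)})
    genes = GeneTrack(pd.DataFrame(
        [{"chrom": "1", "start": 1 + 10_000 * i, "end": 10_000 * (i + 1),
          "strand": "+", "name": f"g{i}"} for i in range(20)]
    ))
    return panel, cons, genes


def test_identical_load_distributions_give_no_significant_genes():
    panel, cons, genes = _gene_load_panels(shifted=False)
    table = individual_load(panel, cons, genes)
    res = gene_load_test(table, panel)
    assert not res["significant"].any()


def test_planted_domestic_load_shift_is_detected():
    panel, cons, genes = _gene_load_panels(shifted=True)
    table = individual_load(panel, cons, genes)
    res = gene_load_test(table, panel)
    sig = set(res.loc[res["significant"], "gene"])
    assert {"g0", "g1"} <= sig
    assert len(sig - {"g0", "g1"}) == 0


def test_wild_direction_shift_yields_nothing_one_sided():
    panel, cons, genes = _gene_load_panels(shifted=False, seed=3)
    # plant the shift in WILD individuals instead
    g = panel.genotypes.copy()
    rng = np.random.default_rng(4)
    extra = rng.random((20, 15)) < 0.5
    rows, cols = np.nonzero(extra)
    g[rows, cols, :] = 1
    import dataclasses

    panel = dataclasses.replace(panel, genotypes=g)
    table = individual_load(panel, cons, genes)
    res = gene_load_test(table, panel)
    assert not res["significant"].any()


# ---------------------------------------------------------------------------
# F-load correlation
# ---------------------------------------------------------------------------

def test_affine_load_in_f_gives_r_one():
    rng = np.random.default_rng(5)
    g = (rng.random((300, 10, 2)) < 0.4).astype(np.int8)
    panel = make_panel(g, [("W", "wild", 4), ("A", "domestic_A", 3),
                           ("B", "domestic_B", 3)])
    F = inbreeding_coefficient(panel)
    fake = F * 2.0 + 1.0

    class T:
        per_individual = pd.DataFrame({"load_per_hom": fake})

    r, p = load_inbreeding_correlation(T(), F)
    assert r == pytest.approx(1.0)


def test_zero_variance_correlation_is_flagged_nan():
    F = pd.Series({"a": 0.1, "b": 0.2, "c": 0.3})

    class T:
        per_individual = pd.DataFrame({"load_per_hom": [1.0, 1.0, 1.0]},
                                      index=["a", "b", "c"])

    r, p = load_inbreeding_correlation(T(), F)
    assert np.isnan(r)
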