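"""Diversity, inbreeding, FST, Reynolds distances, and the kinship model,
checked against hand arithmetic and brute-force oracles."""

import numpy as np
import pytest
from skbio import TreeNode

from conftest import make_panel, random_panel
from domescan import popgen
from domescan.io import GenotypePanel


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def test_pi_counts_differing_pairs():
    # one site, 4 haplotypes, 2 REF + 2 ALT -> 4 differing pairs / C(4,2)=6
    g = np.array([[[0, 0], [1, 1]]])
    panel = make_panel(g, [("W", "wild", 2)])
    assert popgen.nucleotide_diversity(panel, "W") == pytest.approx(4 / 6)


def test_pi_zero_for_identical_haplotypes_and_monomorphic_sites():
    g = np.ones((5, 3, 2), dtype=np.int8)
    panel = make_panel(g, [("W", "wild", 3)])
    assert popgen.nucleotide_diversity(panel, "W") == 0.0


def test_pi_windows_average_site_pi_and_round_trip_bed(tmp_path):
    rng = np.random.default_rng(8)
    panel = random_panel(rng, n_sites=50, group_sizes=(("W", "wild", 6),))
    win = popgen.pi_windows(panel, "W", window=20_000)  # 20 sites per window
    hap = panel.haplotypes()
    by_hand = popgen.site_pi(hap)[:20].mean()
    assert win.iloc[0]["pi"] == pytest.approx(by_hand)
    assert (win["pi"].to_numpy() >= 0).all()
    path = tmp_path / "pi.bed"
    popgen.write_pi_bed(win, path)
    first = path.read_text().splitlines()[0].split("\t")
    assert first[1] == "0" and int(first[2]) == 20_000


def test_pi_empty_interval_flagged_nan(small_panel):
    panel, _ = small_panel
    wild = panel.group_for_role("wild")
    assert np.isnan(popgen.nucleotide_diversity(panel, wild, "1", 1, 2))


def test_pi_matches_exhaustive_pair_counting():
    rng = np.random.default_rng(3)
    panel = random_panel(rng, n_sites=10, group_sizes=(("W", "wild", 6),))
    hap = panel.haplotypes()
    n = hap.shape[1]
    diffs = 0
    for i in range(n):
        for j in range(i + 1, n):
            diffs += (hap[:, i] != hap[:, j]).sum()
    expected = diffs / (n * (n - 1) / 2) / hap.shape[0]
    assert popgen.nucleotide_diversity(panel, "W") == pytest.approx(expected)


# ---------------------------------------------------------------------------
# inbreeding
# ---------------------------------------------------------------------------

def test_fully_homozygous_individual_has_f_one():
    rng = np.random.default_rng(0)
    g = (rng.random((50, 6, 2)) < 0.5).astype(np.int8)
    g[:, 0, 1] = g[:, 0, 0]  # individual 0 homozygous everywhere
    panel = make_panel(g, [("W", "wild", 6)])
    F = popgen.inbreeding_coefficient(panel)
    assert F.iloc[0] == pytest.approx(1.0)


def test_mean_f_near_zero_under_hardy_weinberg():
    rng = np.random.default_rng(1)
    p = rng.uniform(0.2, 0.8, 3000)
    g = (rng.random((3000, 40, 2)) < p[:, None, None]).astype(np.int8)
    panel = make_panel(g, [("W", "wild", 40)])
    F = popgen.inbreeding_coefficient(panel)
    assert abs(F.mean()) < 0.02


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def test_fst_near_zero_for_identical_populations():
    # two independent samples from the same allele frequencies
    rng = np.random.default_rng(2)
    p = rng.uniform(0.1, 0.9, 5000)
    g = (rng.random((5000, 60, 2)) < p[:, None, None]).astype(np.int8)
    panel = make_panel(g, [("A", "wild", 30), ("B", "domestic_A", 30)])
    assert abs(popgen.weir_cockerham_fst(panel, "A", "B")) < 0.01


def test_fst_approaches_one_for_reciprocally_fixed_site():
    g = np.zeros((1, 40, 2), dtype=np.int8)
    g[0, 20:, :] = 1
    panel = make_panel(g, [("A", "wild", 20), ("B", "domestic_A", 20)])
    assert popgen.weir_cockerham_fst(panel, "A", "B") > 0.97


def _wc_oracle(panel, ga, gb):
    """Scalar per-site Weir-Cockerham components, written long-hand."""
    a_sum = b_sum = c_sum = 0.0
    cols = {g: panel.group_columns(g) for g in (ga, gb)}
    for s in range(panel.n_sites):
        n = {}
        p = {}
        h = {}
        for g in (ga, gb):
            geno = panel.genotypes[s, cols[g], :]
            n[g] = len(cols[g])
            p[g] = geno.mean()
            h[g] = np.mean(geno[:, 0] != geno[:, 1])
        r = 2
        nbar = (n[ga] + n[gb]) / r
        nc = (r * nbar - (n[ga] ** 2 + n[gb] ** 2) / (r * nbar)) / (r - 1)
        pbar = (n[ga] * p[ga] + n[gb] * p[gb]) / (r * nbar)
        s2 = (n[ga] * (p[ga] - pbar) ** 2 + n[gb] * (p[gb] - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n[ga] * h[ga] + n[gb] * h[gb]) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum / (a_sum + b_sum + c_sum)


def test_fst_matches_scalar_component_oracle():
    rng = np.random.default_rng(4)
    panel = random_panel(
        rng, n_sites=10,
        group_sizes=(("A", "wild", 4), ("B", "domestic_A", 6), ("C", "domestic_B", 3)),
    )
    got = popgen.weir_cockerham_fst(panel, "A", "B")
    assert got == pytest.approx(_wc_oracle(panel, "A", "B"), abs=1e-12)


# ---------------------------------------------------------------------------
# Reynolds distance
# ---------------------------------------------------------------------------

def test_reynolds_identical_frequencies_zero_and_symmetric():
    rng = np.random.default_rng(5)
    fa = rng.uniform(0.1, 0.9, 50)
    fb = rng.uniform(0.1, 0.9, 50)
    assert popgen.reynolds_distance(fa, fa) == 0.0
    assert popgen.reynolds_distance(fa, fb) == pytest.approx(
        popgen.reynolds_distance(fb, fa)
    )


def test_reynolds_fixed_difference_is_one():
    assert popgen.reynolds_distance(np.array([0.0]), np.array([1.0])) == pytest.approx(1.0)


def test_reynolds_fixed_identical_returns_zero_with_warning():
    assert popgen.reynolds_distance(np.array([1.0]), np.array([1.0])) == 0.0


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def test_kinship_from_tree_path_sum_oracle():
    # rooted tree ((P1:0.1, P2:0.2):0.05) -> F = [[0.15, 0.05], [0.05, 0.25]]
    tree = TreeNode.read(["((P1:0.1,P2:0.2):0.05);"])
    F = popgen.kinship_from_tree(tree, ["P1", "P2"])
    assert F.loc["P1", "P1"] == pytest.approx(0.15)
    assert F.loc["P2", "P2"] == pytest.approx(0.25)
    assert F.loc["P1", "P2"] == pytest.approx(0.05)


def test_kinship_star_tree_is_diagonal():
    tree = TreeNode.read(["(P1:0.3,P2:0.3,P3:0.3);"])
    F = popgen.kinship_from_tree(tree, ["P1", "P2", "P3"])
    assert np.allclose(F.to_numpy(), 0.3 * np.eye(3))


def test_build_kinship_recovers_balding_nichols_drift():
    """Star tree, drift 0.05 per branch, independent sites: F ~ 0.05 I.

    Large samples per population: the plain Reynolds estimator carries a
    ~1/(2n) sampling inflation that would otherwise mask the drift signal.
    """
    rng = np.random.default_rng(6)
    c, m, n_per = 0.05, 10_000, 100
    p = rng.uniform(0.2, 0.8, m)
    blocks = []
    for _ in range(3):
        q = rng.beta(p * (1 - c) / c, (1 - p) * (1 - c) / c)
        blocks.append((rng.random((m, n_per, 2)) < q[:, None, None]).astype(np.int8))
    panel = make_panel(
        np.concatenate(blocks, axis=1),
        [("W", "wild", n_per), ("A", "domestic_A", n_per), ("B", "domestic_B", n_per)],
    )
    kin = popgen.build_kinship(panel, ["W", "A", "B"], seed=0, min_sites=m)
    diag = np.diag(kin.covariance.to_numpy())
    off = kin.covariance.to_numpy()[~np.eye(3, dtype=bool)]
    assert np.all(np.abs(diag - c) < 0.2 * c + 0.01)
    assert np.all(np.abs(off) < 0.01)


def test_kinship_covariance_is_positive_semidefinite(small_panel):
    panel, _ = small_panel
    kin = popgen.build_kinship(panel, panel.scan_groups(), seed=3)
    eig = np.linalg.eigvalsh(kin.covariance.to_numpy())
    assert eig.min() >= -1e-10
    D = kin.distances.to_numpy()
    assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)


def test_build_kinship_needs_two_groups(small_panel):
    panel, _ = small_panel
    with pytest.raises(ValueError):
        popgen.build_kinship(panel, [panel.scan_groups()[0]])


# ---------------------------------------------------------------------------
# group comparison tests
# ---------------------------------------------------------------------------

def test_mannwhitney_identical_samples_p_near_one():
    x = np.arange(10.0)
    p = popgen.group_comparison_test(x, x, "mannwhitney_two_sided")
    assert p > 0.9


def test_all_tied_values_give_p_one():
    x = np.ones(8)
    assert popgen.group_comparison_test(x, x, "mannwhitney_two_sided") == 1.0


def test_t_statistic_matches_textbook_formula():
    from scipy import stats

    w = np.array([1.0, 2.0, 3.0, 4.0])
    d = np.array([2.5, 3.5, 4.5, 6.5])
    p = popgen.group_comparison_test(w, d, "t_one_sided")
    t_expected = (d.mean() - w.mean()) / np.sqrt(d.var(ddof=1) / 4 + w.var(ddof=1) / 4)
    nu = (d.var(ddof=1) / 4 + w.var(ddof=1) / 4) ** 2 / (
        (d.var(ddof=1) / 4) ** 2 / 3 + (w.var(ddof=1) / 4) ** 2 / 3
    )
    assert p == pytest.approx(stats.t.sf(t_expected, nu), rel=1e-10)


def test_one_sided_alternative_is_domestic_larger():
    rng = np.random.default_rng(7)
    wild = rng.normal(1.0, 0.1, 30)       # wild stochastically larger
    dom = rng.normal(0.0, 0.1, 30)
    assert popgen.group_comparison_test(wild, dom, "t_one_sided") > 0.5
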