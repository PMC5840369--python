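"""Population-genetic summaries and the drift-covariance (kinship) model.

Implements nucleotide diversity, per-individual inbreeding, pairwise
Weir-Cockerham FST (ratio-of-sums "weighted" estimator), Reynolds genetic
distances, and the kinship matrix used as the drift null of the FLK family
of tests: Reynolds distances on a random site subset -> neighbor-joining
tree -> midpoint rooting -> covariance matrix whose (i, j) entry is the
branch length shared by the root-to-i and root-to-j paths.
"""

from __future__ import annotations

import io as _stdio
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .io import GenotypePanel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Diversity and inbreeding
# ---------------------------------------------------------------------------

def site_pi(hap: np.ndarray) -> np.ndarray:
    """Per-site nucleotide diversity from a (sites x haplotypes) 0/1 matrix.

    Unbiased pairwise estimator: number of differing haplotype pairs over
    C(n, 2) pairs.
    """
    n = hap.shape[1]
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    k = hap.sum(axis=1, dtype=float)
    return k * (n - k) / (n * (n - 1) / 2.0)


def nucleotide_diversity(
    panel: GenotypePanel,
    group: str,
    chrom: str | None = None,
    start: int | None = None,
    end: int | None = None,
) -> float:
    """Mean per-site pi for a group, over an interval or the whole panel.

    Returns NaN for an empty interval.
    """
    cols = panel.group_columns(group)
    if chrom is not None:
        mask = panel.site_mask_interval(chrom, start, end)
        if not mask.any():
            logger.warning("empty interval %s:%s-%s for pi", chrom, start, end)
            return float("nan")
        hap = panel.haplotypes(cols)[mask]
    else:
        hap = panel.haplotypes(cols)
    return float(site_pi(hap).mean())


def polymorphic_site_count(panel: GenotypePanel, group: str | None = None) -> int:
    f = panel.alt_freq(group)
    return int(np.count_nonzero((f > 0) & (f < 1)))


def inbreeding_coefficient(panel: GenotypePanel, group: str | None = None) -> pd.Series:
    """Method-of-moments F per individual, from within-group allele frequencies.

    F = (O_hom - E_hom) / (L - E_hom) with E_hom the expected homozygote
    count under Hardy-Weinberg, using the small-sample correction
    2 p q * n/(n - 1) per site (n = sampled chromosomes), as in common
    VCF-based implementations.  Computed per group so that wild and domestic
    individuals are each referenced to their own gene pool.
    """
    out = {}
    groups = sorted(set(panel.groups.values())) if group is None else [group]
    for g in groups:
        cols = panel.group_columns(g)
        hap = panel.haplotypes(cols)
        n_chr = hap.shape[1]
        p = hap.mean(axis=1)
        e_hom = 1.0 - 2.0 * p * (1.0 - p) * n_chr / (n_chr - 1.0)
        E = float(e_hom.sum())
        L = hap.shape[0]
        geno = panel.genotypes[:, cols, :]
        o_hom = (geno[:, :, 0] == geno[:, :, 1]).sum(axis=0)
        denom = L - E
        if abs(denom) < 1e-12:
            logger.warning("inbreeding undefined for group %s (L == E_hom)", g)
            vals = np.full(len(cols), np.nan)
        else:
            vals = (o_hom - E) / denom
        for c, v in zip(cols, vals):
            out[panel.individuals[c]] = float(v)
    return pd.Series(out, name="F")


def pi_windows(
    panel: GenotypePanel, group: str, window: int = 100_000
) -> pd.DataFrame:
    """Per-window mean pi for a group: columns chrom, start, end, pi
    (1-based inclusive windows; windows without sites are omitted)."""
    cols = panel.group_columns(group)
    pi = site_pi(panel.haplotypes(cols))
    rows = []
    for chrom, sub in panel.sites.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        win = (pos - 1) // window
        for w in np.unique(win):
            m = win == w
            rows.append((chrom, int(w * window + 1), int((w + 1) * window),
                         float(pi[sub.index.to_numpy()[m]].mean())))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "pi"])


def write_pi_bed(windows: pd.DataFrame, path) -> None:
    """BED4 (0-based half-open) of per-window pi."""
    with open(path, "w") as fh:
        for _, r in windows.iterrows():
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.pi:.6g}\n")


# ---------------------------------------------------------------------------
# Differentiation
# ---------------------------------------------------------------------------

def weir_cockerham_fst(panel: GenotypePanel, group_a: str, group_b: str) -> float:
    """Multi-locus weighted (ratio-of-sums) Weir-Cockerham FST for two groups."""
    comp = weir_cockerham_components(panel, group_a, group_b)
    a, b, c = (comp[k].sum() for k in ("a", "b", "c"))
    tot = a + b + c
    if tot == 0:
        logger.warning("FST undefined: no polymorphic sites between %s and %s",
                       group_a, group_b)
        return float("nan")
    return float(a / tot)


def weir_cockerham_fst_mean_pairwise(panel: GenotypePanel, groups: list[str]) -> float:
    vals = [
        weir_cockerham_fst(panel, a, b)
        for i, a in enumerate(groups)
        for b in groups[i + 1:]
    ]
    return float(np.nanmean(vals))


def weir_cockerham_components(
    panel: GenotypePanel, group_a: str, group_b: str
) -> pd.DataFrame:
    """Per-site Weir-Cockerham variance components a (among populations),
    b (among individuals within populations), c (within individuals)."""
    r = 2.0
    ns, ps, hs = [], [], []
    for g in (group_a, group_b):
        cols = panel.group_columns(g)
        geno = panel.genotypes[:, cols, :]
        ns.append(float(len(cols)))
        ps.append(geno.mean(axis=(1, 2)))
        hs.append((geno[:, :, 0] != geno[:, :, 1]).mean(axis=1))
    n1, n2 = ns
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * ps[0] + n2 * ps[1]) / (r * nbar)
    s2 = (n1 * (ps[0] - pbar) ** 2 + n2 * (ps[1] - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * hs[0] + n2 * hs[1]) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
    )
    c = hbar / 2.0
    return pd.DataFrame({"a": a, "b": b, "c": c})


def reynolds_distance(freq_a: np.ndarray, freq_b: np.ndarray) -> float:
    """Multi-locus Reynolds distance from per-site ALT frequencies.

    Ratio-of-sums dialect: sum over sites of (1/2) sum over alleles of the
    squared frequency difference, over sum over sites of (1 - sum of allele
    frequency products).
    """
    pa, pb = np.asarray(freq_a, float), np.asarray(freq_b, float)
    num = float(((pa - pb) ** 2).sum())  # = sum of 0.5 * [(dp)^2 + (dq)^2]
    den = float((1.0 - (pa * pb + (1 - pa) * (1 - pb))).sum())
    if den == 0.0:
        logger.warning("Reynolds distance denominator zero; returning 0")
        return 0.0
    return num / den


def reynolds_distance_per_locus(freq_a: np.ndarray, freq_b: np.ndarray) -> float:
    """Per-locus-averaged dialect (average of per-site ratios)."""
    pa, pb = np.asarray(freq_a, float), np.asarray(freq_b, float)
    num = (pa - pb) ** 2
    den = 1.0 - (pa * pb + (1 - pa) * (1 - pb))
    ok = den > 0
    if not ok.any():
        return 0.0
    return float((num[ok] / den[ok]).mean())


# ---------------------------------------------------------------------------
# Kinship model
# ---------------------------------------------------------------------------

@dataclass
class KinshipModel:
    populations: list[str]
    distances: pd.DataFrame          # Reynolds D, symmetric, zero diagonal
    tree: TreeNode | None            # rooted NJ tree (None for 2 populations)
    covariance: pd.DataFrame         # drift covariance matrix F

    def submatrix(self, pops: list[str]) -> np.ndarray:
        return self.covariance.loc[pops, pops].to_numpy()

    def newick(self) -> str:
        if self.tree is None:
            d = self.distances.iloc[0, 1]
            a, b = self.populations
            return f"({a}:{d:.6g},{b}:{d:.6g});"
        buf = _stdio.StringIO()
        self.tree.write(buf)
        return buf.getvalue().strip()


def kinship_from_tree(tree: TreeNode, populations: list[str]) -> pd.DataFrame:
    """Covariance matrix from a rooted tree: F[i, j] = shared root-path length.

    Negative branch lengths are clamped to zero (with a warning); the result
    is positive semi-definite by construction.
    """
    clamped = False
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped = True
    if clamped:
        warnings.warn("negative NJ branch lengths clamped to 0")

    def depth(node) -> float:
        d = 0.0
        while node.parent is not None:
            d += node.length or 0.0
            node = node.parent
        return d

    tips = {t.name: t for t in tree.tips()}
    k = len(populations)
    F = np.zeros((k, k))
    for i, a in enumerate(populations):
        for j, b in enumerate(populations):
            if i == j:
                F[i, j] = depth(tips[a])
            elif i < j:
                lca = tree.lowest_common_ancestor([tips[a], tips[b]])
                F[i, j] = F[j, i] = depth(lca)
    return pd.DataFrame(F, index=populations, columns=populations)


def build_kinship(
    panel: GenotypePanel,
    groups: list[str],
    subsample_fraction: float = 0.01,
    seed: int = 0,
    rooting: str = "midpoint",
    min_sites: int = 2000,
) -> KinshipModel:
    """Reynolds distances on a seeded random site subset -> NJ -> kinship.

    The fraction emulates whole-genome practice (a random 1% of variants);
    ``min_sites`` keeps the estimate stable on small panels, where 1% would
    be a handful of sites.

    The tree is fitted to 2D: the Reynolds distance between two populations
    estimates the *mean* of their two drift accumulations since divergence
    (checked by simulation), while the drift covariance needs path *sums* --
    without the factor the FLK null variance is halved.  With exactly two
    populations the doubled distance splits at its midpoint, so the
    covariance is diag(D, D).
    """
    if len(groups) < 2:
        raise ValueError("kinship needs at least 2 populations")
    rng = np.random.default_rng(seed)
    m = max(min_sites, int(round(subsample_fraction * panel.n_sites)))
    m = min(m, panel.n_sites)
    idx = np.sort(rng.choice(panel.n_sites, size=m, replace=False))
    logger.info("build_kinship: %d of %d sites (seed=%d)", m, panel.n_sites, seed)
    freqs = {g: panel.alt_freq(g)[idx] for g in groups}
    k = len(groups)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            D[i, j] = D[j, i] = reynolds_distance(freqs[groups[i]], freqs[groups[j]])
    Ddf = pd.DataFrame(D, index=groups, columns=groups)

    if k == 2:
        F = pd.DataFrame(
            np.diag([D[0, 1], D[0, 1]]), index=groups, columns=groups
        )
        return KinshipModel(list(groups), Ddf, None, F)

    tree = nj(DistanceMatrix(2.0 * D, ids=groups))
    if rooting == "midpoint":
        tree = tree.root_at_midpoint()
    F = kinship_from_tree(tree, list(groups))
    return KinshipModel(list(groups), Ddf, tree, F)


# ---------------------------------------------------------------------------
# Group comparison tests
# ---------------------------------------------------------------------------

def group_comparison_test(
    values_wild, values_domestic, kind: str
) -> float:
    """Wild-vs-domestic comparison used for diversity/inbreeding/load summaries.

    ``t_one_sided``: one-sided Welch t-test with alternative "domestic larger".
    ``mannwhitney_two_sided``: two-sided Mann-Whitney U.
    """
    w = np.asarray(values_wild, float)
    d = np.asarray(values_domestic, float)
    if len(w) == 0 or len(d) == 0:
        raise ValueError("empty sample")
    if kind == "t_one_sided":
        return float(stats.ttest_ind(d, w, equal_var=False, alternative="greater").pvalue)
    if kind == "mannwhitney_two_sided":
        if np.all(w == w[0]) and np.all(d == d[0]) and w[0] == d[0]:
            logger.warning("all values tied in Mann-Whitney; p = 1")
            return 1.0
        return float(stats.mannwhitneyu(w, d, alternative="two-sided").pvalue)
    raise ValueError(f"unknown test kind {kind!r}")
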