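"""Combining the two wild-vs-domestic contrasts into candidate regions.

The two contrast p-values per SNP (wild vs each traditional domestic group)
are combined with Stouffer's method, converted to q-values, and SNPs below
the significance threshold are merged into candidate regions with a 50-kb
rule.  Regions are then annotated with their most differentiated single
SNPs (FLK), checked for haplotype-clustering consistency across domestic
groups, and assigned overlapping/nearby genes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.tree import nj

from .io import GenotypePanel, GeneTrack

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# p-value combination and q-values
# ---------------------------------------------------------------------------

def stouffer_combine(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Stouffer combination of two one-sided upper-tail p-value vectors.

    z_i = Phi^-1(1 - p_i); combined p = 1 - Phi((z1 + z2) / sqrt(2)).
    Boundary p-values are clamped to machine-representable bounds.
    """
    out = []
    tiny = 1e-300
    for p in (np.asarray(p1, float), np.asarray(p2, float)):
        if np.any((p <= 0) | (p >= 1)):
            logger.warning("boundary p-values clamped before Stouffer combination")
        out.append(np.clip(p, tiny, 1 - 1e-16))
    z = stats.norm.isf(out[0]) + stats.norm.isf(out[1])
    return stats.norm.sf(z / np.sqrt(2.0))


def storey_pi0(pvals: np.ndarray, lam: float = 0.5) -> float:
    """Storey's pi0: #{p > lambda} / (m (1 - lambda)), clamped to [0, 1]."""
    p = np.asarray(pvals, float)
    if len(p) == 0:
        raise ValueError("empty p-value vector")
    if not 0.0 < lam < 1.0:
        raise ValueError("lambda must be in (0, 1)")
    pi0 = np.count_nonzero(p > lam) / (len(p) * (1.0 - lam))
    return float(min(max(pi0, 0.0), 1.0))


def qvalues(pvals: np.ndarray, pi0: float | None = None, lam: float = 0.5) -> np.ndarray:
    """Storey-Tibshirani q-values with plug-in pi0 (BH when pi0 = 1).

    Monotone step-up: q_(i) = min_{j >= i} pi0 * m * p_(j) / j, capped at 1.
    """
    p = np.asarray(pvals, float)
    if len(p) == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    if pi0 is None:
        pi0 = storey_pi0(p, lam)
        if pi0 == 0.0:
            # all p below lambda: fall back to the most conservative in-range value
            pi0 = 1.0 / len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * pi0 * len(p) / np.arange(1, len(p) + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# region calling
# ---------------------------------------------------------------------------

@dataclass
class RegionRecord:
    """A merged run of significant SNPs plus downstream annotations."""

    region_id: str
    chrom: str
    start: int
    end: int
    snp_pos: list[int]
    snp_q: list[float]
    top_pos: int
    top_q: float
    singleton: bool = False
    top_flk_pos: list[int] = field(default_factory=list)
    consistency: str = "indeterminate"   # pass | fail | indeterminate
    genes: list[str] = field(default_factory=list)
    closest_gene: str | None = None
    delta_pi: float | None = None
    classification: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def call_regions(
    scan: pd.DataFrame,
    q_col: str = "q",
    q_max: float = 1e-2,
    merge_gap: int = 50_000,
) -> list[RegionRecord]:
    """Merge SNPs with q < q_max (strict) into regions.

    Consecutive retained SNPs on a chromosome join the same region when
    their distance is strictly less than ``merge_gap``.  The top SNP is the
    lowest q (ties broken by lowest position); single-SNP regions are
    flagged singleton.
    """
    sig = scan[scan[q_col] < q_max].sort_values(["chrom", "pos"])
    regions: list[RegionRecord] = []
    for chrom, sub in sig.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        qv = sub[q_col].to_numpy()
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) >= merge_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for s, e in zip(starts, ends):
            ps, qs = pos[s : e + 1], qv[s : e + 1]
            top_i = np.lexsort((ps, qs))[0]
            regions.append(
                RegionRecord(
                    region_id=f"{chrom}:{ps[0]}-{ps[-1]}",
                    chrom=str(chrom),
                    start=int(ps[0]),
                    end=int(ps[-1]),
                    snp_pos=[int(x) for x in ps],
                    snp_q=[float(x) for x in qs],
                    top_pos=int(ps[top_i]),
                    top_q=float(qs[top_i]),
                    singleton=len(ps) == 1,
                )
            )
    return regions


def top_flk_snps(
    region: RegionRecord, flk_table: pd.DataFrame, p_col: str = "flk_comb_p",
    p_max: float = 1e-4,
) -> list[int]:
    """Member SNP positions with combined FLK p strictly below ``p_max``."""
    sub = flk_table[
        (flk_table["chrom"] == region.chrom)
        & flk_table["pos"].isin(region.snp_pos)
        & (flk_table[p_col] < p_max)
    ]
    return [int(x) for x in sub["pos"]]


# ---------------------------------------------------------------------------
# haplotype-clustering consistency
# ---------------------------------------------------------------------------

def haplotype_consistency(
    region: RegionRecord,
    panel: GenotypePanel,
    min_fraction: float = 0.5,
    include_world_panel: bool = True,
):
    """Heuristic check that the sweep haplotype is shared by the domestic groups.

    Haplotypes over the region's SNPs are clustered with a neighbor-joining
    tree on 1 - fraction-of-identical-alleles distances (midpoint-rooted).
    The region passes when some clade of the tree holds at least
    ``min_fraction`` of the haplotypes of *every* domestic group (world
    panel included when present) and under ``min_fraction`` of the wild
    haplotypes -- i.e. a clade representing a haplotype shared across
    domestic groups but rare in the wilds.  Every clade is inspected, not
    only the root bipartition: with many near-identical swept haplotypes
    the midpoint root frequently falls *inside* the sweep clade, which
    would split it across the root and mask a genuine shared signal.
    Regions with fewer than 2 SNPs are indeterminate.

    Returns (status, newick or None).
    """
    sub = panel.subset_interval(region.chrom, region.start, region.end)
    if sub.n_sites < 2:
        return "indeterminate", None
    roles_wanted = ["domestic_A", "domestic_B"] + (
        ["world_panel"]
        if include_world_panel and any(r == "world_panel" for r in panel.roles.values())
        else []
    )
    hap_ids, hap_group = [], []
    haps = []
    for grp, role in panel.roles.items():
        if role not in roles_wanted + ["wild"]:
            continue
        cols = panel.group_columns(grp)
        H = sub.haplotypes(cols)
        for j in range(H.shape[1]):
            hap_ids.append(f"{grp}.{j}")
            hap_group.append(role)
            haps.append(H[:, j])
    H = np.column_stack(haps)
    ident = (H[:, :, None] == H[:, None, :]).mean(axis=0)
    D = 1.0 - ident
    np.fill_diagonal(D, 0.0)
    tree = nj(DistanceMatrix(D, ids=hap_ids))
    tree = tree.root_at_midpoint()
    role_of = dict(zip(hap_ids, hap_group))
    role_total = {r: hap_group.count(r) for r in set(hap_group)}

    def clade_ok(names: set[str]) -> bool:
        counts: dict[str, int] = {}
        for hid in names:
            role = role_of[hid]
            counts[role] = counts.get(role, 0) + 1
        dom_ok = all(
            counts.get(r, 0) >= min_fraction * role_total.get(r, 0)
            for r in roles_wanted
            if role_total.get(r, 0) > 0
        )
        wild_ok = counts.get("wild", 0) < min_fraction * role_total.get("wild", 1)
        return dom_ok and wild_ok

    status = "fail"
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        names = {t.name for t in node.tips()}
        if clade_ok(names):
            status = "pass"
            break
    return status, _newick(tree)


def _newick(tree) -> str:
    import io as _stdio

    buf = _stdio.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def annotate_regions(
    regions: list[RegionRecord],
    genes: GeneTrack,
    region_flank: int = 50_000,
    gene_flank: int = 5_000,
) -> list[RegionRecord]:
    """Assign genes whose flanked span overlaps the flanked region.

    A gene is assigned when [region.start - region_flank, region.end +
    region_flank] overlaps [gene.start - gene_flank, gene.end + gene_flank].
    The closest gene to the top signal (the lowest-q SNP) is recorded, with
    distance 0 for genes containing it.
    """
    tbl = genes.genes
    for reg in regions:
        sub = tbl[tbl["chrom"] == reg.chrom]
        if len(sub) == 0:
            reg.genes, reg.closest_gene = [], None
            continue
        r0, r1 = reg.start - region_flank, reg.end + region_flank
        g0 = sub["start"].to_numpy() - gene_flank
        g1 = sub["end"].to_numpy() + gene_flank
        hit = (g0 <= r1) & (g1 >= r0)
        reg.genes = [str(n) for n in sub["name"].to_numpy()[hit]]
        if reg.genes:
            dist = np.maximum(
                0, np.maximum(sub["start"].to_numpy() - reg.top_pos,
                              reg.top_pos - sub["end"].to_numpy())
            )
            dist = np.where(hit, dist, np.iinfo(np.int64).max)
            reg.closest_gene = str(sub["name"].to_numpy()[int(np.argmin(dist))])
        else:
            reg.closest_gene = None
    return regions


# ---------------------------------------------------------------------------
# SNP-class distribution comparison
# ---------------------------------------------------------------------------

def class_distribution_test(
    selected_counts: dict[str, int], background_counts: dict[str, int]
) -> tuple[float, float]:
    """Pearson chi-squared of selected SNP-class counts vs background proportions.

    Cells with zero expected count are merged into a pooled category (with a
    warning).  Returns (statistic, p-value).
    """
    labels = list(background_counts)
    obs = np.array([selected_counts.get(k, 0) for k in labels], float)
    bg = np.array([background_counts[k] for k in labels], float)
    if bg.sum() == 0:
        raise ValueError("empty background counts")
    exp = obs.sum() * bg / bg.sum()
    if np.any(exp == 0):
        logger.warning("zero expected count; merging categories")
        keep = exp > 0
        obs = np.append(obs[keep], obs[~keep].sum())
        exp = np.append(exp[keep], 0.0)
        if obs[-1] > 0:
            raise ValueError("observed counts in categories absent from background")
        obs, exp = obs[:-1], exp[:-1]
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    if df <= 0:
        return stat, 1.0
    return stat, float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def regions_to_json(regions: list[RegionRecord], path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in regions], fh, indent=1, sort_keys=True)


def regions_to_bed(regions: list[RegionRecord], path) -> None:
    """BED6+ (0-based half-open) with q-value, classification and genes."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                "\t".join(
                    [
                        r.chrom, str(r.start - 1), str(r.end), r.region_id,
                        f"{r.top_q:.3g}", "+",
                        r.consistency, str(r.classification),
                        ",".join(r.genes) or ".",
                    ]
                )
                + "\n"
            )
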