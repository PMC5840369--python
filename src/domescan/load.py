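"""Delta-pi classification of candidate regions and conservation-weighted load.

Delta-pi contrasts wild and domestic nucleotide diversity in a region,
baseline-corrected by the genome-wide difference:

    delta_pi = (pi_wild - pi_dom)_region - (pi_wild - pi_dom)_genome

with pi_dom the average of the two traditional domestic groups.  A positive
value (lower relative diversity in domestics) indicates directional or
stabilizing selection in the domestic groups; a negative value indicates
relaxed or diversifying selection in domestics, or a sweep in the wilds.

Genetic load weighs each homozygous-derived genotype at an evolutionarily
constrained site (conservation score >= 1.5) by its score, so damage at
strongly constrained positions counts more; heterozygotes are excluded so
no dominance model is needed.  The per-individual total is normalized by
the number of analyzed (constrained, genotyped) positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .combine import RegionRecord
from .io import GenotypePanel, GeneTrack
from .popgen import nucleotide_diversity

logger = logging.getLogger(__name__)

CLASS_DIRECTIONAL = "directional_or_stabilizing_in_domestics"
CLASS_RELAXATION = "relaxation_or_diversifying_or_wild_sweep"


# ---------------------------------------------------------------------------
# delta-pi
# ---------------------------------------------------------------------------

@dataclass
class DeltaPiRecord:
    region_id: str
    pi_wild_region: float
    pi_dom_region: float
    genomewide_term: float
    delta_pi: float
    classification: str


def genomewide_pi_difference(panel: GenotypePanel) -> float:
    """(pi_wild - mean pi of the two domestic groups), genome-wide."""
    wild = panel.group_for_role("wild")
    doms = [panel.group_for_role("domestic_A"), panel.group_for_role("domestic_B")]
    pi_w = nucleotide_diversity(panel, wild)
    pi_d = np.mean([nucleotide_diversity(panel, d) for d in doms])
    return float(pi_w - pi_d)


def delta_pi(
    region: RegionRecord,
    panel: GenotypePanel,
    genomewide_term: float | None = None,
) -> DeltaPiRecord:
    """Delta-pi for one region; sign determines the selection-mode class."""
    if genomewide_term is None:
        genomewide_term = genomewide_pi_difference(panel)
    wild = panel.group_for_role("wild")
    doms = [panel.group_for_role("domestic_A"), panel.group_for_role("domestic_B")]
    pi_w = nucleotide_diversity(panel, wild, region.chrom, region.start, region.end)
    pi_d = float(
        np.mean(
            [
                nucleotide_diversity(panel, d, region.chrom, region.start, region.end)
                for d in doms
            ]
        )
    )
    dpi = (pi_w - pi_d) - genomewide_term
    if not np.isfinite(dpi):
        logger.warning("delta-pi undefined for region %s", region.region_id)
        cls = "undefined"
    else:
        cls = CLASS_DIRECTIONAL if dpi > 0 else CLASS_RELAXATION
    return DeltaPiRecord(region.region_id, pi_w, pi_d, genomewide_term,
                         float(dpi), cls)


def classify_regions(
    regions: list[RegionRecord], panel: GenotypePanel
) -> list[DeltaPiRecord]:
    term = genomewide_pi_difference(panel)
    out = []
    for reg in regions:
        rec = delta_pi(reg, panel, genomewide_term=term)
        reg.delta_pi = rec.delta_pi
        reg.classification = rec.classification
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# genetic load
# ---------------------------------------------------------------------------

@dataclass
class LoadTable:
    per_individual: pd.DataFrame   # total_load, load_per_hom, n_hom_mutated
    gene_load: pd.DataFrame        # genes x individuals
    n_analyzed: int


def individual_load(
    panel: GenotypePanel,
    conservation: pd.DataFrame,
    genes: GeneTrack | None = None,
    constraint_min: float = 1.5,
) -> LoadTable:
    """Per-individual (and optionally per-gene) conservation-weighted load.

    total_load: sum of scores at constrained sites carried homozygous for
    the derived (ALT) allele, divided by the number of analyzed positions
    (constrained sites with genotype data).  load_per_hom: the same score
    sum divided by the individual's count of homozygous genotypes at
    constrained sites -- the per-homozygous-position load used for the
    inbreeding correlation (NaN when an individual has no such site).
    """
    cons = conservation.merge(
        panel.sites.reset_index(), on=["chrom", "pos"], how="inner"
    )
    cons = cons[cons["score"] >= constraint_min]
    idx = cons["index"].to_numpy()
    scores = cons["score"].to_numpy()
    n_analyzed = len(idx)
    if n_analyzed == 0:
        logger.warning("no constrained sites; all load scores are 0")
        zero = pd.DataFrame(
            {"total_load": 0.0, "load_per_hom": np.nan, "n_hom_mutated": 0},
            index=panel.individuals,
        )
        return LoadTable(zero, pd.DataFrame(), 0)

    G = panel.genotypes[idx]                       # (m, n, 2)
    hom_alt = (G[:, :, 0] == 1) & (G[:, :, 1] == 1)
    hom_any = G[:, :, 0] == G[:, :, 1]
    load_sum = scores @ hom_alt
    n_hom = hom_any.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_hom = np.where(n_hom > 0, load_sum / np.maximum(n_hom, 1), np.nan)
    per_ind = pd.DataFrame(
        {
            "total_load": load_sum / n_analyzed,
            "load_per_hom": per_hom,
            "n_hom_mutated": hom_alt.sum(axis=0),
        },
        index=panel.individuals,
    )

    gene_rows = {}
    if genes is not None:
        site_chrom = panel.sites["chrom"].to_numpy()[idx]
        site_pos = panel.sites["pos"].to_numpy()[idx]
        for _, g in genes.genes.iterrows():
            m = (site_chrom == g["chrom"]) & (site_pos >= g["start"]) & (site_pos <= g["end"])
            if not m.any():
                continue
            gene_rows[g["name"]] = scores[m] @ hom_alt[m]
    gene_load = pd.DataFrame(gene_rows, index=panel.individuals).T
    return LoadTable(per_ind, gene_load, n_analyzed)


def gene_load_test(
    load_table: LoadTable,
    panel: GenotypePanel,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene one-sided rank-sum test for excess load in domestics.

    Alternative: domestic individuals carry more load than wild ones.
    Benjamini-Hochberg adjustment; genes with all-zero loads in both groups
    are skipped.  Returns a table with raw p, adjusted p, and significance
    at adjusted p < ``alpha``.
    """
    wild = panel.group_for_role("wild")
    doms = [panel.group_for_role("domestic_A"), panel.group_for_role("domestic_B")]
    wild_ids = panel.group_members(wild)
    dom_ids = [i for d in doms for i in panel.group_members(d)]
    rows = []
    for gene, loads in load_table.gene_load.iterrows():
        w = loads[wild_ids].to_numpy(float)
        d = loads[dom_ids].to_numpy(float)
        if np.all(w == 0) and np.all(d == 0):
            continue
        p = stats.mannwhitneyu(d, w, alternative="greater", method="asymptotic").pvalue
        rows.append((gene, float(p)))
    if not rows:
        return pd.DataFrame(columns=["gene", "p", "p_adj", "significant"])
    tbl = pd.DataFrame(rows, columns=["gene", "p"])
    tbl["p_adj"] = stats.false_discovery_control(tbl["p"], method="bh")
    tbl["significant"] = tbl["p_adj"] < alpha
    return tbl.sort_values("p").reset_index(drop=True)


def load_inbreeding_correlation(
    load_table: LoadTable, F: pd.Series
) -> tuple[float, float]:
    """Pearson correlation of inbreeding F vs load per homozygous position."""
    merged = pd.concat([F.rename("F"), load_table.per_individual["load_per_hom"]],
                       axis=1).dropna()
    x, y = merged["F"].to_numpy(), merged["load_per_hom"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("zero variance; F-load correlation undefined")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
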