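"""Cross-genus stratification, stratified FDR, and the convergence curve.

SNPs of one genus are split into two a-priori strata: *shared* (lying in
the homologous image of the other genus's candidate regions) and *general*
(the rest of the genome).  q-values are computed independently within each
stratum, which raises power in the shared stratum when selection targets
are convergent.

The convergence curve quantifies this: for a grid of region-stringency
thresholds t (q-value scale, default 10 log-spaced points from 0.2 down to
0.002), genus-A regions with minimum member q <= t are mapped to genus-B
coordinates, and the estimated fraction of selected SNPs in the resulting
shared stratum, pi1 = 1 - pi0 (Storey), is recorded.  A positive rank
correlation between stringency (-log t) and pi1 indicates convergent
selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .combine import RegionRecord, call_regions, qvalues, storey_pi0
from .io import HomologyMap

logger = logging.getLogger(__name__)


def mapped_region_intervals(
    regions: list[RegionRecord], hmap: HomologyMap
) -> list[tuple[str, int, int]]:
    """Images of region intervals in the other genus's coordinates."""
    out = []
    for reg in regions:
        ivs = hmap.map_interval(reg.chrom, reg.start, reg.end)
        if not ivs:
            logger.info("region %s entirely unmapped", reg.region_id)
        out.extend(ivs)
    return out


def _in_intervals(snps: pd.DataFrame, intervals) -> np.ndarray:
    mask = np.zeros(len(snps), dtype=bool)
    chrom = snps["chrom"].to_numpy()
    pos = snps["pos"].to_numpy()
    for c, s, e in intervals:
        mask |= (chrom == c) & (pos >= s) & (pos <= e)
    return mask


def assign_strata(
    snps_b: pd.DataFrame, regions_a: list[RegionRecord], hmap: HomologyMap
) -> pd.Series:
    """Label each genus-B SNP ``shared`` or ``general``.

    A SNP is shared iff its position lies in the homologous image of any
    genus-A candidate region; the split is a partition.
    """
    intervals = mapped_region_intervals(regions_a, hmap)
    mask = _in_intervals(snps_b, intervals)
    return pd.Series(np.where(mask, "shared", "general"), index=snps_b.index,
                     name="stratum")


def stratified_qvalues(
    scan: pd.DataFrame,
    strata: pd.Series,
    p_col: str = "p_comb",
    q_max: float = 1e-2,
    merge_gap: int = 50_000,
) -> tuple[pd.DataFrame, list[RegionRecord]]:
    """q-values computed independently per stratum; significant SNPs merged
    into regions with the 50-kb rule.  Returns (table with q_strat column,
    regions)."""
    out = scan.copy()
    out["stratum"] = strata.to_numpy()
    out["q_strat"] = np.nan
    for name, sub in out.groupby("stratum"):
        if len(sub) == 0:
            logger.warning("empty stratum %s skipped", name)
            continue
        out.loc[sub.index, "q_strat"] = qvalues(sub[p_col].to_numpy())
    regions = call_regions(out, q_col="q_strat", q_max=q_max, merge_gap=merge_gap)
    return out, regions


@dataclass
class ConvergenceCurve:
    thresholds: np.ndarray       # strictly decreasing
    n_shared: np.ndarray         # shared-stratum SNP count per threshold
    pi0: np.ndarray              # NaN where undefined (empty stratum)
    pi1: np.ndarray
    spearman_rho: float
    spearman_p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "n_shared": self.n_shared,
                "pi0": self.pi0,
                "pi1": self.pi1,
            }
        )


def default_grid(t_max: float = 0.2, t_min: float = 0.002, n: int = 10) -> np.ndarray:
    return np.geomspace(t_max, t_min, n)


def convergence_curve(
    regions_a: list[RegionRecord],
    scan_b: pd.DataFrame,
    hmap: HomologyMap,
    p_col: str = "p_comb",
    grid: np.ndarray | None = None,
    lam: float = 0.5,
) -> ConvergenceCurve:
    """pi1 in the genus-B shared stratum as genus-A stringency increases.

    Region-level stringency is the minimum member-SNP q.  Undefined points
    (no qualifying region or empty stratum) are excluded from the rank
    correlation but kept in the curve as NaN.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, float)
    n_shared = np.zeros(len(grid), dtype=int)
    pi0 = np.full(len(grid), np.nan)
    pvals = scan_b[p_col].to_numpy()
    for i, t in enumerate(grid):
        sel = [r for r in regions_a if r.top_q <= t]
        if not sel:
            continue
        intervals = mapped_region_intervals(sel, hmap)
        mask = _in_intervals(scan_b, intervals)
        n_shared[i] = int(mask.sum())
        if n_shared[i] == 0:
            continue
        pi0[i] = storey_pi0(pvals[mask], lam=lam)
    pi1 = np.clip(1.0 - pi0, 0.0, 1.0)
    ok = np.isfinite(pi1)
    if ok.sum() >= 3 and np.ptp(pi1[ok]) > 0:
        rho, pval = stats.spearmanr(-np.log(grid[ok]), pi1[ok])
    else:
        rho, pval = float("nan"), float("nan")
    return ConvergenceCurve(grid, n_shared, pi0, pi1, float(rho), float(pval))
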