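"""FLK and hapFLK selection statistics against a kinship drift null.

FLK measures the deviation of single-SNP population allele frequencies from
the neutral drift expectation encoded by the kinship matrix F: with
estimated ancestral frequency p0 (GLS weighted mean), the score is the
quadratic form (p - p0 1)' [p0 (1 - p0) F]^-1 (p - p0 1), asymptotically
chi-squared with n_pops - 1 degrees of freedom under neutrality.

hapFLK applies the same quadratic form to each haplotype-cluster frequency
vector from the LD model and sums over clusters; because its null
distribution is not analytic, scores are calibrated genome-wide by fitting
a scaled chi-squared (a * chi2_d) by trimmed moment matching, with the
trimmed moments corrected for the truncation they introduce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import GenotypePanel
from .ldmodel import ClusterFrequencies, ClusterModel, cluster_frequencies
from .popgen import KinshipModel

logger = logging.getLogger(__name__)

_P0_EPS = 1e-6


def _gls_weights(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    try:
        Finv = np.linalg.inv(F)
    except np.linalg.LinAlgError:
        logger.warning("kinship matrix singular; using pseudo-inverse")
        Finv = np.linalg.pinv(F)
    ones = np.ones(F.shape[0])
    wvec = Finv @ ones
    return Finv, wvec / (ones @ wvec)


def flk_statistic(p: np.ndarray, F: np.ndarray, p0: float | None = None) -> float:
    """FLK score for one SNP (population frequency vector p)."""
    return float(flk_vector(np.asarray(p, float)[None, :], F, p0)[0])


def flk_vector(
    freqs: np.ndarray, F: np.ndarray, p0: float | np.ndarray | None = None
) -> np.ndarray:
    """Vectorized FLK over sites: freqs has shape (n_sites, n_pops)."""
    freqs = np.asarray(freqs, float)
    if not np.all(np.isfinite(freqs)):
        raise ValueError("non-finite population frequencies")
    Finv, w = _gls_weights(np.asarray(F, float))
    if p0 is None:
        p0 = freqs @ w
    else:
        p0 = np.broadcast_to(np.asarray(p0, float), freqs.shape[:1]).copy()
    resid = freqs - p0[:, None]
    quad = np.einsum("si,ij,sj->s", resid, Finv, resid)
    denom = p0 * (1.0 - p0)
    ok = (p0 > _P0_EPS) & (p0 < 1.0 - _P0_EPS)
    out = np.zeros(freqs.shape[0])
    out[ok] = quad[ok] / denom[ok]
    return out


def flk_pvalues(scores: np.ndarray, n_pops: int) -> np.ndarray:
    """Asymptotic chi-squared p-values (df = n_pops - 1)."""
    return stats.chi2.sf(scores, df=n_pops - 1)


def hapflk_statistic(cfreqs: ClusterFrequencies, F: np.ndarray) -> np.ndarray:
    """Per-site hapFLK: cluster-wise FLK quadratic forms summed over clusters,
    averaged over EM runs.  Clusters whose estimated ancestral frequency is
    0 or 1 contribute nothing."""
    n_runs, S, K, n_pops = cfreqs.freqs.shape
    if F.shape != (n_pops, n_pops):
        raise ValueError("kinship and cluster frequencies disagree on populations")
    scores = np.zeros((n_runs, S))
    for run in range(n_runs):
        for k in range(K):
            scores[run] += flk_vector(cfreqs.freqs[run, :, k, :], F)
    return scores.mean(axis=0)


# ---------------------------------------------------------------------------
# chi-squared calibration
# ---------------------------------------------------------------------------

@dataclass
class Chi2Fit:
    scale: float
    df: float
    trim_upper: float

    def pvalues(self, scores: np.ndarray) -> np.ndarray:
        return stats.chi2.sf(np.asarray(scores, float) / self.scale, df=self.df)


def _truncated_chi2_moments(d: float, keep: float) -> tuple[float, float]:
    """Mean and variance of chi2_d conditional on X <= its ``keep`` quantile."""
    t = stats.chi2.ppf(keep, d)
    m1 = d * stats.chi2.cdf(t, d + 2) / keep
    m2 = d * (d + 2) * stats.chi2.cdf(t, d + 4) / keep
    return m1, m2 - m1 * m1


def fit_chi2(scores: np.ndarray, trim_upper: float = 0.01) -> tuple[Chi2Fit, np.ndarray]:
    """Fit a * chi2_d to scores by trimmed moment matching; return fit + p-values.

    The top ``trim_upper`` fraction of scores is removed so true sweeps do
    not inflate the null fit; the estimator then matches the mean and
    variance of the *truncated* scaled chi-squared, which removes the bias
    the trimming would otherwise introduce.  p-values are upper-tail
    probabilities for all (untrimmed) scores.
    """
    scores = np.asarray(scores, float)
    m = len(scores)
    if m < 1000:
        logger.warning("fit_chi2 on only %d scores; calibration may be poor", m)
    keep = 1.0 - trim_upper
    t_emp = np.quantile(scores, keep)
    trimmed = scores[scores <= t_emp]
    mean_t = float(trimmed.mean())
    var_t = float(trimmed.var())
    if var_t == 0.0:
        raise ValueError("zero variance in trimmed scores; cannot calibrate")
    ratio_obs = var_t / (mean_t * mean_t)

    def g(d):
        m1, v = _truncated_chi2_moments(d, keep)
        return v / (m1 * m1) - ratio_obs

    lo, hi = 0.05, 500.0
    if g(lo) < 0:       # heavier-tailed than chi2_0.05: clamp
        d_hat = lo
    elif g(hi) > 0:
        d_hat = hi
    else:
        d_hat = optimize.brentq(g, lo, hi, xtol=1e-8)
    m1, _ = _truncated_chi2_moments(d_hat, keep)
    a_hat = mean_t / m1
    fit = Chi2Fit(scale=a_hat, df=d_hat, trim_upper=trim_upper)
    return fit, fit.pvalues(scores)


# ---------------------------------------------------------------------------
# per-contrast scan
# ---------------------------------------------------------------------------

def run_contrast(
    panel: GenotypePanel,
    wild_group: str,
    domestic_group: str,
    kinship: KinshipModel,
    cluster_models: list[ClusterModel] | None = None,
    cfreqs: ClusterFrequencies | None = None,
    trim_upper: float = 0.01,
) -> pd.DataFrame:
    """hapFLK + FLK scan of one wild-vs-domestic contrast.

    Uses the 2x2 submatrix of the kinship covariance for the two groups.
    Both statistics are calibrated genome-wide with the fitted chi-squared.
    Returns a per-SNP table with columns chrom, pos, hapflk, hapflk_p,
    flk, flk_p.
    """
    for g, label in ((wild_group, "wild"), (domestic_group, "domestic")):
        if len(panel.group_columns(g)) < 2:
            raise ValueError(f"{label} group {g} has fewer than 2 individuals")
    pops = [wild_group, domestic_group]
    F = kinship.submatrix(pops)
    if cfreqs is None:
        if cluster_models is None:
            raise ValueError("need cluster_models or precomputed cfreqs")
        cfreqs = cluster_frequencies(cluster_models, panel, pops)
    else:
        sel = [cfreqs.populations.index(p) for p in pops]
        cfreqs = ClusterFrequencies(
            cfreqs.freqs[:, :, :, sel], pops, cfreqs.sites
        )
    hap_scores = hapflk_statistic(cfreqs, F)
    _, hap_p = fit_chi2(hap_scores, trim_upper=trim_upper)

    freqs = np.column_stack([panel.alt_freq(g) for g in pops])
    flk_scores = flk_vector(freqs, F)
    _, flk_p = fit_chi2(flk_scores, trim_upper=trim_upper)

    return pd.DataFrame(
        {
            "chrom": panel.sites["chrom"],
            "pos": panel.sites["pos"],
            "hapflk": hap_scores,
            "hapflk_p": hap_p,
            "flk": flk_scores,
            "flk_p": flk_p,
        }
    )
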