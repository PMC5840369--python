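"""Haplotype-cluster hidden Markov model (Scheet-Stephens / fastPHASE style).

Local haplotype structure is summarized by K latent clusters.  Along a
chromosome, each haplotype follows a Markov chain over clusters: between
adjacent sites it keeps its cluster or, with interval-specific switch
probability rho, redraws one from the site-specific cluster weights w.
Cluster k emits the ALT allele at site s with probability alpha[s, k].

For unphased genotypes the hidden state of an individual is a cluster
*pair*; the two components transition independently and the genotype
emission is the convolution of the two allele emissions, so phase
uncertainty is integrated out exactly rather than resolved by
pseudo-phasing.

Fitting is by EM (Baum-Welch with the jump parameterization), which gives a
monotone non-decreasing log-likelihood.  Several independent EM runs from
seeded random starts are kept; downstream haplotype-frequency statistics
average over runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .io import GenotypePanel

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class ChromModel:
    positions: np.ndarray   # (S,)
    alpha: np.ndarray       # (S, K) ALT emission frequency per cluster
    w: np.ndarray           # (S, K) cluster weights; w[0] is the initial law
    rho: np.ndarray         # (S,) switch probability into site s (rho[0] = 1)


@dataclass
class ClusterModel:
    K: int
    chrom_models: dict[str, ChromModel]
    loglik_history: list[float] = field(default_factory=list)
    seed: int = 0

    @property
    def loglik(self) -> float:
        return self.loglik_history[-1]


@dataclass
class ClusterFrequencies:
    """Expected cluster frequencies: (n_runs, n_sites, K, n_populations)."""

    freqs: np.ndarray
    populations: list[str]
    sites: pd.DataFrame


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _init_chrom(rng, positions, site_freq, K) -> ChromModel:
    S = len(positions)
    alpha = np.clip(
        site_freq[:, None] + rng.normal(0, 0.15, size=(S, K)), 1e-3, 1 - 1e-3
    )
    w = 1.0 + 0.2 * rng.random((S, K))
    w /= w.sum(axis=1, keepdims=True)
    rho = np.empty(S)
    rho[0] = 1.0
    if S > 1:
        dist = np.diff(positions).astype(float)
        rho[1:] = np.clip(1.0 - np.exp(-1e-5 * dist), 1e-4, 0.2)
    return ChromModel(np.asarray(positions), alpha, w, rho)


# ---------------------------------------------------------------------------
# phased forward-backward + EM accumulators
# ---------------------------------------------------------------------------

def _emission_hap(alpha_s: np.ndarray, x_s: np.ndarray) -> np.ndarray:
    return np.where(x_s[:, None] == 1, alpha_s[None, :], 1.0 - alpha_s[None, :])


def _forward_hap(cm: ChromModel, H: np.ndarray):
    S, K = cm.alpha.shape
    n = H.shape[1]
    f = np.empty((S, n, K))
    c = np.empty((S, n))
    e = _emission_hap(cm.alpha[0], H[0])
    f0 = cm.w[0][None, :] * e
    c[0] = f0.sum(axis=1)
    f[0] = f0 / c[0][:, None]
    for s in range(1, S):
        r = cm.rho[s]
        pred = (1.0 - r) * f[s - 1] + r * cm.w[s][None, :]
        fs = pred * _emission_hap(cm.alpha[s], H[s])
        c[s] = fs.sum(axis=1)
        f[s] = fs / c[s][:, None]
    return f, c


def _estep_hap(cm: ChromModel, H: np.ndarray):
    """One E-step over phased haplotypes. Returns (loglik, accumulators)."""
    S, K = cm.alpha.shape
    n = H.shape[1]
    f, c = _forward_hap(cm, H)
    ll = float(np.log(c).sum())
    b = np.ones((n, K))
    a_num = np.zeros((S, K))
    a_den = np.zeros((S, K))
    jump = np.zeros((S, K))
    for s in range(S - 1, -1, -1):
        e = _emission_hap(cm.alpha[s], H[s])
        g = f[s] * b
        g /= g.sum(axis=1, keepdims=True)
        x = (H[s] == 1).astype(float)
        a_num[s] = (g * x[:, None]).sum(axis=0)
        a_den[s] = g.sum(axis=0)
        if s > 0:
            r = cm.rho[s]
            jump[s] = (
                r * cm.w[s][None, :] * e * b / c[s][:, None]
            ).sum(axis=0)
            eb = e * b
            b = ((1.0 - r) * eb + r * (eb @ cm.w[s])[:, None]) / c[s][:, None]
        else:
            jump[0] = g.sum(axis=0)
    return ll, (a_num, a_den, jump, float(n))


# ---------------------------------------------------------------------------
# unphased (genotype pair-state) forward-backward + EM accumulators
# ---------------------------------------------------------------------------

def _emission_geno(alpha_s: np.ndarray, g_s: np.ndarray) -> np.ndarray:
    """(N, K, K) genotype emission for one site."""
    a = alpha_s
    M0 = np.multiply.outer(1 - a, 1 - a)
    M1 = np.multiply.outer(a, 1 - a)
    M1 = M1 + M1.T
    M2 = np.multiply.outer(a, a)
    out = np.empty((len(g_s),) + M0.shape)
    out[g_s == 0] = M0
    out[g_s == 1] = M1
    out[g_s == 2] = M2
    return out


def _predict_pair(fprev: np.ndarray, w: np.ndarray, r: float) -> np.ndarray:
    colsum = fprev.sum(axis=1)              # over first component
    B = (1 - r) * fprev + r * w[None, :, None] * colsum[:, None, :]
    rowsum = B.sum(axis=2)
    return (1 - r) * B + r * rowsum[:, :, None] * w[None, None, :]


def _forward_geno(cm: ChromModel, G: np.ndarray):
    S, K = cm.alpha.shape
    N = G.shape[1]
    f = np.empty((S, N, K, K))
    c = np.empty((S, N))
    e = _emission_geno(cm.alpha[0], G[0])
    f0 = np.multiply.outer(cm.w[0], cm.w[0])[None] * e
    c[0] = f0.sum(axis=(1, 2))
    f[0] = f0 / c[0][:, None, None]
    for s in range(1, S):
        pred = _predict_pair(f[s - 1], cm.w[s], cm.rho[s])
        fs = pred * _emission_geno(cm.alpha[s], G[s])
        c[s] = fs.sum(axis=(1, 2))
        f[s] = fs / c[s][:, None, None]
    return f, c


def _estep_geno(cm: ChromModel, G: np.ndarray):
    S, K = cm.alpha.shape
    N = G.shape[1]
    f, c = _forward_geno(cm, G)
    ll = float(np.log(c).sum())
    b = np.ones((N, K, K))
    a_num = np.zeros((S, K))
    a_den = np.zeros((S, K))
    jump = np.zeros((S, K))
    for s in range(S - 1, -1, -1):
        a = cm.alpha[s]
        e = _emission_geno(a, G[s])
        g = f[s] * b
        g /= g.sum(axis=(1, 2), keepdims=True)
        g1 = g.sum(axis=2)   # first-component marginal (N, K)
        g2 = g.sum(axis=1)
        a_den[s] = (g1 + g2).sum(axis=0)
        het = G[s] == 1
        num_s = np.zeros(K)
        hom = G[s] == 2
        if hom.any():
            num_s += (g1[hom] + g2[hom]).sum(axis=0)
        if het.any():
            W1 = np.multiply.outer(a, 1 - a)
            denomM = W1 + W1.T
            with np.errstate(invalid="ignore", divide="ignore"):
                R = np.where(denomM > 0, W1 / np.maximum(denomM, _EPS), 0.5)
            gh = g[het]
            num_s += np.einsum("nij,ij->i", gh, R)
            num_s += np.einsum("nij,ij->j", gh, 1.0 - R)
        a_num[s] = num_s
        if s > 0:
            r = cm.rho[s]
            u = f[s - 1].sum(axis=1)                      # (N, K) second-comp marginal
            v = (1 - r) * u + r * cm.w[s][None, :]
            u2 = f[s - 1].sum(axis=2)
            v2 = (1 - r) * u2 + r * cm.w[s][None, :]
            eb = e * b / c[s][:, None, None]
            # component-1 jump into k1; component-2 jump into k2
            jump[s] = r * cm.w[s] * np.einsum("nj,nkj->k", v, eb)
            jump[s] += r * cm.w[s] * np.einsum("nj,njk->k", v2, eb)
            # backward recursion
            M = e * b
            wM = np.einsum("k,nkj->nj", cm.w[s], M)
            B = (1 - r) * M + r * wM[:, None, :]
            Bw = np.einsum("njk,k->nj", B, cm.w[s])
            b = ((1 - r) * B + r * Bw[:, :, None]) / c[s][:, None, None]
        else:
            jump[0] = (g1 + g2).sum(axis=0)
    return ll, (a_num, a_den, jump, 2.0 * N)


# ---------------------------------------------------------------------------
# compiled unphased kernels (identical math to _estep_geno; used by default
# because the pair-state recursion is the pipeline's hot loop)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _geno_emission_scalar(g, a1, a2):
    if g == 0:
        return (1.0 - a1) * (1.0 - a2)
    if g == 1:
        return a1 * (1.0 - a2) + (1.0 - a1) * a2
    return a1 * a2


@njit(cache=True)
def _geno_forward_kernel(G, alpha, w, rho):
    S, N = G.shape
    K = alpha.shape[1]
    f = np.empty((S, N, K, K))
    c = np.empty((S, N))
    for n in range(N):
        g = G[0, n]
        tot = 0.0
        for k1 in range(K):
            for k2 in range(K):
                v = w[0, k1] * w[0, k2] * _geno_emission_scalar(
                    g, alpha[0, k1], alpha[0, k2]
                )
                f[0, n, k1, k2] = v
                tot += v
        c[0, n] = tot
        for k1 in range(K):
            for k2 in range(K):
                f[0, n, k1, k2] /= tot
    B = np.empty((K, K))
    colsum = np.empty(K)
    rowsum = np.empty(K)
    for s in range(1, S):
        r = rho[s]
        for n in range(N):
            for j2 in range(K):
                acc = 0.0
                for j1 in range(K):
                    acc += f[s - 1, n, j1, j2]
                colsum[j2] = acc
            for k1 in range(K):
                rs = 0.0
                for j2 in range(K):
                    val = (1.0 - r) * f[s - 1, n, k1, j2] + r * w[s, k1] * colsum[j2]
                    B[k1, j2] = val
                    rs += val
                rowsum[k1] = rs
            g = G[s, n]
            tot = 0.0
            for k1 in range(K):
                for k2 in range(K):
                    pred = (1.0 - r) * B[k1, k2] + r * rowsum[k1] * w[s, k2]
                    v = pred * _geno_emission_scalar(g, alpha[s, k1], alpha[s, k2])
                    f[s, n, k1, k2] = v
                    tot += v
            c[s, n] = tot
            inv = 1.0 / tot
            for k1 in range(K):
                for k2 in range(K):
                    f[s, n, k1, k2] *= inv
    return f, c


@njit(cache=True)
def _geno_estep_kernel(G, alpha, w, rho):
    S, N = G.shape
    K = alpha.shape[1]
    f, c = _geno_forward_kernel(G, alpha, w, rho)
    ll = 0.0
    for s in range(S):
        for n in range(N):
            ll += np.log(c[s, n])
    a_num = np.zeros((S, K))
    a_den = np.zeros((S, K))
    jump = np.zeros((S, K))
    b = np.ones((N, K, K))
    M = np.empty((K, K))
    wM = np.empty(K)
    Bw = np.empty(K)
    u = np.empty(K)
    u2 = np.empty(K)
    for s in range(S - 1, -1, -1):
        r = rho[s]
        for n in range(N):
            g = G[s, n]
            tot = 0.0
            for k1 in range(K):
                for k2 in range(K):
                    tot += f[s, n, k1, k2] * b[n, k1, k2]
            inv = 1.0 / tot
            for k1 in range(K):
                a1 = alpha[s, k1]
                for k2 in range(K):
                    gm = f[s, n, k1, k2] * b[n, k1, k2] * inv
                    a_den[s, k1] += gm
                    a_den[s, k2] += gm
                    if g == 2:
                        a_num[s, k1] += gm
                        a_num[s, k2] += gm
                    elif g == 1:
                        a2 = alpha[s, k2]
                        w1 = a1 * (1.0 - a2)
                        w2 = (1.0 - a1) * a2
                        den = w1 + w2
                        if den > 0.0:
                            a_num[s, k1] += gm * w1 / den
                            a_num[s, k2] += gm * w2 / den
                        else:
                            a_num[s, k1] += gm * 0.5
                            a_num[s, k2] += gm * 0.5
                    if s == 0:
                        jump[0, k1] += gm
                        jump[0, k2] += gm
            if s > 0:
                for j2 in range(K):
                    acc = 0.0
                    acc2 = 0.0
                    for j1 in range(K):
                        acc += f[s - 1, n, j1, j2]
                        acc2 += f[s - 1, n, j2, j1]
                    u[j2] = (1.0 - r) * acc + r * w[s, j2]
                    u2[j2] = (1.0 - r) * acc2 + r * w[s, j2]
                cinv = 1.0 / c[s, n]
                for k1 in range(K):
                    a1 = alpha[s, k1]
                    for k2 in range(K):
                        e = _geno_emission_scalar(g, a1, alpha[s, k2])
                        eb = e * b[n, k1, k2] * cinv
                        jump[s, k1] += r * w[s, k1] * u[k2] * eb
                        jump[s, k2] += r * w[s, k2] * u2[k1] * eb
                        M[k1, k2] = e * b[n, k1, k2]
                for j in range(K):
                    acc = 0.0
                    for k in range(K):
                        acc += w[s, k] * M[k, j]
                    wM[j] = acc
                for j1 in range(K):
                    acc = 0.0
                    for k in range(K):
                        acc += ((1.0 - r) * M[j1, k] + r * wM[k]) * w[s, k]
                    Bw[j1] = acc
                for j1 in range(K):
                    for j2 in range(K):
                        Bj = (1.0 - r) * M[j1, j2] + r * wM[j2]
                        b[n, j1, j2] = ((1.0 - r) * Bj + r * Bw[j1]) * cinv
    return ll, a_num, a_den, jump


@njit(cache=True)
def _geno_dosage_kernel(G, alpha, w, rho):
    S, N = G.shape
    K = alpha.shape[1]
    f, c = _geno_forward_kernel(G, alpha, w, rho)
    out = np.empty((S, N, K))
    b = np.ones((N, K, K))
    M = np.empty((K, K))
    wM = np.empty(K)
    Bw = np.empty(K)
    for s in range(S - 1, -1, -1):
        r = rho[s]
        for n in range(N):
            g = G[s, n]
            tot = 0.0
            for k1 in range(K):
                for k2 in range(K):
                    tot += f[s, n, k1, k2] * b[n, k1, k2]
            inv = 1.0 / tot
            for k in range(K):
                out[s, n, k] = 0.0
            for k1 in range(K):
                for k2 in range(K):
                    gm = f[s, n, k1, k2] * b[n, k1, k2] * inv
                    out[s, n, k1] += gm
                    out[s, n, k2] += gm
            if s > 0:
                cinv = 1.0 / c[s, n]
                for k1 in range(K):
                    a1 = alpha[s, k1]
                    for k2 in range(K):
                        M[k1, k2] = _geno_emission_scalar(
                            g, a1, alpha[s, k2]
                        ) * b[n, k1, k2]
                for j in range(K):
                    acc = 0.0
                    for k in range(K):
                        acc += w[s, k] * M[k, j]
                    wM[j] = acc
                for j1 in range(K):
                    acc = 0.0
                    for k in range(K):
                        acc += ((1.0 - r) * M[j1, k] + r * wM[k]) * w[s, k]
                    Bw[j1] = acc
                for j1 in range(K):
                    for j2 in range(K):
                        Bj = (1.0 - r) * M[j1, j2] + r * wM[j2]
                        b[n, j1, j2] = ((1.0 - r) * Bj + r * Bw[j1]) * cinv
    return out


def _estep_geno_fast(cm: ChromModel, G: np.ndarray):
    ll, a_num, a_den, jump = _geno_estep_kernel(
        np.ascontiguousarray(G), cm.alpha, cm.w, cm.rho
    )
    return ll, (a_num, a_den, jump, 2.0 * G.shape[1])


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------

def _mstep(cm: ChromModel, acc) -> None:
    a_num, a_den, jump, n_chain = acc
    S = cm.alpha.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(a_den > _EPS, a_num / np.maximum(a_den, _EPS), cm.alpha)
    cm.alpha = np.clip(alpha, _EPS, 1.0 - _EPS)
    tot = jump.sum(axis=1)
    for s in range(S):
        if tot[s] > _EPS:
            cm.w[s] = np.maximum(jump[s] / tot[s], _EPS)
            cm.w[s] /= cm.w[s].sum()
    if S > 1:
        cm.rho[1:] = np.clip(tot[1:] / n_chain, _EPS, 1.0 - _EPS)


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------

def _chrom_data(panel: GenotypePanel, phased: bool):
    """Split the panel into per-chromosome observation matrices."""
    out = {}
    for chrom, sub in panel.sites.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        if phased:
            obs = panel.haplotypes()[idx]
        else:
            obs = panel.alt_dosage()[idx]
        out[chrom] = (sub["pos"].to_numpy(), obs)
    return out


def fit_cluster_model(
    panel: GenotypePanel,
    K: int = 25,
    n_em_runs: int = 5,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int = 0,
    phased: bool | None = None,
) -> list[ClusterModel]:
    """Fit ``n_em_runs`` independent EM runs of the K-cluster model.

    ``phased=None`` uses the panel's phase flag; ``phased=False`` trains on
    genotypes with exact pair-state phase integration.  Convergence is
    declared when the relative log-likelihood change drops below ``tol`` or
    after ``max_iter`` iterations.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if phased is None:
        phased = panel.phased
    n_chains = 2 * panel.n_individuals
    if n_chains < 2 * K:
        logger.warning("fewer than 2K haplotypes (%d < %d); fit may be unstable",
                       n_chains, 2 * K)
    data = _chrom_data(panel, phased)
    site_freq = panel.alt_freq()
    estep = _estep_hap if phased else _estep_geno_fast

    models = []
    for run in range(n_em_runs):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), run]))
        cms = {}
        for chrom, sub in panel.sites.groupby("chrom", sort=False):
            idx = sub.index.to_numpy()
            cms[chrom] = _init_chrom(rng, data[chrom][0], site_freq[idx], K)
        history = []
        for it in range(max_iter):
            total = 0.0
            for chrom, cm in cms.items():
                ll, acc = estep(cm, data[chrom][1])
                _mstep(cm, acc)
                total += ll
            if not np.isfinite(total):
                raise FloatingPointError(
                    f"non-finite log-likelihood in EM run {run}, iter {it}"
                )
            history.append(total)
            if len(history) > 1:
                rel = (history[-1] - history[-2]) / max(1.0, abs(history[-2]))
                if abs(rel) < tol:
                    break
        models.append(ClusterModel(K, cms, history, seed=run))
        logger.info("EM run %d: loglik %.2f after %d iterations",
                    run, history[-1], len(history))
    return models


def model_loglik(model: ClusterModel, panel: GenotypePanel, phased: bool | None = None) -> float:
    """Log-likelihood of a (possibly held-out) panel under a fitted model."""
    if phased is None:
        phased = panel.phased
    data = _chrom_data(panel, phased)
    total = 0.0
    for chrom, cm in model.chrom_models.items():
        obs = data[chrom][1]
        if phased:
            _, c = _forward_hap(cm, obs)
        else:
            _, c = _forward_geno(cm, obs)
        total += float(np.log(c).sum())
    return total


# ---------------------------------------------------------------------------
# population cluster frequencies
# ---------------------------------------------------------------------------

def _posterior_cluster_dosage(cm: ChromModel, obs: np.ndarray, phased: bool) -> np.ndarray:
    """Expected per-chain cluster membership (S, n_chains_or_N, K).

    Phased: per-haplotype posterior gamma.  Unphased: per-individual sum of
    the two component marginals (values sum to 2 over clusters).
    """
    S, K = cm.alpha.shape
    if phased:
        f, c = _forward_hap(cm, obs)
        n = obs.shape[1]
        b = np.ones((n, K))
        out = np.empty((S, n, K))
        for s in range(S - 1, -1, -1):
            g = f[s] * b
            out[s] = g / g.sum(axis=1, keepdims=True)
            if s > 0:
                r = cm.rho[s]
                eb = _emission_hap(cm.alpha[s], obs[s]) * b
                b = ((1 - r) * eb + r * (eb @ cm.w[s])[:, None]) / c[s][:, None]
        return out
    return _geno_dosage_kernel(np.ascontiguousarray(obs), cm.alpha, cm.w, cm.rho)


def cluster_frequencies(
    models: list[ClusterModel],
    panel: GenotypePanel,
    populations: list[str],
    phased: bool | None = None,
) -> ClusterFrequencies:
    """Per-run expected cluster frequencies per site and population.

    Frequencies are posterior cluster memberships from the forward-backward
    pass, averaged over the chains (haplotypes, or individual pair
    components) of each population; they sum to 1 over clusters.
    """
    if phased is None:
        phased = panel.phased
    for pop in populations:
        panel.group_columns(pop)  # raises if absent
    K = models[0].K
    n_runs = len(models)
    freqs = np.empty((n_runs, panel.n_sites, K, len(populations)))
    for run, model in enumerate(models):
        row0 = 0
        for chrom, sub in panel.sites.groupby("chrom", sort=False):
            idx = sub.index.to_numpy()
            cm = model.chrom_models[chrom]
            for p, pop in enumerate(populations):
                cols = panel.group_columns(pop)
                if phased:
                    obs = panel.haplotypes(cols)[idx]
                    dos = _posterior_cluster_dosage(cm, obs, True)
                    freqs[run, idx, :, p] = dos.mean(axis=1)
                else:
                    obs = panel.alt_dosage(cols)[idx]
                    dos = _posterior_cluster_dosage(cm, obs, False)
                    freqs[run, idx, :, p] = dos.sum(axis=1) / (2.0 * len(cols))
            row0 += len(idx)
    return ClusterFrequencies(freqs, list(populations), panel.sites)
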