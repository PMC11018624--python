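"""Site-frequency spectra and diversity from genotype likelihoods.

The chain is the standard low-coverage one: per-site *site allele frequency*
(SAF) likelihoods marginalize individual genotypes onto the population
minor-allele count j = 0..2N; an EM over sites estimates the (folded) SFS;
the SFS then acts as an empirical-Bayes prior giving per-site posterior
expectations of pairwise diversity pi and of the segregating-site indicator
(Watterson's theta), which are summed in sliding windows and combined into
Tajima's D.  No hard genotype calls are ever made.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .glmodel import GLMatrix
from .windows import sliding_windows


@dataclass
class SAFMatrix:
    """Per-site log-likelihoods over population minor-allele counts.

    ``values[s, j]`` = log L(minor-allele count = j at site s), j = 0..2N,
    max-normalized per site.  ``folded`` marks a matrix whose classes are
    the folded ones j = 0..N (class j pooled with 2N-j).
    """

    sites: pd.DataFrame  # chrom, pos
    values: np.ndarray  # (S, 2N+1) or (S, N+1) if folded
    n_chromosomes: int  # 2N
    folded: bool = False

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    def fold(self) -> "SAFMatrix":
        """Pool symmetric classes j and 2N-j (even 2N assumed: N diploids)."""
        if self.folded:
            return self
        lin = np.exp(self.values)
        n = self.n_chromosomes
        half = n // 2
        folded = lin[:, : half + 1].copy()
        folded[:, :half] += lin[:, : half - 1 - n : -1]
        with np.errstate(divide="ignore"):
            out = np.log(folded)
        out -= out.max(axis=1, keepdims=True)
        return SAFMatrix(self.sites, out, n, folded=True)


@dataclass
class SFS:
    """Expected number of sites per allele-count class."""

    counts: np.ndarray
    folded: bool
    n_chromosomes: int
    loglik_trace: np.ndarray | None = None

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def saf_likelihoods(gls: GLMatrix, individuals=None) -> SAFMatrix:
    """SAF by iterative convolution of per-individual GL triplets.

    The likelihood of total minor count j is the convolution over
    individuals of L_i(g) C(2, g), divided by C(2N, j) — the exact sum over
    genotype configurations weighted by the hypergeometric probability of
    each configuration given j.
    """
    values = gls.values if individuals is None else gls.values[:, individuals]
    S, N, _ = values.shape
    if N < 1:
        raise ValueError("need at least one individual")
    w = np.exp(values) * np.array([1.0, 2.0, 1.0])
    conv = np.zeros((S, 2 * N + 1))
    conv[:, 0] = 1.0
    length = 1
    for i in range(N):
        new = np.zeros_like(conv)
        new[:, :length] = conv[:, :length] * w[:, i, 0:1]
        new[:, 1 : length + 1] += conv[:, :length] * w[:, i, 1:2]
        new[:, 2 : length + 2] += conv[:, :length] * w[:, i, 2:3]
        conv = new
        length += 2
        # guard against overflow on long convolutions
        m = conv.max(axis=1, keepdims=True)
        conv /= np.where(m == 0, 1.0, m)
    j = np.arange(2 * N + 1)
    log_choose = gammaln(2 * N + 1) - gammaln(j + 1) - gammaln(2 * N - j + 1)
    with np.errstate(divide="ignore"):
        out = np.log(conv) - log_choose
    out -= out.max(axis=1, keepdims=True)
    return SAFMatrix(sites=gls.sites[["chrom", "pos"]].copy(), values=out, n_chromosomes=2 * N)


def estimate_sfs(saf: SAFMatrix, folded: bool = True, tol: float = 1e-6, max_iter: int = 500) -> SFS:
    """Maximum-likelihood SFS by EM over sites (realSFS-style).

    Maximizes sum_s log sum_j SFS_j SAF_s(j) over the probability simplex;
    the log-likelihood is non-decreasing at every iteration and iteration
    stops at an increase below ``tol``.  Counts are scaled to the number of
    input sites.
    """
    work = saf.fold() if (folded and not saf.folded) else saf
    lik = np.exp(work.values)  # (S, m)
    S, m = lik.shape
    if np.allclose(lik, lik[:, :1]):
        warnings.warn("all SAF vectors flat: returning uniform SFS")
        return SFS(np.full(m, S / m), folded, saf.n_chromosomes, np.array([]))
    sfs = np.full(m, 1.0 / m)
    trace = []
    for _ in range(max_iter):
        w = lik * sfs
        tot = w.sum(axis=1, keepdims=True)
        trace.append(np.log(tot).sum())
        post = w / tot
        new = post.mean(axis=0)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            sfs = new
            break
        sfs = new
    return SFS(sfs * S, folded, saf.n_chromosomes, np.array(trace))


@dataclass
class ThetaTrack:
    """Per-site posterior expectations of pi and the Watterson increment."""

    sites: pd.DataFrame  # chrom, pos
    pi: np.ndarray
    theta_w: np.ndarray
    p_segregating: np.ndarray
    n_chromosomes: int


def tajima_constants(n: int) -> dict:
    """Tajima's normalization constants for sample size n chromosomes."""
    if n < 2:
        raise ValueError("need n >= 2 chromosomes")
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def per_site_thetas(saf: SAFMatrix, sfs_prior: SFS) -> ThetaTrack:
    """Posterior E[pi] and E[theta_W contribution] per site.

    The posterior over the allele count is P(j) ~ SFS_j SAF(j); then
    E[pi] = sum_j P(j) 2 j (2N - j) / (2N (2N - 1)) and the Watterson
    increment is P(segregating) / a1.
    """
    work = saf.fold() if sfs_prior.folded and not saf.folded else saf
    n = saf.n_chromosomes
    if sfs_prior.n_chromosomes != n:
        raise ValueError("SFS and SAF sample sizes differ")
    lik = np.exp(work.values)
    w = lik * sfs_prior.proportions
    post = w / w.sum(axis=1, keepdims=True)
    j = np.arange(work.values.shape[1])
    pi_j = 2.0 * j * (n - j) / (n * (n - 1.0))
    pi = post @ pi_j
    if sfs_prior.folded:
        p_seg = 1.0 - post[:, 0]
    else:
        p_seg = 1.0 - post[:, 0] - post[:, -1]
    a1 = tajima_constants(n)["a1"]
    return ThetaTrack(
        sites=work.sites.copy(), pi=pi, theta_w=p_seg / a1, p_segregating=p_seg, n_chromosomes=n
    )


def tajimas_d(pi_sum: float, theta_w_sum: float, s_count: float, n: int) -> float:
    """Tajima's D from window totals; NaN when no segregating sites."""
    if s_count <= 0:
        return float("nan")
    c = tajima_constants(n)
    var = c["e1"] * s_count + c["e2"] * s_count * (s_count - 1.0)
    if var <= 0:
        return float("nan")
    return (pi_sum - theta_w_sum) / np.sqrt(var)


def windowed_diversity(thetas: ThetaTrack, window_bp: int = 10_000, step_bp: int = 5_000) -> pd.DataFrame:
    """Window pi, Watterson's theta and Tajima's D.

    ``pi`` / ``theta_w`` columns are per evaluated site (sums divided by
    ``n_sites``); ``pi_sum`` / ``theta_w_sum`` are the raw totals; ``S`` is
    the expected number of segregating sites.  Windows with S = 0 report D
    as NaN, never 0.
    """
    rows = []
    for chrom, start, end, idx in sliding_windows(
        thetas.sites["chrom"].to_numpy(), thetas.sites["pos"].to_numpy(), window_bp, step_bp
    ):
        n_sites = idx.size
        pi_sum = float(thetas.pi[idx].sum())
        tw_sum = float(thetas.theta_w[idx].sum())
        s_count = float(thetas.p_segregating[idx].sum())
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "n_sites": n_sites,
                "pi_sum": pi_sum,
                "theta_w_sum": tw_sum,
                "S": s_count,
                "pi": pi_sum / n_sites if n_sites else float("nan"),
                "theta_w": tw_sum / n_sites if n_sites else float("nan"),
                "tajimas_d": tajimas_d(pi_sum, tw_sum, s_count, thetas.n_chromosomes),
            }
        )
    return pd.DataFrame(rows)


def genomewide_tajimas_d(thetas: ThetaTrack) -> float:
    """Tajima's D from genomewide totals (alternative to per-window D)."""
    return tajimas_d(
        float(thetas.pi.sum()), float(thetas.theta_w.sum()),
        float(thetas.p_segregating.sum()), thetas.n_chromosomes,
    )


def estimate_ne(theta_per_site: float, mu: float) -> float:
    """Effective population size Ne = theta / (4 mu)."""
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    return theta_per_site / (4.0 * mu)


def write_sfs(sfs: SFS, path) -> None:
    np.savetxt(path, sfs.counts[None], fmt="%.6f")


def read_sfs(path, folded: bool, n_chromosomes: int) -> SFS:
    counts = np.loadtxt(path).ravel()
    return SFS(counts, folded, n_chromosomes)
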