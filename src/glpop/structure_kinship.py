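"""Population structure and relatedness from genotype likelihoods.

* PCA: single-pass covariance of posterior genotype dosages standardized by
  per-site allele frequency (the GL analogue of a standard genotype PCA).
* Admixture: GL-aware EM for the admixture likelihood
  P(reads_i,s) = sum_g L_is(g) Binom(g | 2, sum_k Q_ik F_sk),
  estimating individual ancestry proportions Q and cluster allele
  frequencies F.
* Kinship: KING-robust phi from shared-heterozygote / opposite-homozygote
  counts, with interval masking (e.g. inversion regions) and a simple
  relationship classifier using the published powers-of-two thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glmodel import GLMatrix, _hwe, estimate_freq


def posterior_dosages(gls: GLMatrix, freqs: np.ndarray) -> np.ndarray:
    """(n_ind, S) posterior expected minor-allele dosage E[g].

    E[g] = sum_k k L(k) HWE(k|f) / sum_k L(k) HWE(k|f); a missing (flat)
    triplet falls back to the HWE mean 2f.
    """
    lik = np.exp(gls.values)  # (S, N, 3)
    w = lik * _hwe(freqs)[:, None, :]
    tot = w.sum(axis=2)
    eg = (w[..., 1] + 2.0 * w[..., 2]) / tot
    return eg.T


def covariance_pca(dosages: np.ndarray, freqs: np.ndarray, n_pcs: int = 10) -> tuple:
    """Frequency-standardized covariance and its leading PCs.

    C_ij = (1/S) sum_s (E[g_is] - 2 f_s)(E[g_js] - 2 f_s) / (2 f_s (1-f_s));
    monomorphic sites (f in {0,1}) are excluded with a warning.  Returns
    (C, scores, eigenvalues) with scores = eigenvectors * sqrt(eigenvalue),
    eigenvalues descending.
    """
    if dosages.shape[0] < 2 or dosages.shape[1] < 2:
        raise ValueError("need >= 2 individuals and >= 2 sites")
    freqs = np.asarray(freqs, dtype=float)
    poly = (freqs > 0) & (freqs < 1)
    if not poly.all():
        warnings.warn(f"excluding {int((~poly).sum())} monomorphic sites from PCA")
    f = freqs[poly]
    X = (dosages[:, poly] - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))
    C = X @ X.T / f.size
    C = (C + C.T) / 2.0
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    n_pcs = min(n_pcs, vals.size)
    scores = vecs[:, :n_pcs] * np.sqrt(np.maximum(vals[:n_pcs], 0.0))
    return C, scores, vals


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray  # (n_ind, K) ancestry proportions
    F: np.ndarray  # (S, K) cluster allele frequencies
    loglik: float
    loglik_trace: np.ndarray
    seed: int | None = None


def _admixture_em_once(lik, K, rng, tol, max_iter):
    S, N, _ = lik.shape
    Q = rng.dirichlet(np.ones(K), size=N)  # (N, K)
    f0 = estimate_freq(np.log(np.maximum(lik, 1e-300)))
    F = np.clip(f0[:, None] + rng.normal(0, 0.05, size=(S, K)), 0.01, 0.99)
    g = np.array([0.0, 1.0, 2.0])
    trace = []
    eps = 1e-9
    for _ in range(max_iter):
        H = np.clip(F @ Q.T, eps, 1 - eps)  # (S, N) individual allele freq
        pg = np.stack([(1 - H) ** 2, 2 * H * (1 - H), H**2], axis=2)
        w = lik * pg
        tot = w.sum(axis=2)
        trace.append(float(np.log(tot).sum()))
        post = w / tot[..., None]
        Eg = post @ g  # expected minor dosage (S, N)
        # attribute allele copies to clusters
        QF = Q[None, :, :] * F[:, None, :]  # (S, N, K)
        Q1F = Q[None, :, :] * (1.0 - F[:, None, :])
        r_min = QF / H[..., None]  # P(cluster | minor copy)
        r_maj = Q1F / (1.0 - H)[..., None]
        a = Eg[..., None] * r_min  # expected minor copies from cluster k
        b = (2.0 - Eg)[..., None] * r_maj
        F = np.clip(a.sum(axis=1) / np.maximum((a + b).sum(axis=1), eps), eps, 1 - eps)
        Q = (a + b).sum(axis=0) / (2.0 * S)
        Q = np.clip(Q, eps, None)
        Q /= Q.sum(axis=1, keepdims=True)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            break
    H = np.clip(F @ Q.T, eps, 1 - eps)
    pg = np.stack([(1 - H) ** 2, 2 * H * (1 - H), H**2], axis=2)
    ll = float(np.log((lik * pg).sum(axis=2)).sum())
    trace.append(ll)
    return Q, F, ll, np.array(trace)


def admixture_em(gls: GLMatrix, K: int, seed: int = 0, n_starts: int = 3, tol: float = 1e-6, max_iter: int = 2000) -> AdmixtureFit:
    """Best-of-``n_starts`` EM fit of the K-cluster admixture model.

    K = 1 has the analytic optimum Q = 1, F = per-site ML frequency and is
    returned directly.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gls.n_individuals:
        raise ValueError("K cannot exceed the number of individuals")
    lik = np.exp(gls.values)
    if K == 1:
        F = estimate_freq(gls.values)[:, None]
        Q = np.ones((gls.n_individuals, 1))
        H = np.clip(F @ Q.T, 1e-9, 1 - 1e-9)
        pg = np.stack([(1 - H) ** 2, 2 * H * (1 - H), H**2], axis=2)
        ll = float(np.log((lik * pg).sum(axis=2)).sum())
        return AdmixtureFit(1, Q, F, ll, np.array([ll]), seed)
    best = None
    for s in range(n_starts):
        rng = np.random.default_rng(seed + s)
        Q, F, ll, trace = _admixture_em_once(lik, K, rng, tol, max_iter)
        if best is None or ll > best.loglik:
            best = AdmixtureFit(K, Q, F, ll, trace, seed + s)
    return best


# ---------------------------------------------------------------------------
# kinship


def hard_call(gls: GLMatrix, freqs: np.ndarray | None = None, posterior_min: float = 0.95) -> np.ndarray:
    """(n_ind, S) called genotypes; -1 where the HWE posterior of the best
    genotype is below ``posterior_min`` or the site is missing."""
    if freqs is None:
        freqs = estimate_freq(gls.values)
    lik = np.exp(gls.values)
    w = lik * _hwe(freqs)[:, None, :]
    post = w / w.sum(axis=2, keepdims=True)
    calls = post.argmax(axis=2)
    calls[post.max(axis=2) < posterior_min] = -1
    calls[gls.missing_mask()] = -1
    return calls.T.astype(np.int8)


def mask_sites(sites: pd.DataFrame, mask_intervals) -> np.ndarray:
    """Boolean keep-mask excluding sites inside any (chrom, start, end)
    interval (0-based half-open, BED-style)."""
    keep = np.ones(len(sites), dtype=bool)
    pos0 = sites["pos"].to_numpy() - 1
    chroms = sites["chrom"].to_numpy()
    for chrom, start, end in mask_intervals:
        keep &= ~((chroms == str(chrom)) & (pos0 >= int(start)) & (pos0 < int(end)))
    return keep


def king_kinship(genotypes: np.ndarray, sample_ids=None, sites: pd.DataFrame | None = None, mask_intervals=()) -> pd.DataFrame:
    """KING-robust kinship for every individual pair.

    ``genotypes`` is (n_ind, S) in {0,1,2}, -1 = missing.  phi =
    (N_both_het - 2 N_opposite_hom) / (N_het_i + N_het_j), counted over
    sites non-missing in both individuals and outside the mask; phi can be
    strongly negative for structured pairs.  Pairs with no usable
    heterozygous sites get NaN.
    """
    g = np.asarray(genotypes)
    n = g.shape[0]
    if sample_ids is None:
        sample_ids = [f"ind{i:03d}" for i in range(n)]
    if mask_intervals and sites is not None:
        g = g[:, mask_sites(sites, mask_intervals)]
    valid = (g >= 0).astype(np.float64)
    het = (g == 1).astype(np.float64)
    hom0 = (g == 0).astype(np.float64)
    hom2 = (g == 2).astype(np.float64)
    both_het = het @ het.T
    opp_hom = hom0 @ hom2.T + hom2 @ hom0.T
    het_i = het @ valid.T  # het in i at sites valid in j
    rows = []
    for i in range(n):
        for jx in range(i, n):
            denom = het_i[i, jx] + het_i[jx, i]
            phi = (both_het[i, jx] - 2.0 * opp_hom[i, jx]) / denom if denom > 0 else float("nan")
            rows.append(
                {
                    "id1": sample_ids[i],
                    "id2": sample_ids[jx],
                    "n_both_het": int(both_het[i, jx]),
                    "n_opposite_hom": int(opp_hom[i, jx]),
                    "n_het_1": int(het_i[i, jx]),
                    "n_het_2": int(het_i[jx, i]),
                    "phi": phi,
                }
            )
    return pd.DataFrame(rows)


def classify_relationships(kinship: pd.DataFrame) -> pd.DataFrame:
    """KING powers-of-two bins, with first-degree pairs split into full-sib
    versus parent-offspring by the opposite-homozygote count.

    phi > 0.354 duplicate/monozygotic; (0.177, 0.354] first degree;
    (0.0884, 0.177] second degree; otherwise unrelated.  Parent-offspring
    pairs share an allele at every site, so N_opposite_hom stays near the
    genotyping-error floor; first-degree pairs above that floor are
    full-sibs.
    """
    out = kinship.copy()
    n_pairs_sites = (out["n_het_1"] + out["n_het_2"]).to_numpy(dtype=float)

    def one(row, floor):
        phi = row["phi"]
        if not np.isfinite(phi):
            return "unknown"
        if row["id1"] == row["id2"]:
            return "self"
        if phi > 0.354:
            return "duplicate"
        if phi > 0.177:
            return "full_sib" if row["n_opposite_hom"] > floor else "parent_offspring"
        if phi > 0.0884:
            return "second_degree"
        return "unrelated"

    floors = 0.005 * n_pairs_sites  # tolerate a small error-driven count
    out["category"] = [one(r, f) for (_, r), f in zip(out.iterrows(), floors)]
    return out
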