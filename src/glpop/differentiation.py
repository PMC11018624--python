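"""Pairwise differentiation: joint 2D SFS, windowed Hudson Fst, mode-based
outlier-window designation, and intersection of outlier windows with a gene
annotation.

The Fst estimator is Hudson's, in the ratio-of-sums form: per site

    alpha = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    beta  = p1(1-p2) + p2(1-p1)

with n_k the haploid sample sizes, and window or genomewide Fst equal to
sum(alpha)/sum(beta).  At low coverage the p_k are posterior mean allele
frequencies under the joint 2D-SFS prior; with called genotypes they are
plain sample frequencies.  Negative per-site alpha is retained, never
clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sfs_diversity import SAFMatrix
from .windows import sliding_windows


@dataclass
class Joint2DSFS:
    """Expected site counts over joint allele-count classes (j1, j2)."""

    counts: np.ndarray  # (2N1+1, 2N2+1)
    n_chromosomes: tuple
    loglik_trace: np.ndarray | None = None

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def joint_sfs(saf1: SAFMatrix, saf2: SAFMatrix, tol: float = 1e-6, max_iter: int = 500) -> Joint2DSFS:
    """EM estimate of the joint 2D SFS from two aligned SAF matrices.

    Maximizes sum_s log sum_{j1,j2} SFS_{j1,j2} SAF1_s(j1) SAF2_s(j2); the
    log-likelihood is non-decreasing per iteration.
    """
    if saf1.n_sites != saf2.n_sites or not saf1.sites["pos"].equals(saf2.sites["pos"]):
        raise ValueError("SAF matrices must cover the same site list")
    lik1, lik2 = np.exp(saf1.values), np.exp(saf2.values)
    S, m1 = lik1.shape
    m2 = lik2.shape[1]
    sfs = np.full((m1, m2), 1.0 / (m1 * m2))
    trace = []
    for _ in range(max_iter):
        right = lik2 @ sfs.T  # (S, m1): sum_j2 SFS_{j1,j2} lik2_{j2}
        tot = (lik1 * right).sum(axis=1)  # per-site likelihood
        trace.append(np.log(tot).sum())
        # posterior sum over sites: (lik1/tot)' lik2 elementwise with sfs
        new = sfs * ((lik1 / tot[:, None]).T @ lik2) / S
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            sfs = new
            break
        sfs = new
    return Joint2DSFS(sfs * S, (m1 - 1, m2 - 1), np.array(trace))


def posterior_pair_freqs(saf1: SAFMatrix, saf2: SAFMatrix, sfs2d: Joint2DSFS) -> tuple:
    """Per-site posterior mean allele frequencies (p1, p2) under the 2D SFS."""
    lik1, lik2 = np.exp(saf1.values), np.exp(saf2.values)
    prior = sfs2d.proportions
    right = lik2 @ prior.T  # (S, m1)
    left = lik1 @ prior  # (S, m2)
    tot = (lik1 * right).sum(axis=1)
    j1 = np.arange(lik1.shape[1]) / (lik1.shape[1] - 1)
    j2 = np.arange(lik2.shape[1]) / (lik2.shape[1] - 1)
    p1 = ((lik1 * right) @ j1) / tot
    p2 = ((lik2 * left) @ j2) / tot
    return p1, p2


@dataclass
class FstComponents:
    """Per-site Hudson numerator (alpha) and denominator (beta)."""

    sites: pd.DataFrame  # chrom, pos
    alpha: np.ndarray
    beta: np.ndarray
    n1: int  # haploid sample size, population 1
    n2: int
    labels: tuple = ("pop1", "pop2")


def fst_components(p1, p2, n1: int, n2: int, sites: pd.DataFrame | None = None, labels=("pop1", "pop2")) -> FstComponents:
    """Hudson/Bhatia per-site alpha and beta from allele frequencies.

    ``n1``/``n2`` are haploid (chromosome) sample sizes; both must be >= 2
    for the within-population sampling correction to exist.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 chromosomes per population")
    p1, p2 = np.asarray(p1, dtype=float), np.asarray(p2, dtype=float)
    alpha = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    beta = p1 * (1 - p2) + p2 * (1 - p1)
    if sites is None:
        sites = pd.DataFrame({"chrom": np.repeat("NA", p1.size), "pos": np.arange(1, p1.size + 1)})
    return FstComponents(sites=sites.reset_index(drop=True), alpha=alpha, beta=beta, n1=n1, n2=n2, labels=labels)


def fst_components_from_genotypes(g1: np.ndarray, g2: np.ndarray, sites=None, labels=("pop1", "pop2")) -> FstComponents:
    """Components from called diploid genotype matrices (n_ind, S) in {0,1,2};
    entries < 0 are treated as missing."""
    def freq(g):
        g = np.asarray(g, dtype=float)
        miss = g < 0
        g = np.where(miss, 0.0, g)
        n_called = (~miss).sum(axis=0)
        return g.sum(axis=0) / (2.0 * np.maximum(n_called, 1)), n_called
    p1, _ = freq(g1)
    p2, _ = freq(g2)
    return fst_components(p1, p2, 2 * g1.shape[0], 2 * g2.shape[0], sites=sites, labels=labels)


def fst_components_from_gls(saf1: SAFMatrix, saf2: SAFMatrix, sfs2d: Joint2DSFS | None = None, labels=("pop1", "pop2")) -> FstComponents:
    """Low-coverage path: posterior mean frequencies under the 2D-SFS prior."""
    if sfs2d is None:
        sfs2d = joint_sfs(saf1, saf2)
    p1, p2 = posterior_pair_freqs(saf1, saf2, sfs2d)
    return fst_components(
        p1, p2, saf1.n_chromosomes, saf2.n_chromosomes,
        sites=saf1.sites[["chrom", "pos"]], labels=labels,
    )


def windowed_fst(components: FstComponents, window_bp: int = 10_000, step_bp: int = 5_000) -> pd.DataFrame:
    """Ratio-of-sums Fst in sliding windows; windows with zero denominator
    (or no sites) report NaN."""
    rows = []
    for chrom, start, end, idx in sliding_windows(
        components.sites["chrom"].to_numpy(), components.sites["pos"].to_numpy(), window_bp, step_bp
    ):
        a = float(components.alpha[idx].sum())
        b = float(components.beta[idx].sum())
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "n_sites": idx.size,
                "alpha_sum": a,
                "beta_sum": b,
                "fst": a / b if b > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def genomewide_fst(components: FstComponents) -> float:
    """Genomewide ratio-of-sums Fst over all retained sites."""
    b = components.beta.sum()
    return float(components.alpha.sum() / b) if b > 0 else float("nan")


def mean_window_fst(windows: pd.DataFrame) -> float:
    """Unweighted mean of window Fst (reported alongside the ratio of sums)."""
    return float(windows["fst"].mean())


def estimate_fst_mode(values: np.ndarray, grid_points: int = 512) -> float:
    """Deterministic mode of the window-Fst distribution: Gaussian KDE with
    Silverman bandwidth, argmax on a fixed grid over [min, max]."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return float(lo)
    kde = sps.gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(lo, hi, grid_points)
    return float(grid[np.argmax(kde(grid))])


def designate_outliers(windows: pd.DataFrame, fst_col: str = "fst", min_windows: int = 30) -> pd.DataFrame:
    """Mode-based outlier rule on the right tail of the Fst distribution.

    With d = mode - min of the window Fst values, any window with
    Fst > mode + 3 d is an outlier.  Returns the input with ``is_outlier``,
    ``threshold`` and ``fst_mode`` columns added (NaN-Fst windows are never
    outliers and are excluded from mode estimation).
    """
    out = windows.copy()
    vals = out[fst_col].to_numpy(dtype=float)
    ok = np.isfinite(vals)
    if ok.sum() < min_windows:
        raise ValueError(f"need >= {min_windows} windows with defined Fst for a meaningful mode")
    mode = estimate_fst_mode(vals[ok])
    d = mode - vals[ok].min()
    threshold = mode + 3.0 * d
    if d == 0:
        warnings.warn("degenerate Fst distribution (mode equals minimum): no outliers")
    out["fst_mode"] = mode
    out["threshold"] = threshold
    out["is_outlier"] = ok & (vals > threshold) & (d > 0)
    return out


def read_gff_genes(gff_path) -> pd.DataFrame:
    """Gene records (id, name, chrom, 1-based inclusive start/end) via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for gene in db.features_of_type("gene"):
        name = gene.attributes.get("Name", [gene.id])[0]
        rows.append({"gene_id": gene.id, "name": name, "chrom": gene.seqid,
                     "start": gene.start, "end": gene.end})
    return pd.DataFrame(rows)


def intersect_genes(outliers: pd.DataFrame, annotation) -> pd.DataFrame:
    """Genes overlapping any outlier window by >= 1 bp, ranked by the peak
    Fst among their overlapping windows (descending).

    ``annotation`` is a GFF3 path or a gene DataFrame from
    :func:`read_gff_genes`.  Window coordinates are 0-based half-open; gene
    coordinates 1-based inclusive (GFF3) and converted internally.
    """
    genes = annotation if isinstance(annotation, pd.DataFrame) else read_gff_genes(annotation)
    hits = outliers[outliers["is_outlier"]]
    rows = []
    for _, g in genes.iterrows():
        g0, g1 = g["start"] - 1, g["end"]  # to 0-based half-open
        over = hits[(hits["chrom"] == g["chrom"]) & (hits["start"] < g1) & (hits["end"] > g0)]
        if len(over):
            rows.append(
                {
                    "gene_id": g["gene_id"],
                    "name": g["name"],
                    "chrom": g["chrom"],
                    "start": g["start"],
                    "end": g["end"],
                    "peak_fst": float(over["fst"].max()),
                    "n_outlier_windows": int(len(over)),
                }
            )
    out = pd.DataFrame(
        rows, columns=["gene_id", "name", "chrom", "start", "end", "peak_fst", "n_outlier_windows"]
    )
    return out.sort_values("peak_fst", ascending=False).reset_index(drop=True)
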