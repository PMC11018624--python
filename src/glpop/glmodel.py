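"""Diallelic genotype likelihoods from read pileups, plus site/individual
filters and the BEAGLE genotype-likelihood text format.

The likelihood model is the classic samtools one: for a genotype carrying
``k`` copies of the minor allele (k = 0, 1, 2),

    L(k) = prod over reads [ (k/2) P(read|minor) + (1-k/2) P(read|major) ]

with ``P(read|allele) = 1 - e`` when the read base equals the allele and
``e/3`` otherwise, ``e = 10^(-q/10)`` the phred error probability of the
read.  Likelihoods are stored log-scaled and normalized so the per-individual
maximum is 0; a missing individual-site is the flat triplet (0, 0, 0).
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import BASE_INDEX, BASES, Pileup, PileupBlock

FLAT = np.zeros(3)


@dataclass
class GLMatrix:
    """Per-site, per-individual log genotype likelihoods.

    ``values[s, i]`` is the log-likelihood triplet for genotypes
    (major/major, major/minor, minor/minor) at site ``s`` for individual
    ``i``, max-normalized per individual.  ``sites`` has columns
    chrom, pos (1-based), major, minor, sorted by (chrom, pos).
    """

    sites: pd.DataFrame
    values: np.ndarray  # (S, N, 3) log-scaled
    sample_ids: list

    def __post_init__(self):
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError("values must be (n_sites, n_ind, 3)")

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> np.ndarray:
        """(S, N) True where the triplet is flat (no information)."""
        return np.all(self.values == 0.0, axis=2)

    def take_sites(self, mask_or_idx) -> "GLMatrix":
        idx = np.asarray(mask_or_idx)
        return GLMatrix(
            sites=self.sites.iloc[idx].reset_index(drop=True)
            if idx.dtype != bool
            else self.sites.loc[idx].reset_index(drop=True),
            values=self.values[idx],
            sample_ids=list(self.sample_ids),
        )

    def take_individuals(self, idx) -> "GLMatrix":
        idx = np.asarray(idx)
        return GLMatrix(
            sites=self.sites.copy(),
            values=self.values[:, idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )


def genotype_likelihoods(site: Pileup, major: str | None = None, minor: str | None = None) -> np.ndarray:
    """Log GL triplets for one pileup site (reference implementation).

    Handles per-read qualities.  ``major``/``minor`` default to the pileup's
    ref/alt.  Individuals with zero reads get the flat triplet.
    """
    major = site.ref if major is None else major
    minor = site.alt if minor is None else minor
    out = np.zeros((len(site.reads), 3))
    for i, reads in enumerate(site.reads):
        if not reads:
            continue
        ll = np.zeros(3)
        for base, q in reads:
            e = 10.0 ** (-q / 10.0)
            p_major = 1.0 - e if base == major else e / 3.0
            p_minor = 1.0 - e if base == minor else e / 3.0
            for k in range(3):
                ll[k] += np.log((k / 2.0) * p_minor + (1.0 - k / 2.0) * p_major)
        out[i] = ll - ll.max()
    return out


def gl_from_counts(base_counts: np.ndarray, qual: float, major_code: np.ndarray, minor_code: np.ndarray) -> np.ndarray:
    """Vectorized GLs from per-base read counts with one shared quality.

    ``base_counts`` is (S, N, 4); ``major_code``/``minor_code`` are per-site
    indices into the A,C,G,T alphabet.  Returns (S, N, 3) log triplets,
    max-normalized; zero-depth entries are flat.
    """
    e = 10.0 ** (-qual / 10.0)
    S, N, _ = base_counts.shape
    # per site, per base, per genotype: log of the read-level mixture
    p_of_base = np.full((S, 4, 2), e / 3.0)  # [..., 0]=P(b|major), 1=P(b|minor)
    p_of_base[np.arange(S), major_code, 0] = 1.0 - e
    p_of_base[np.arange(S), minor_code, 1] = 1.0 - e
    k = np.array([0.0, 0.5, 1.0])  # k/2 for genotypes 0,1,2
    mix = (1.0 - k)[None, None, :] * p_of_base[:, :, 0, None] + k[None, None, :] * p_of_base[:, :, 1, None]
    log_mix = np.log(mix)  # (S, 4, 3)
    ll = np.einsum("snb,sbk->snk", base_counts.astype(np.float64), log_mix)
    ll -= ll.max(axis=2, keepdims=True)
    ll[base_counts.sum(axis=2) == 0] = 0.0
    return ll


def _hwe(f: np.ndarray) -> np.ndarray:
    """(..., 3) Hardy-Weinberg genotype frequencies for minor-allele freq f."""
    f = np.asarray(f)
    return np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1)


def estimate_freq(gl_values: np.ndarray, tol: float = 1e-8, max_iter: int = 100) -> np.ndarray:
    """ML frequency of the minor-labelled allele per site, by EM over GLs.

    ``gl_values`` is (S, N, 3) or (N, 3) log-scaled.  Flat (missing)
    triplets contribute their HWE prior only and do not bias the estimate.
    """
    single = gl_values.ndim == 2
    gl = gl_values[None] if single else gl_values
    lik = np.exp(gl)  # (S, N, 3)
    f = np.full(gl.shape[0], 0.25)
    for _ in range(max_iter):
        w = lik * _hwe(f)[:, None, :]
        tot = w.sum(axis=2, keepdims=True)
        post = w / np.where(tot == 0, 1.0, tot)
        f_new = (post[..., 1] + 2.0 * post[..., 2]).mean(axis=1) / 2.0
        delta = np.abs(f_new - f).max()
        f = f_new
        if delta < tol:
            break
    return f[0] if single else f


def estimate_maf(gl_values: np.ndarray, **kw) -> np.ndarray:
    """ML minor allele frequency: the folded version of :func:`estimate_freq`."""
    gl = np.asarray(gl_values)
    if gl.ndim == 2 and np.all(gl == 0):
        raise ValueError("all individuals missing: site unusable")
    f = estimate_freq(gl, **kw)
    return np.minimum(f, 1.0 - f)


def _loglik_at(gl_values: np.ndarray, f) -> np.ndarray:
    """Site log-likelihood(s) at frequency f (scalar or per-site array)."""
    gl = gl_values if gl_values.ndim == 3 else gl_values[None]
    lik = np.exp(gl)
    hwe = _hwe(np.broadcast_to(np.asarray(f, dtype=float), (gl.shape[0],)))
    site_ll = np.log((lik * hwe[:, None, :]).sum(axis=2)).sum(axis=1)
    return site_ll


def snp_lrt(gl_values: np.ndarray, f_hat) -> tuple:
    """Likelihood-ratio test of polymorphism: H0 f=0 vs H1 f=f_hat.

    Returns (statistic, p) per site; the statistic is 2[l(f_hat) - l(0)]
    referred to the chi-squared distribution with 1 df.
    """
    single = gl_values.ndim == 2
    gl = gl_values[None] if single else gl_values
    lrt = 2.0 * (_loglik_at(gl, np.asarray(f_hat, dtype=float)) - _loglik_at(gl, 0.0))
    lrt = np.maximum(lrt, 0.0)
    p = stats.chi2.sf(lrt, df=1)
    if single:
        return float(lrt[0]), float(p[0])
    return lrt, p


@dataclass(frozen=True)
class FilterConfig:
    """Site and individual filters, defaulting to the standard low-coverage
    pipeline values: total depth <= 6000x, base quality >= 30, per-site
    missingness <= 0.75 absent individuals, SNP p <= 0.05, MAF >= 0.05."""

    max_total_depth: int = 6000
    min_base_q: int = 30
    min_ind_fraction: float = 0.25
    snp_pvalue_max: float = 0.05
    maf_min: float = 0.05
    polymorphism_filters_on: bool = True


@dataclass
class FilterStats:
    n_input: int = 0
    n_depth_fail: int = 0
    n_missingness_fail: int = 0
    n_snp_p_fail: int = 0
    n_maf_fail: int = 0
    n_retained: int = 0
    removed_individuals: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_depth_fail": self.n_depth_fail,
            "n_missingness_fail": self.n_missingness_fail,
            "n_snp_p_fail": self.n_snp_p_fail,
            "n_maf_fail": self.n_maf_fail,
            "n_retained": self.n_retained,
            "removed_individuals": list(self.removed_individuals),
        }


def gl_from_pileups(block: PileupBlock, min_base_q: int = 0) -> GLMatrix:
    """GLMatrix from a pileup block, assigning major/minor by ML frequency.

    GLs are first computed with ref as the provisional major allele; sites
    where the ML frequency of the alt allele exceeds 0.5 have their triplet
    reversed and allele labels swapped so that "minor" is the rarer allele.
    Reads below ``min_base_q`` are excluded before GL computation (here: the
    whole block shares one quality, so the exclusion is all-or-nothing).
    """
    counts = block.base_counts
    if block.qual < min_base_q:
        counts = np.zeros_like(counts)
    major_code = np.array([BASE_INDEX[b] for b in block.ref])
    minor_code = np.array([BASE_INDEX[b] for b in block.alt])
    values = gl_from_counts(counts, block.qual, major_code, minor_code)
    f = estimate_freq(values)
    swap = f > 0.5
    values[swap] = values[swap][:, :, ::-1]
    major = np.where(swap, block.alt, block.ref)
    minor = np.where(swap, block.ref, block.alt)
    sites = pd.DataFrame(
        {"chrom": block.chroms, "pos": block.positions, "major": major, "minor": minor}
    )
    return GLMatrix(sites=sites, values=values, sample_ids=list(block.sample_ids))


def gl_from_pileup_list(pileups, sample_ids, min_base_q: int = 0) -> GLMatrix:
    """GLMatrix from per-site :class:`Pileup` records (per-read qualities
    honoured; reads below ``min_base_q`` are dropped before GL computation).
    Major/minor are assigned by ML frequency as in :func:`gl_from_pileups`."""
    values = np.empty((len(pileups), len(sample_ids), 3))
    sites_rows = []
    for s, p in enumerate(pileups):
        if min_base_q > 0:
            p = Pileup(
                p.chrom, p.pos, p.ref, p.alt,
                [[(b, q) for b, q in reads if q >= min_base_q] for reads in p.reads],
            )
        values[s] = genotype_likelihoods(p)
        sites_rows.append((p.chrom, p.pos, p.ref, p.alt))
    f = estimate_freq(values)
    swap = f > 0.5
    values[swap] = values[swap][:, :, ::-1]
    sites = pd.DataFrame(sites_rows, columns=["chrom", "pos", "ref", "alt"])
    sites["major"] = np.where(swap, sites["alt"], sites["ref"])
    sites["minor"] = np.where(swap, sites["ref"], sites["alt"])
    return GLMatrix(
        sites=sites[["chrom", "pos", "major", "minor"]],
        values=values,
        sample_ids=list(sample_ids),
    )


def filter_sites(gls: GLMatrix, block: PileupBlock, cfg: FilterConfig) -> tuple:
    """Apply the site filters; returns (filtered GLMatrix, FilterStats).

    Depth, SNP-p and MAF filters are the "polymorphism" filters and are
    skipped when ``cfg.polymorphism_filters_on`` is False (the monomorphic-
    sites-included mode used for diversity estimation); the missingness rule
    always applies.
    """
    stats_out = FilterStats(n_input=gls.n_sites)
    keep = np.ones(gls.n_sites, dtype=bool)

    present = ~gls.missing_mask()
    frac_present = present.mean(axis=1)
    miss_fail = frac_present < cfg.min_ind_fraction
    stats_out.n_missingness_fail = int(miss_fail.sum())
    keep &= ~miss_fail

    if cfg.polymorphism_filters_on:
        depth_fail = block.total_depth() > cfg.max_total_depth
        stats_out.n_depth_fail = int(depth_fail.sum())
        keep &= ~depth_fail

        f = estimate_freq(gls.values)
        maf = np.minimum(f, 1 - f)
        _, p = snp_lrt(gls.values, f)
        snp_fail = p > cfg.snp_pvalue_max
        maf_fail = maf < cfg.maf_min
        stats_out.n_snp_p_fail = int((snp_fail & keep).sum())
        keep &= ~snp_fail
        stats_out.n_maf_fail = int((maf_fail & keep).sum())
        keep &= ~maf_fail

    stats_out.n_retained = int(keep.sum())
    if stats_out.n_retained == 0:
        warnings.warn("no sites survive filtering")
    return gls.take_sites(keep), stats_out


def filter_individuals(gls: GLMatrix, max_missing: float = 0.25) -> tuple:
    """Drop individuals missing at more than ``max_missing`` of sites
    (strictly greater, so exactly-at-threshold individuals are retained).
    Returns (GLMatrix, list of removed sample ids)."""
    miss = gls.missing_mask().mean(axis=0)
    removed = [sid for sid, m in zip(gls.sample_ids, miss) if m > max_missing]
    keep_idx = [i for i, m in enumerate(miss) if m <= max_missing]
    if not keep_idx:
        raise ValueError("all individuals exceed the missingness threshold")
    return gls.take_individuals(keep_idx), removed


# ---------------------------------------------------------------------------
# BEAGLE genotype-likelihood text format

_ALLELE_CODE = {"A": "0", "C": "1", "G": "2", "T": "3"}
_CODE_ALLELE = {v: k for k, v in _ALLELE_CODE.items()}
_CODE_ALLELE.update({b: b for b in "ACGT"})


def _open(path, mode):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_beagle(gls: GLMatrix, path) -> None:
    """BEAGLE GL text: marker, allele1, allele2, then three linear-scale
    likelihood columns per individual (AA, Aa, aa), normalized to sum 1."""
    lik = np.exp(gls.values)
    tot = lik.sum(axis=2, keepdims=True)
    lik = lik / np.where(tot == 0, 1.0, tot)
    with _open(path, "w") as fh:
        cols = ["marker", "allele1", "allele2"]
        for sid in gls.sample_ids:
            cols.extend([sid] * 3)
        fh.write("\t".join(cols) + "\n")
        for s in range(gls.n_sites):
            row = gls.sites.iloc[s]
            out = [
                f"{row.chrom}_{row.pos}",
                _ALLELE_CODE[row.major],
                _ALLELE_CODE[row.minor],
            ]
            out.extend(f"{v:.6f}" for v in lik[s].ravel())
            fh.write("\t".join(out) + "\n")


def read_beagle(path) -> GLMatrix:
    """Parse a BEAGLE GL file back into a (log, max-normalized) GLMatrix."""
    with _open(path, "r") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["marker", "allele1", "allele2"]:
            raise ValueError(f"line 1: not a BEAGLE GL header: {header[:3]}")
        sample_ids = header[3::3]
        chroms, positions, majors, minors, rows = [], [], [], [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3 + 3 * len(sample_ids):
                raise ValueError(f"line {lineno}: expected {3 + 3 * len(sample_ids)} columns, got {len(parts)}")
            try:
                chrom, pos = parts[0].rsplit("_", 1)
                positions.append(int(pos))
                chroms.append(chrom)
                majors.append(_CODE_ALLELE[parts[1]])
                minors.append(_CODE_ALLELE[parts[2]])
                rows.append([float(x) for x in parts[3:]])
            except (ValueError, KeyError) as exc:
                raise ValueError(f"line {lineno}: malformed row ({exc})") from None
    lik = np.array(rows).reshape(len(rows), len(sample_ids), 3)
    with np.errstate(divide="ignore"):
        values = np.log(lik)
    values -= values.max(axis=2, keepdims=True)
    values[~np.isfinite(values)] = -np.inf
    flat = np.isclose(lik, lik[..., :1]).all(axis=2)
    values[flat] = 0.0
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "major": majors, "minor": minors}
    )
    return GLMatrix(sites=sites, values=values, sample_ids=sample_ids)
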