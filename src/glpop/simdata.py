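"""Synthetic structured populations with known truth.

Emulates a two-species, multi-ecoregion, multi-site low-coverage WGS study:
Balding–Nichols allele-frequency differentiation at a target Fst, localized
selective sweeps (haplotype copying), one high-differentiation "inversion"
block, full-sib pairs bred from unsampled parents, and Poisson-distributed
read depth with phred-scaled base-calling errors.  Every downstream stage of
the pipeline can therefore be tested against ground truth without any real
sequencing data.

The generator is frequency-based, not coalescent: each SNP is independent,
with an ancestral minor-allele frequency drawn from a neutral-like 1/f
density and per-population frequencies drawn from the Balding–Nichols Beta
distribution parameterized by the target Fst.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

BASES = np.array(["A", "C", "G", "T"])
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class SweepLocus:
    """A localized selective sweep: haplotype copying inside a window.

    ``strength`` is the fraction of haplotypes in the window replaced by
    copies of one randomly chosen donor haplotype.  ``pops`` restricts the
    sweep to the listed population indices (None = all populations), which
    is how divergent selection between ecoregions is emulated.
    """

    chrom: str
    center: int
    width: int
    strength: float
    pops: tuple[int, ...] | None = None
    name: str = "IRgene"

    @property
    def start(self) -> int:
        return max(1, self.center - self.width // 2)

    @property
    def end(self) -> int:
        return self.center + self.width // 2


@dataclass(frozen=True)
class InversionBlock:
    """Contiguous region with extra Beta variance (elevated local Fst)."""

    chrom: str
    start: int
    end: int
    extra_fst: float


@dataclass(frozen=True)
class SimConfig:
    n_pops: int = 2
    n_dip_per_pop: int = 40
    target_fst: float = 0.05
    chrom_lengths: dict = field(default_factory=lambda: {"1": 1_000_000})
    mut_density: float = 0.005  # expected SNPs per bp
    sweep_loci: tuple[SweepLocus, ...] = ()
    inversion_block: InversionBlock | None = None
    n_sib_pairs: int = 0
    mean_coverage: float = 13.7
    base_error: int = 20  # phred
    seed: int = 0
    # "truncated_1f": ancestral frequency density ~ 1/f on freq_range, a
    # common-variant (post-MAF-filter-like) spectrum for structured
    # simulations.  "neutral": the exact neutral sample spectrum — per-site
    # sample allele counts drawn with P(j) ~ 1/j and assigned to chromosomes
    # at random — valid only for undifferentiated (target_fst = 0)
    # simulations, where it makes E[pi] equal E[theta_W] site by site.
    spectrum: str = "truncated_1f"
    freq_range: tuple[float, float] = (0.05, 0.95)
    sites_per_pop: int = 3  # collection-site labels per population
    pop_labels: tuple[tuple[str, str], ...] | None = None  # (species, ecoregion)

    def __post_init__(self):
        if not (0.0 <= self.target_fst < 1.0):
            raise ValueError("target_fst must be in [0, 1)")
        for locus in self.sweep_loci:
            if not (0.0 <= locus.strength <= 1.0):
                raise ValueError("sweep strength must be in [0, 1]")
        if self.mean_coverage < 0:
            raise ValueError("mean_coverage must be >= 0")
        if self.spectrum not in ("truncated_1f", "neutral"):
            raise ValueError(f"unknown spectrum {self.spectrum!r}")
        if self.spectrum == "neutral" and self.target_fst != 0:
            raise ValueError("the neutral spectrum requires target_fst = 0")

    @property
    def n_individuals(self) -> int:
        return self.n_pops * self.n_dip_per_pop


@dataclass
class SimulationTruth:
    """Ground truth emitted by the simulator for parameter-recovery tests."""

    chroms: np.ndarray  # per-SNP chromosome name
    positions: np.ndarray  # per-SNP 1-based bp
    ref: np.ndarray  # per-SNP reference (ancestral-ish) base
    alt: np.ndarray  # per-SNP alternate base
    ancestral_freqs: np.ndarray  # per-SNP ancestral minor-allele frequency
    pop_freqs: np.ndarray  # (n_pops, S) per-pop frequencies
    haplotypes: np.ndarray  # (n_ind, 2, S) in {0,1}
    pop_of_ind: np.ndarray  # (n_ind,) population index
    sample_ids: list
    metadata: pd.DataFrame  # sample_id, species, ecoregion, site, lat, lon
    pedigree: list  # (offspring_id, parent1_id, parent2_id)
    parental_haplotypes: dict  # parent_id -> (2, S) array
    sweep_windows: list  # (chrom, start, end)
    config: SimConfig

    @property
    def genotypes(self) -> np.ndarray:
        """(n_ind, S) minor-allele dosage in {0, 1, 2}."""
        return self.haplotypes.sum(axis=1)

    @property
    def n_snps(self) -> int:
        return self.positions.size


def _draw_ancestral_freqs(rng, n, lo, hi):
    # inverse-CDF sampling of density proportional to 1/f on [lo, hi]
    u = rng.random(n)
    return lo * (hi / lo) ** u


def simulate_frequencies(config: SimConfig, rng=None) -> SimulationTruth:
    """Draw SNPs, per-population frequencies, haplotypes and pedigrees.

    Per-population frequencies follow the Balding–Nichols model:
    ``p ~ Beta(f(1-F)/F, (1-f)(1-F)/F)`` with ancestral frequency ``f`` and
    differentiation ``F = target_fst`` (``F = 0`` means all populations share
    the ancestral frequency exactly).  Inside the configured inversion block
    the Beta variance parameter is ``F + extra_fst``.  Full-sib offspring are
    bred by Mendelian transmission from stored unsampled parents.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    chrom_names, positions = [], []
    for chrom, length in config.chrom_lengths.items():
        n_sites = rng.poisson(length * config.mut_density)
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=min(n_sites, length), replace=False))
        positions.append(pos)
        chrom_names.append(np.repeat(chrom, pos.size))
    chroms = np.concatenate(chrom_names)
    positions = np.concatenate(positions)
    S = positions.size

    n_total = config.n_individuals
    neutral_counts = None
    if config.spectrum == "neutral":
        n_chrom = 2 * n_total
        j = np.arange(1, n_chrom)
        pj = (1.0 / j) / np.sum(1.0 / j)
        neutral_counts = rng.choice(j, size=S, p=pj)
        anc = neutral_counts / n_chrom
    else:
        lo, hi = config.freq_range
        anc = _draw_ancestral_freqs(rng, S, lo, hi)

    F_site = np.full(S, config.target_fst)
    inv = config.inversion_block
    if inv is not None:
        in_block = (chroms == inv.chrom) & (positions >= inv.start) & (positions <= inv.end)
        F_site[in_block] = np.minimum(config.target_fst + inv.extra_fst, 0.999)

    pop_freqs = np.empty((config.n_pops, S))
    nonzero = F_site > 0
    for p in range(config.n_pops):
        pop_freqs[p] = anc
        if nonzero.any():
            f, Fs = anc[nonzero], F_site[nonzero]
            a = f * (1.0 - Fs) / Fs
            b = (1.0 - f) * (1.0 - Fs) / Fs
            pop_freqs[p, nonzero] = rng.beta(a, b)

    pop_of_ind = np.repeat(np.arange(config.n_pops), config.n_dip_per_pop)
    haplotypes = np.empty((n_total, 2, S), dtype=np.uint8)
    if neutral_counts is not None:
        # exact sample counts: place j minor alleles on 2N chromosomes at random
        order = np.argsort(rng.random((S, 2 * n_total)), axis=1)
        mat = (order < neutral_counts[:, None]).astype(np.uint8)  # (S, 2N)
        haplotypes = mat.T.reshape(n_total, 2, S)
    else:
        for p in range(config.n_pops):
            idx = np.where(pop_of_ind == p)[0]
            haplotypes[idx] = (
                rng.random((idx.size, 2, S)) < pop_freqs[p]
            ).astype(np.uint8)

    sample_ids = [f"ind{i:03d}" for i in range(n_total)]

    pedigree, parental_haplotypes = [], {}
    for k in range(config.n_sib_pairs):
        p = k % config.n_pops
        pop_idx = np.where(pop_of_ind == p)[0]
        # replace the last two individuals of the population with sibs
        off_idx = pop_idx[-2 - 2 * (k // config.n_pops) :][:2]
        par_ids = (f"par{2 * k:03d}", f"par{2 * k + 1:03d}")
        par_haps = [
            (rng.random((2, S)) < pop_freqs[p]).astype(np.uint8) for _ in range(2)
        ]
        for pid, ph in zip(par_ids, par_haps):
            parental_haplotypes[pid] = ph
        for oi in off_idx:
            # per-SNP Mendelian choice of one allele from each parent
            pick1 = rng.integers(0, 2, S)
            pick2 = rng.integers(0, 2, S)
            haplotypes[oi, 0] = par_haps[0][pick1, np.arange(S)]
            haplotypes[oi, 1] = par_haps[1][pick2, np.arange(S)]
            pedigree.append((sample_ids[oi], par_ids[0], par_ids[1]))

    ref_idx = rng.integers(0, 4, S)
    alt_idx = (ref_idx + rng.integers(1, 4, S)) % 4

    metadata = _assign_sites(config, sample_ids, pop_of_ind, rng)

    truth = SimulationTruth(
        chroms=chroms,
        positions=positions,
        ref=BASES[ref_idx],
        alt=BASES[alt_idx],
        ancestral_freqs=anc,
        pop_freqs=pop_freqs,
        haplotypes=haplotypes,
        pop_of_ind=pop_of_ind,
        sample_ids=sample_ids,
        metadata=metadata,
        pedigree=pedigree,
        parental_haplotypes=parental_haplotypes,
        sweep_windows=[],
        config=config,
    )
    return truth


def _assign_sites(config, sample_ids, pop_of_ind, rng):
    """Place collection sites on a grid spanning roughly 300 km.

    Real per-site coordinates are not modelled; a regular lat/lon grid is a
    stand-in that preserves the ingredients isolation-by-distance analysis
    needs (site labels, plausible pairwise distances up to a few hundred km).
    """
    lat0, lon0 = 5.2, -3.0  # coastal West Africa
    rows = []
    labels = config.pop_labels
    for i, sid in enumerate(sample_ids):
        p = pop_of_ind[i]
        within = i - p * config.n_dip_per_pop
        site_k = within % config.sites_per_pop
        site = f"site_p{p}s{site_k}"
        # grid: populations along longitude, sites along latitude
        lon = lon0 + 0.9 * p + 0.25 * site_k
        lat = lat0 + 0.8 * site_k + 0.15 * p
        if labels is not None:
            species, eco = labels[p]
        else:
            species, eco = "spA", f"eco{p}"
        rows.append((sid, species, eco, site, lat, lon))
    return pd.DataFrame(
        rows, columns=["sample_id", "species", "ecoregion", "site", "lat", "lon"]
    )


def apply_sweep(truth: SimulationTruth, locus: SweepLocus, rng=None) -> SimulationTruth:
    """Copy one donor haplotype over a fraction of haplotypes in a window.

    Cheap stand-in for a selective sweep that directly produces the elevated
    haplotype homozygosity H1/H12/H123 measure, and (when restricted to a
    subset of populations) elevated local Fst.
    """
    if rng is None:
        rng = np.random.default_rng(truth.config.seed + 104729)
    out = copy.deepcopy(truth)
    in_win = (
        (out.chroms == locus.chrom)
        & (out.positions >= locus.start)
        & (out.positions <= locus.end)
    )
    if not in_win.any():
        warnings.warn(f"sweep window {locus.chrom}:{locus.start}-{locus.end} contains no SNPs")
        return out
    if locus.strength == 0:
        out.sweep_windows.append((locus.chrom, locus.start, locus.end))
        return out

    if locus.pops is None:
        ind_mask = np.ones(out.pop_of_ind.size, dtype=bool)
    else:
        ind_mask = np.isin(out.pop_of_ind, locus.pops)
    ind_idx = np.where(ind_mask)[0]
    hap_ids = [(i, h) for i in ind_idx for h in (0, 1)]
    donor = hap_ids[rng.integers(0, len(hap_ids))]
    donor_hap = out.haplotypes[donor[0], donor[1], in_win].copy()
    n_replace = int(round(locus.strength * len(hap_ids)))
    chosen = rng.choice(len(hap_ids), size=n_replace, replace=False)
    for c in chosen:
        i, h = hap_ids[c]
        out.haplotypes[i, h, in_win] = donor_hap
    out.sweep_windows.append((locus.chrom, locus.start, locus.end))
    return out


def simulate(config: SimConfig) -> SimulationTruth:
    """Full truth simulation: frequencies + haplotypes, then every sweep."""
    rng = np.random.default_rng(config.seed)
    truth = simulate_frequencies(config, rng)
    for locus in config.sweep_loci:
        truth = apply_sweep(truth, locus, rng)
    return truth


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class PileupBlock:
    """Per-site base-call counts for all individuals.

    ``base_counts[s, i, b]`` is the number of reads for individual ``i`` at
    site ``s`` calling base ``b`` (A,C,G,T order).  All reads carry the same
    phred quality ``qual`` (the simulator emits a single quality stratum).
    """

    chroms: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    base_counts: np.ndarray  # (S, n_ind, 4) uint16
    qual: int
    sample_ids: list

    @property
    def n_sites(self) -> int:
        return self.positions.size

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    def total_depth(self) -> np.ndarray:
        return self.base_counts.sum(axis=(1, 2))

    def iter_pileups(self):
        for s in range(self.n_sites):
            yield Pileup.from_counts(
                self.chroms[s], int(self.positions[s]), self.ref[s], self.alt[s],
                self.base_counts[s], self.qual,
            )


@dataclass
class Pileup:
    """One site's reads: per individual, lists of (base, phred quality)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    reads: list  # per individual: list of (base, qual)

    @classmethod
    def from_counts(cls, chrom, pos, ref, alt, counts, qual):
        reads = []
        for i in range(counts.shape[0]):
            r = []
            for b in range(4):
                r.extend([(BASES[b], qual)] * int(counts[i, b]))
            reads.append(r)
        return cls(chrom, pos, ref, alt, reads)


def simulate_reads(truth: SimulationTruth, config: SimConfig | None = None, rng=None) -> PileupBlock:
    """Poisson read depth, equal-probability allele sampling, phred errors.

    Per individual per site the read count is Poisson(mean_coverage); each
    read is drawn from the individual's two alleles with probability 1/2 and
    flipped to a uniformly chosen different base with probability
    ``e = 10^(-phred/10)``.
    """
    if config is None:
        config = truth.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 15485863)
    S, n_ind = truth.n_snps, len(truth.sample_ids)
    e = 10.0 ** (-config.base_error / 10.0)

    geno = truth.genotypes.T  # (S, n_ind)
    depth = rng.poisson(config.mean_coverage, size=(S, n_ind))
    # reads supporting the alt allele before error: Binomial(depth, g/2)
    n_alt_origin = rng.binomial(depth, geno / 2.0)
    n_ref_origin = depth - n_alt_origin

    ref_code = np.array([BASE_INDEX[b] for b in truth.ref])
    alt_code = np.array([BASE_INDEX[b] for b in truth.alt])

    counts = np.zeros((S, n_ind, 4), dtype=np.uint16)
    for origin_counts, code in ((n_ref_origin, ref_code), (n_alt_origin, alt_code)):
        for b in range(4):
            sites = np.where(code == b)[0]
            if sites.size == 0:
                continue
            n = origin_counts[sites]  # (n_sites_b, n_ind)
            pvals = np.full(4, e / 3.0)
            pvals[b] = 1.0 - e
            drawn = rng.multinomial(n.ravel(), pvals).reshape(n.shape + (4,))
            counts[sites] += drawn.astype(np.uint16)
    return PileupBlock(
        chroms=truth.chroms,
        positions=truth.positions,
        ref=truth.ref,
        alt=truth.alt,
        base_counts=counts,
        qual=config.base_error,
        sample_ids=list(truth.sample_ids),
    )


# ---------------------------------------------------------------------------
# file emission


def write_pileup_tsv(block: PileupBlock, path) -> None:
    """Pileup interchange TSV: chrom, pos, ref, alt, then one column per
    sample of semicolon-joined base:qual pairs ('.' = no reads)."""
    with open(path, "w") as fh:
        fh.write("\t".join(["chrom", "pos", "ref", "alt", *block.sample_ids]) + "\n")
        for s in range(block.n_sites):
            cells = []
            for i in range(block.n_individuals):
                reads = [
                    f"{BASES[b]}:{block.qual}"
                    for b in range(4)
                    for _ in range(int(block.base_counts[s, i, b]))
                ]
                cells.append(";".join(reads) if reads else ".")
            fh.write(
                "\t".join(
                    [block.chroms[s], str(block.positions[s]), block.ref[s], block.alt[s], *cells]
                )
                + "\n"
            )


def read_pileup_tsv(path) -> tuple:
    """Read the pileup interchange TSV; returns (list of Pileup, sample ids)."""
    pileups = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[4:]
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(f"line {lineno}: expected {len(header)} columns")
            reads = []
            for cell in parts[4:]:
                if cell == "." or not cell:
                    reads.append([])
                else:
                    reads.append(
                        [(bq.split(":")[0], int(bq.split(":")[1])) for bq in cell.split(";")]
                    )
            pileups.append(Pileup(parts[0], int(parts[1]), parts[2], parts[3], reads))
    return pileups, sample_ids


def write_metadata(truth: SimulationTruth, path) -> None:
    truth.metadata.to_csv(path, sep="\t", index=False)


def write_truth_tables(truth: SimulationTruth, prefix) -> None:
    """Truth frequencies / genotypes / pedigree as TSV next to `prefix`."""
    sites = pd.DataFrame(
        {
            "chrom": truth.chroms,
            "pos": truth.positions,
            "ref": truth.ref,
            "alt": truth.alt,
            "ancestral_freq": truth.ancestral_freqs,
        }
    )
    for p in range(truth.pop_freqs.shape[0]):
        sites[f"freq_pop{p}"] = truth.pop_freqs[p]
    sites.to_csv(f"{prefix}.sites.tsv", sep="\t", index=False)
    geno = pd.DataFrame(truth.genotypes.T, columns=truth.sample_ids)
    geno.insert(0, "chrom", truth.chroms)
    geno.insert(1, "pos", truth.positions)
    geno.to_csv(f"{prefix}.genotypes.tsv", sep="\t", index=False)
    pd.DataFrame(truth.pedigree, columns=["offspring", "parent1", "parent2"]).to_csv(
        f"{prefix}.pedigree.tsv", sep="\t", index=False
    )


def write_genome_fasta(truth: SimulationTruth, path, rng=None) -> None:
    """Random genome consistent with SNP reference bases (60-col FASTA)."""
    if rng is None:
        rng = np.random.default_rng(truth.config.seed + 32452843)
    with open(path, "w") as fh:
        for chrom, length in truth.config.chrom_lengths.items():
            seq = BASES[rng.integers(0, 4, length)]
            mask = truth.chroms == chrom
            seq[truth.positions[mask] - 1] = truth.ref[mask]
            fh.write(f">{chrom}\n")
            s = "".join(seq)
            for i in range(0, length, 60):
                fh.write(s[i : i + 60] + "\n")


# synthetic gene model geometry (bp offsets from the gene start):
#   5'UTR 0-99, CDS exon1 100-299, intron 300-499, CDS exon2 500-899,
#   3'UTR 900-1099; total CDS 600 bp (divisible by 3), strand +.
GENE_SPAN = 1100


def _gene_features(gene_id, chrom, start, kind):
    g0, g1 = start, start + GENE_SPAN - 1
    rows = [
        (chrom, "glpop_sim", "gene", g0, g1, ".", "+", ".",
         f"ID={gene_id};Name={gene_id};gene_kind={kind}"),
        (chrom, "glpop_sim", "mRNA", g0, g1, ".", "+", ".",
         f"ID={gene_id}.t1;Parent={gene_id}"),
        (chrom, "glpop_sim", "exon", g0, g0 + 299, ".", "+", ".",
         f"ID={gene_id}.e1;Parent={gene_id}.t1"),
        (chrom, "glpop_sim", "exon", g0 + 500, g1, ".", "+", ".",
         f"ID={gene_id}.e2;Parent={gene_id}.t1"),
        (chrom, "glpop_sim", "five_prime_UTR", g0, g0 + 99, ".", "+", ".",
         f"ID={gene_id}.u5;Parent={gene_id}.t1"),
        (chrom, "glpop_sim", "CDS", g0 + 100, g0 + 299, ".", "+", "0",
         f"ID={gene_id}.c1;Parent={gene_id}.t1"),
        (chrom, "glpop_sim", "CDS", g0 + 500, g0 + 899, ".", "+", "2",
         f"ID={gene_id}.c2;Parent={gene_id}.t1"),
        (chrom, "glpop_sim", "three_prime_UTR", g0 + 900, g1, ".", "+", ".",
         f"ID={gene_id}.u3;Parent={gene_id}.t1"),
    ]
    return rows


def write_annotation(truth: SimulationTruth, path, background_per_chrom: int = 8) -> None:
    """GFF3 with one synthetic "IR gene" centred on each sweep locus plus
    evenly spaced background genes (for gene-ranking tests)."""
    rows = []
    k = 0
    for chrom, start, end in truth.sweep_windows:
        center = (start + end) // 2
        g0 = max(1, center - GENE_SPAN // 2)
        rows.extend(_gene_features(f"IR_{chrom}_{k}", chrom, g0, "IR"))
        k += 1
    sweep_spans = [(c, s, e) for c, s, e in truth.sweep_windows]
    for chrom, length in truth.config.chrom_lengths.items():
        spacing = length // (background_per_chrom + 1)
        for j in range(background_per_chrom):
            g0 = (j + 1) * spacing
            if any(c == chrom and g0 < e + GENE_SPAN and g0 + GENE_SPAN > s
                   for c, s, e in sweep_spans):
                continue  # keep background genes clear of sweep windows
            rows.extend(_gene_features(f"BG_{chrom}_{j}", chrom, g0, "background"))
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in truth.config.chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        df.to_csv(fh, sep="\t", header=False, index=False)
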