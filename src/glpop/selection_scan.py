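"""Haplotype-homozygosity sweep scans and a minimal variant-effect caller.

Garud's statistics summarize the haplotype frequency spectrum p1 >= p2 >= ...
of a window:

    H1   = sum p_i^2
    H12  = (p1 + p2)^2 + sum_{i>=3} p_i^2
    H123 = (p1 + p2 + p3)^2 + sum_{i>=4} p_i^2
    H2/H1 = (H1 - p1^2) / H1

H12 and H123 merge the top haplotype classes, gaining power for soft sweeps
where several haplotypes ride to high frequency together.  Scans run in
fixed-SNP-count windows on phased haplotypes.

The effect classifier maps a SNP onto a single-transcript gene model
(UTRs / CDS / introns, strand-aware) and reports synonymous / missense
calls with p.Xxx123Yyy protein notation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import seq3


@dataclass
class HaplotypeBlock:
    """Phased binary haplotypes: (n_haplotypes, n_snps), positions ascending."""

    haplotypes: np.ndarray
    positions: np.ndarray
    chrom: str = "NA"

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.positions = np.asarray(self.positions)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.haplotypes.shape[1] != self.positions.size:
            raise ValueError("haplotype width and position count differ")


def block_from_truth(truth, chrom: str | None = None, individuals=None) -> HaplotypeBlock:
    """HaplotypeBlock from a SimulationTruth (optionally one chromosome /
    individual subset)."""
    mask = np.ones(truth.n_snps, dtype=bool) if chrom is None else truth.chroms == chrom
    haps = truth.haplotypes if individuals is None else truth.haplotypes[individuals]
    h = haps[:, :, mask].reshape(-1, int(mask.sum()))
    return HaplotypeBlock(h, truth.positions[mask], chrom or "all")


def haplotype_frequencies(block: HaplotypeBlock) -> np.ndarray:
    """Distinct-haplotype frequencies in descending order."""
    if block.haplotypes.size == 0:
        raise ValueError("empty haplotype block")
    _, counts = np.unique(block.haplotypes, axis=0, return_counts=True)
    p = np.sort(counts / counts.sum())[::-1]
    return p


def garud_h(block: HaplotypeBlock) -> dict:
    """H1, H12, H123 and H2/H1 for one window of phased haplotypes."""
    p = haplotype_frequencies(block)
    if p.size < 3:  # absorbed classes count as frequency zero
        p = np.concatenate([p, np.zeros(3 - p.size)])
    sq = p**2
    h1 = sq.sum()
    h12 = (p[0] + p[1]) ** 2 + sq[2:].sum()
    h123 = (p[0] + p[1] + p[2]) ** 2 + sq[3:].sum()
    return {"H1": float(h1), "H12": float(h12), "H123": float(h123),
            "H2H1": float((h1 - sq[0]) / h1)}


def scan_h(block: HaplotypeBlock, window_snps: int = 100, step_snps: int | None = None) -> pd.DataFrame:
    """Garud's H in consecutive windows of exactly ``window_snps`` SNPs.

    The default step equals the window (non-overlapping); a trailing partial
    window is dropped.
    """
    step = window_snps if step_snps is None else step_snps
    S = block.positions.size
    rows = []
    for s0 in range(0, S - window_snps + 1, step):
        idx = slice(s0, s0 + window_snps)
        sub = HaplotypeBlock(block.haplotypes[:, idx], block.positions[idx], block.chrom)
        h = garud_h(sub)
        rows.append(
            {
                "chrom": block.chrom,
                "start_pos": int(block.positions[idx][0]),
                "end_pos": int(block.positions[idx][-1]),
                "n_snps": window_snps,
                **h,
            }
        )
    if not rows:
        warnings.warn("fewer SNPs than one window: empty H scan")
    return pd.DataFrame(
        rows, columns=["chrom", "start_pos", "end_pos", "n_snps", "H1", "H12", "H123", "H2H1"]
    )


# ---------------------------------------------------------------------------
# variant effects


@dataclass
class GeneModelRecord:
    """Single-transcript gene model with its underlying genomic sequence.

    Intervals are 1-based inclusive.  ``sequence`` is the full chromosome
    sequence (string) the coordinates refer to.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list  # [(start, end)]
    cds: list  # [(start, end)] in genomic order
    utr5: list = field(default_factory=list)
    utr3: list = field(default_factory=list)
    sequence: str = ""

    def __post_init__(self):
        cds_len = sum(e - s + 1 for s, e in self.cds)
        if cds_len % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {cds_len} not divisible by 3")

    @property
    def span(self) -> tuple:
        coords = [c for s, e in self.exons for c in (s, e)]
        return min(coords), max(coords)

    def cds_sequence(self) -> str:
        seq = "".join(self.sequence[s - 1 : e] for s, e in sorted(self.cds))
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset of a genomic position within the spliced CDS, in
        translation (5'->3') orientation; None if not in the CDS."""
        parts = sorted(self.cds)
        off = 0
        hit = None
        for s, e in parts:
            if s <= pos <= e:
                hit = off + (pos - s)
            off += e - s + 1
        if hit is None:
            return None
        return off - 1 - hit if self.strand == "-" else hit


def _in_any(pos, intervals):
    return any(s <= pos <= e for s, e in intervals)


def classify_variant_effect(variant: tuple, model: GeneModelRecord) -> dict:
    """Effect of a SNP (chrom, pos, ref, alt) on a gene model.

    Categories: five_prime_UTR, three_prime_UTR, intronic, synonymous,
    missense, intergenic.  Coding calls include p.Asn224Ile-style notation.
    A mismatch between ``ref`` and the model sequence raises.
    """
    chrom, pos, ref, alt = variant
    if chrom != model.chrom:
        return {"category": "intergenic", "protein": None}
    if model.sequence and model.sequence[pos - 1].upper() != ref.upper():
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: model has {model.sequence[pos - 1]}, variant says {ref}"
        )
    lo, hi = model.span
    if pos < lo or pos > hi:
        return {"category": "intergenic", "protein": None}
    off = model.cds_offset(pos)
    if off is not None:
        cds = model.cds_sequence()
        codon_i = off // 3
        within = off % 3
        codon = list(cds[3 * codon_i : 3 * codon_i + 3])
        base_ref, base_alt = ref, alt
        if model.strand == "-":
            base_ref = str(Seq(ref).reverse_complement())
            base_alt = str(Seq(alt).reverse_complement())
        assert codon[within].upper() == base_ref.upper()
        aa_ref = str(Seq("".join(codon)).translate())
        codon[within] = base_alt
        aa_alt = str(Seq("".join(codon)).translate())
        if aa_ref == aa_alt:
            return {"category": "synonymous", "protein": f"p.{seq3(aa_ref)}{codon_i + 1}{seq3(aa_alt)}"}
        return {"category": "missense", "protein": f"p.{seq3(aa_ref)}{codon_i + 1}{seq3(aa_alt)}"}
    if _in_any(pos, model.utr5):
        return {"category": "five_prime_UTR", "protein": None}
    if _in_any(pos, model.utr3):
        return {"category": "three_prime_UTR", "protein": None}
    if _in_any(pos, model.exons):
        # exonic but non-coding and not annotated UTR: treat by position
        return {"category": "five_prime_UTR" if _upstream(pos, model) else "three_prime_UTR", "protein": None}
    return {"category": "intronic", "protein": None}


def _upstream(pos, model):
    cds_lo = min(s for s, _ in model.cds)
    cds_hi = max(e for _, e in model.cds)
    return pos < cds_lo if model.strand == "+" else pos > cds_hi


def gene_models_from_gff(gff_path, fasta_path) -> dict:
    """Load one GeneModelRecord per gene from GFF3 + genome FASTA."""
    import gffutils
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models = {}
    for gene in db.features_of_type("gene"):
        def coll(ftype):
            return sorted(
                (f.start, f.end)
                for f in db.region(region=(gene.seqid, gene.start, gene.end), featuretype=ftype)
            )
        models[gene.id] = GeneModelRecord(
            gene_id=gene.id,
            chrom=gene.seqid,
            strand=gene.strand,
            exons=coll("exon"),
            cds=coll("CDS"),
            utr5=coll("five_prime_UTR"),
            utr3=coll("three_prime_UTR"),
            sequence=seqs.get(gene.seqid, ""),
        )
    return models


def effect_table(variants, models: dict) -> pd.DataFrame:
    """Classify each (chrom, pos, ref, alt) against every overlapping gene
    model; SNPs hitting no model are intergenic."""
    rows = []
    for chrom, pos, ref, alt in variants:
        hit = False
        for m in models.values():
            if m.chrom != chrom:
                continue
            lo, hi = m.span
            if lo <= pos <= hi:
                eff = classify_variant_effect((chrom, pos, ref, alt), m)
                rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                             "gene_id": m.gene_id, **eff})
                hit = True
        if not hit:
            rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                         "gene_id": None, "category": "intergenic", "protein": None})
    return pd.DataFrame(rows)


def write_haplotypes(block: HaplotypeBlock, path) -> None:
    df = pd.DataFrame(block.haplotypes.T)
    df.insert(0, "chrom", block.chrom)
    df.insert(1, "pos", block.positions)
    df.to_csv(path, sep="\t", index=False)


def read_haplotypes(path) -> HaplotypeBlock:
    df = pd.read_csv(path, sep="\t")
    chrom = str(df["chrom"].iloc[0])
    mat = df.drop(columns=["chrom", "pos"]).to_numpy(dtype=np.uint8).T
    return HaplotypeBlock(mat, df["pos"].to_numpy(), chrom)
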