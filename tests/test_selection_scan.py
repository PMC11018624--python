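"""Garud's H statistics, window scans, variant-effect classification."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from glpop import selection_scan as sel, simdata


def block_from_freqs(freqs, n_haps=16, n_snps=4, seed=0):
    """Haplotype block whose distinct-haplotype frequencies are `freqs`."""
    assert abs(sum(freqs) - 1) < 1e-9
    rng = np.random.default_rng(seed)
    distinct = rng.integers(0, 2, size=(len(freqs), n_snps))
    while np.unique(distinct, axis=0).shape[0] < len(freqs):
        distinct = rng.integers(0, 2, size=(len(freqs), n_snps))
    rows = []
    for k, f in enumerate(freqs):
        rows.extend([distinct[k]] * round(f * n_haps))
    return sel.HaplotypeBlock(np.array(rows), np.arange(1, n_snps + 1))


def garud_oracle(hap_matrix):
    """Independent brute-force H statistics via string counting."""
    counts = Counter(tuple(row) for row in hap_matrix)
    p = sorted((c / hap_matrix.shape[0] for c in counts.values()), reverse=True)
    while len(p) < 3:
        p.append(0.0)
    h1 = sum(x**2 for x in p)
    h12 = (p[0] + p[1]) ** 2 + sum(x**2 for x in p[2:])
    h123 = (p[0] + p[1] + p[2]) ** 2 + sum(x**2 for x in p[3:])
    return h1, h12, h123


class TestGarudH:
    def test_single_haplotype(self):
        block = sel.HaplotypeBlock(np.zeros((8, 5), dtype=int), np.arange(1, 6))
        h = sel.garud_h(block)
        assert h["H1"] == h["H12"] == h["H123"] == 1.0
        assert h["H2H1"] == 0.0

    def test_half_quarter_quarter(self):
        h = sel.garud_h(block_from_freqs([0.5, 0.25, 0.25]))
        assert h["H1"] == pytest.approx(0.375)
        assert h["H12"] == pytest.approx(0.625)
        assert h["H123"] == pytest.approx(1.0)

    def test_four_equal_classes(self):
        h = sel.garud_h(block_from_freqs([0.25] * 4))
        assert h["H1"] == pytest.approx(0.25)
        assert h["H12"] == pytest.approx(0.375)
        assert h["H123"] == pytest.approx(0.625)

    def test_matches_brute_force_on_random_blocks(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            m = rng.integers(0, 2, size=(rng.integers(4, 20), rng.integers(2, 8)))
            block = sel.HaplotypeBlock(m, np.arange(1, m.shape[1] + 1))
            h = sel.garud_h(block)
            h1, h12, h123 = garud_oracle(m)
            assert h["H1"] == pytest.approx(h1)
            assert h["H12"] == pytest.approx(h12)
            assert h["H123"] == pytest.approx(h123)
            assert 0 < h["H1"] <= h["H12"] <= h["H123"] <= 1.0
            assert 0 <= h["H2H1"] < 1.0

    def test_empty_block_rejected(self):
        with pytest.raises(ValueError):
            sel.garud_h(sel.HaplotypeBlock(np.zeros((0, 3), dtype=int), np.arange(1, 4)))


class TestScan:
    def test_window_count(self):
        rng = np.random.default_rng(1)
        block = sel.HaplotypeBlock(rng.integers(0, 2, (10, 250)), np.arange(1, 251))
        scan = sel.scan_h(block, window_snps=100)
        assert len(scan) == 2  # trailing 50-SNP partial window dropped
        assert scan["n_snps"].unique().tolist() == [100]

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(2)
        m = rng.integers(0, 2, (12, 200))
        block = sel.HaplotypeBlock(m, np.arange(1, 201))
        perm = sel.HaplotypeBlock(m[rng.permutation(12)], np.arange(1, 201))
        pd.testing.assert_frame_equal(sel.scan_h(block, 50), sel.scan_h(perm, 50))

    def test_too_few_snps_warns_empty(self):
        block = sel.HaplotypeBlock(np.zeros((4, 10), dtype=int), np.arange(1, 11))
        with pytest.warns(UserWarning, match="fewer SNPs"):
            scan = sel.scan_h(block, window_snps=100)
        assert scan.empty

    def test_sweep_elevates_window_h12(self):
        cfg = simdata.SimConfig(
            n_pops=1, n_dip_per_pop=40, chrom_lengths={"1": 600_000},
            mut_density=0.004, target_fst=0.0, seed=6,
            sweep_loci=(simdata.SweepLocus("1", 300_000, 40_000, 0.6),),
        )
        truth = simdata.simulate(cfg)
        scan = sel.scan_h(sel.block_from_truth(truth, "1"), 100)
        sweep = scan[(scan["start_pos"] <= 320_000) & (scan["end_pos"] >= 280_000)]
        assert sweep["H12"].max() > scan["H12"].median()

    def test_haplotype_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        block = sel.HaplotypeBlock(rng.integers(0, 2, (6, 30)), np.arange(10, 310, 10), "2L")
        path = tmp_path / "haps.tsv"
        sel.write_haplotypes(block, path)
        back = sel.read_haplotypes(path)
        np.testing.assert_array_equal(back.haplotypes, block.haplotypes)
        assert back.chrom == "2L"


def planted_gene(seq_len=3000):
    """Plus-strand single-exon-pair gene with a long CDS; codon 224 is AAT."""
    rng = np.random.default_rng(11)
    seq = list("ACGT"[i] for i in rng.integers(0, 4, seq_len))
    # gene: 5'UTR 101-200, CDS 201-1100 (900 bp = 300 codons), 3'UTR 1101-1200
    cds_start = 201
    codon224 = cds_start + 223 * 3  # genomic pos of codon 224 base 1
    seq[codon224 - 1 : codon224 + 2] = list("AAT")  # Asn
    codon100 = cds_start + 99 * 3
    seq[codon100 - 1 : codon100 + 2] = list("CTG")  # Leu
    model = sel.GeneModelRecord(
        gene_id="g", chrom="1", strand="+",
        exons=[(101, 1200)], cds=[(cds_start, 1100)],
        utr5=[(101, 200)], utr3=[(1101, 1200)], sequence="".join(seq),
    )
    return model, codon224, codon100


class TestVariantEffects:
    def test_missense_with_protein_notation(self):
        model, codon224, _ = planted_gene()
        eff = sel.classify_variant_effect(("1", codon224 + 1, "A", "T"), model)
        # AAT -> ATT: Asn224Ile
        assert eff["category"] == "missense"
        assert eff["protein"] == "p.Asn224Ile"

    def test_synonymous_leucine(self):
        model, _, codon100 = planted_gene()
        eff = sel.classify_variant_effect(("1", codon100 + 2, "G", "A"), model)
        # CTG -> CTA: both leucine
        assert eff["category"] == "synonymous"

    def test_utr_intron_intergenic(self):
        model, _, _ = planted_gene()
        assert sel.classify_variant_effect(("1", 150, model.sequence[149], "A" if model.sequence[149] != "A" else "C"), model)["category"] == "five_prime_UTR"
        assert sel.classify_variant_effect(("1", 1150, model.sequence[1149], "A" if model.sequence[1149] != "A" else "C"), model)["category"] == "three_prime_UTR"
        assert sel.classify_variant_effect(("1", 2500, model.sequence[2499], "A" if model.sequence[2499] != "A" else "C"), model)["category"] == "intergenic"

    def test_intronic_category(self):
        model, _, _ = planted_gene()
        intron_model = sel.GeneModelRecord(
            gene_id="g2", chrom="1", strand="+",
            exons=[(101, 400), (701, 1200)], cds=[(201, 400), (701, 1100)],
            utr5=[(101, 200)], utr3=[(1101, 1200)], sequence=model.sequence,
        )
        eff = sel.classify_variant_effect(("1", 550, model.sequence[549], "A" if model.sequence[549] != "A" else "C"), intron_model)
        assert eff["category"] == "intronic"

    def test_minus_strand_translation(self):
        # CDS 201-206 on minus strand; genomic CATTGC -> revcomp GCAATG
        seq = "N" * 200 + "CATTGC" + "N" * 100
        model = sel.GeneModelRecord(
            gene_id="m", chrom="1", strand="-", exons=[(201, 206)], cds=[(201, 206)],
            sequence=seq,
        )
        assert model.cds_sequence() == "GCAATG"  # Ala, Met
        # change genomic pos 202 (A->G): revcomp codon2 ATG -> ACG, Met->Thr
        eff = sel.classify_variant_effect(("1", 202, "A", "G"), model)
        assert eff["category"] == "missense"
        assert eff["protein"] == "p.Met2Thr"

    def test_reference_mismatch_raises(self):
        model, codon224, _ = planted_gene()
        with pytest.raises(ValueError, match="mismatch"):
            sel.classify_variant_effect(("1", codon224, "G", "T"), model)

    def test_cds_length_must_be_codon_multiple(self):
        with pytest.raises(ValueError, match="divisible"):
            sel.GeneModelRecord(
                gene_id="bad", chrom="1", strand="+", exons=[(1, 10)], cds=[(1, 10)],
                sequence="A" * 10,
            )

    def test_synthetic_annotation_round_trip(self, tmp_path):
        """Gene models loaded from the simulator's GFF3 + FASTA classify
        planted variants in every compartment correctly."""
        cfg = simdata.SimConfig(
            n_pops=1, n_dip_per_pop=4, chrom_lengths={"1": 60_000},
            mut_density=0.001, target_fst=0.0, seed=3,
            sweep_loci=(simdata.SweepLocus("1", 30_000, 5_000, 0.5),),
        )
        truth = simdata.simulate(cfg)
        gff, fasta = tmp_path / "a.gff3", tmp_path / "g.fa"
        simdata.write_annotation(truth, gff)
        simdata.write_genome_fasta(truth, fasta)
        models = sel.gene_models_from_gff(gff, fasta)
        ir = next(m for k, m in models.items() if k.startswith("IR_"))
        g0 = ir.span[0]
        # compartments per the simulator's fixed gene geometry
        for offset, expect in [(50, "five_prime_UTR"), (150, None), (350, "intronic"), (950, "three_prime_UTR")]:
            pos = g0 + offset
            ref = ir.sequence[pos - 1]
            alt = "A" if ref != "A" else "C"
            cat = sel.classify_variant_effect(("1", pos, ref, alt), ir)["category"]
            if expect is None:
                assert cat in ("synonymous", "missense")  # inside the CDS
            else:
                assert cat == expect
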