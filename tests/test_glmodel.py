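"""Genotype-likelihood model, allele-frequency EM, filters and BEAGLE I/O."""

import math

import numpy as np
import pandas as pd
import pytest

from glpop import glmodel, simdata
from glpop.simdata import Pileup, PileupBlock

from conftest import certain_gls


def one_ind_pileup(reads):
    return Pileup("1", 100, "A", "C", [reads])


class TestGenotypeLikelihoods:
    def test_closed_form_four_major_reads(self):
        """Four reads matching the major allele at e = 0.001."""
        e = 0.001
        gl = glmodel.genotype_likelihoods(one_ind_pileup([("A", 30)] * 4))
        l0 = (1 - e) ** 4
        l1 = (0.5 * (1 - e) + 0.5 * e / 3) ** 4
        l2 = (e / 3) ** 4
        expect = np.log([l0, l1, l2]) - math.log(l0)
        np.testing.assert_allclose(gl[0], expect, atol=1e-12)

    def test_zero_reads_flat(self):
        gl = glmodel.genotype_likelihoods(one_ind_pileup([]))
        np.testing.assert_array_equal(gl[0], [0.0, 0.0, 0.0])

    def test_single_minor_read_limit(self):
        """One minor read at tiny error: het likelihood is half the hom-minor."""
        gl = glmodel.genotype_likelihoods(one_ind_pileup([("C", 90)]))
        assert gl[0, 2] == 0.0  # maximal
        np.testing.assert_allclose(gl[0, 1], math.log(0.5), atol=1e-8)
        assert gl[0, 0] < math.log(1e-8)

    def test_counts_path_matches_reference(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 6, size=(20, 5, 4)).astype(np.uint16)
        major = rng.integers(0, 4, 20)
        minor = (major + 1) % 4
        fast = glmodel.gl_from_counts(counts, 25, major, minor)
        for s in range(20):
            p = Pileup.from_counts("1", s + 1, simdata.BASES[major[s]], simdata.BASES[minor[s]], counts[s], 25)
            slow = glmodel.genotype_likelihoods(p, simdata.BASES[major[s]], simdata.BASES[minor[s]])
            np.testing.assert_allclose(fast[s], slow, atol=1e-10)

    def test_normalization_max_zero(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 8, size=(10, 4, 4)).astype(np.uint16)
        gl = glmodel.gl_from_counts(counts, 20, np.zeros(10, int), np.ones(10, int))
        has_reads = counts.sum(axis=2) > 0
        assert np.allclose(gl.max(axis=2)[has_reads], 0.0)


class TestAlleleFrequency:
    def test_all_hom_major_zero(self):
        gls = certain_gls(np.zeros((6, 30), dtype=int))
        assert np.allclose(glmodel.estimate_maf(gls.values), 0.0, atol=1e-6)

    def test_two_certain_hets_half(self):
        gls = certain_gls(np.ones((2, 5), dtype=int))
        np.testing.assert_allclose(glmodel.estimate_maf(gls.values), 0.5, atol=1e-6)

    def test_matches_grid_search_oracle(self):
        """EM frequency maximizes the same likelihood as a 1e-4 grid search."""
        rng = np.random.default_rng(5)
        S, N = 100, 15
        f_true = rng.uniform(0.02, 0.98, S)
        g = rng.binomial(2, f_true[:, None], (S, N))
        depth = rng.poisson(8, (S, N))
        n_alt = rng.binomial(depth, g / 2.0)
        values = np.zeros((S, N, 4), dtype=np.uint16)
        values[..., 0] = depth - n_alt
        values[..., 1] = n_alt
        values = glmodel.gl_from_counts(values, 20, np.zeros(S, int), np.ones(S, int))
        f_em = glmodel.estimate_freq(values)
        grid = np.linspace(0, 1, 10_001)
        for s in range(S):
            ll = np.array([glmodel._loglik_at(values[s][None], g)[0] for g in grid[::100]])
            coarse = grid[::100][np.argmax(ll)]
            fine = grid[(grid >= coarse - 0.011) & (grid <= coarse + 0.011)]
            llf = np.array([glmodel._loglik_at(values[s][None], g)[0] for g in fine])
            f_grid = fine[np.argmax(llf)]
            assert abs(f_em[s] - f_grid) < 1e-3

    def test_noisy_recovery(self):
        """f = 0.3 at 15x coverage recovered within +-0.1."""
        rng = np.random.default_rng(8)
        N, f = 20, 0.3
        g = rng.binomial(2, f, N)
        depth = rng.poisson(15, N)
        n_alt = rng.binomial(depth, g / 2.0)
        counts = np.zeros((1, N, 4), dtype=np.uint16)
        counts[0, :, 0] = depth - n_alt
        counts[0, :, 1] = n_alt
        gl = glmodel.gl_from_counts(counts, 20, np.zeros(1, int), np.ones(1, int))
        f_hat = glmodel.estimate_maf(gl)
        assert abs(f_hat[0] - min(g.mean() / 2, 1 - g.mean() / 2)) < 0.1

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            glmodel.estimate_maf(np.zeros((4, 3)))


class TestSnpLrt:
    def test_monomorphic_null(self):
        gls = certain_gls(np.zeros((10, 1), dtype=int))
        stat, p = glmodel.snp_lrt(gls.values[0], 0.0)
        assert stat == 0.0 and p == 1.0

    def test_calibration_on_simulated_sites(self):
        """Monomorphic sites are mostly dropped; truly polymorphic mostly kept."""
        rng = np.random.default_rng(10)
        N, reps = 50, 300
        # monomorphic: all hom-ref at 15x, phred 20
        depth = rng.poisson(15, size=(reps, N))
        e = 0.01
        n_err = rng.binomial(depth, e)
        counts = np.zeros((reps, N, 4), dtype=np.uint16)
        counts[..., 0] = depth - n_err
        counts[..., 1] = n_err  # worst case: every error hits the alt allele
        gl = glmodel.gl_from_counts(counts, 20, np.zeros(reps, int), np.ones(reps, int))
        f = glmodel.estimate_freq(gl)
        _, p = glmodel.snp_lrt(gl, f)
        assert (p > 0.05).mean() >= 0.90
        # polymorphic at f=0.2
        g = rng.binomial(2, 0.2, size=(reps, N))
        n_alt = rng.binomial(depth, g / 2.0)
        counts2 = np.zeros((reps, N, 4), dtype=np.uint16)
        counts2[..., 0] = depth - n_alt
        counts2[..., 1] = n_alt
        gl2 = glmodel.gl_from_counts(counts2, 20, np.zeros(reps, int), np.ones(reps, int))
        f2 = glmodel.estimate_freq(gl2)
        _, p2 = glmodel.snp_lrt(gl2, f2)
        assert (p2 <= 0.05).mean() >= 0.95


def toy_block():
    """Six sites, 4 individuals; site 2 exceeds depth, site 4 is monomorphic."""
    S, N = 6, 4
    counts = np.zeros((S, N, 4), dtype=np.uint16)
    counts[:, :, 0] = 5  # ref reads everywhere
    counts[:, [0, 1], 1] = 5  # two hets per site -> MAF 0.25
    counts[4] = 0
    counts[4, :, 0] = 6  # monomorphic site: ref only
    counts[2, 0, 0] = 200  # depth blow-up
    return PileupBlock(
        chroms=np.repeat("1", S), positions=np.arange(1, S + 1) * 100,
        ref=np.repeat("A", S), alt=np.repeat("C", S),
        base_counts=counts, qual=30, sample_ids=[f"i{k}" for k in range(N)],
    )


class TestFilters:
    def test_toy_site_filters_by_hand(self):
        block = toy_block()
        gls = glmodel.gl_from_pileups(block)
        cfg = glmodel.FilterConfig(max_total_depth=100, min_base_q=20, maf_min=0.05)
        kept, stats = glmodel.filter_sites(gls, block, cfg)
        # site index 2 fails depth; site 4 fails the SNP test; 4 remain
        assert stats.n_depth_fail == 1 and stats.n_snp_p_fail == 1
        assert kept.n_sites == 4
        assert list(kept.sites["pos"]) == [100, 200, 400, 600]

    def test_polymorphism_filters_off(self):
        block = toy_block()
        gls = glmodel.gl_from_pileups(block)
        cfg = glmodel.FilterConfig(max_total_depth=100, polymorphism_filters_on=False)
        kept, _ = glmodel.filter_sites(gls, block, cfg)
        assert kept.n_sites == 6  # only missingness applies; nothing is missing

    def test_low_quality_block_all_missing(self):
        block = toy_block()
        gls = glmodel.gl_from_pileups(block, min_base_q=40)  # qual 30 < 40
        assert gls.missing_mask().all()
        cfg = glmodel.FilterConfig()
        kept, stats = glmodel.filter_sites(gls, block, cfg)
        assert kept.n_sites == 0 and stats.n_missingness_fail == 6

    def test_individual_missingness_boundary(self):
        S = 100
        g = np.zeros((3, S), dtype=int)
        gls = certain_gls(g)
        gls.values[: S // 4, 1] = 0.0  # ind 1 missing at exactly 25%
        gls.values[: S // 4 + 1, 2] = 0.0  # ind 2 missing at 26%
        kept, removed = glmodel.filter_individuals(gls, 0.25)
        assert removed == ["i2"]
        assert kept.sample_ids == ["i0", "i1"]

    def test_all_individuals_removed_raises(self):
        gls = certain_gls(np.zeros((2, 10), dtype=int))
        gls.values[:] = 0.0
        with pytest.raises(ValueError):
            glmodel.filter_individuals(gls, 0.25)


class TestBeagle:
    def test_round_trip(self, tmp_path, two_pop_gls):
        gls, _ = two_pop_gls
        sub = gls.take_sites(np.arange(50))
        path = tmp_path / "gl.beagle.gz"
        glmodel.write_beagle(sub, path)
        back = glmodel.read_beagle(path)
        assert back.sample_ids == sub.sample_ids
        pd.testing.assert_frame_equal(back.sites, sub.sites.reset_index(drop=True))
        # compare on the normalized linear scale
        a = np.exp(sub.values) / np.exp(sub.values).sum(axis=2, keepdims=True)
        b = np.exp(back.values) / np.exp(back.values).sum(axis=2, keepdims=True)
        np.testing.assert_allclose(a, b, atol=1e-5)

    def test_empty_matrix_header_only(self, tmp_path):
        gls = certain_gls(np.zeros((2, 0), dtype=int))
        path = tmp_path / "empty.beagle"
        glmodel.write_beagle(gls, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("marker\tallele1\tallele2")

    def test_column_order_contract(self, tmp_path):
        """A (0.3, 0.6, 0.1) triplet lands in AA, Aa, aa column order."""
        values = np.log(np.array([[[0.3, 0.6, 0.1]]]))
        values -= values.max(axis=2, keepdims=True)
        gls = glmodel.GLMatrix(
            sites=pd.DataFrame({"chrom": ["1"], "pos": [7], "major": ["G"], "minor": ["T"]}),
            values=values, sample_ids=["x"],
        )
        path = tmp_path / "one.beagle"
        glmodel.write_beagle(gls, path)
        row = path.read_text().splitlines()[1].split("\t")
        assert row[0] == "1_7" and row[1] == "2" and row[2] == "3"
        np.testing.assert_allclose([float(v) for v in row[3:]], [0.3, 0.6, 0.1], atol=1e-6)

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.beagle"
        path.write_text("marker\tallele1\tallele2\tx\tx\tx\n1_5\t0\t1\t0.2\n")
        with pytest.raises(ValueError, match="line 2"):
            glmodel.read_beagle(path)


class TestConsistency:
    def test_high_coverage_calls_match_truth(self):
        """At 50x the argmax genotype is almost always the simulated one."""
        cfg = simdata.SimConfig(
            n_pops=1, n_dip_per_pop=10, chrom_lengths={"1": 300_000},
            mut_density=0.0035, target_fst=0.0, mean_coverage=50, seed=21,
        )
        truth = simdata.simulate(cfg)
        block = simdata.simulate_reads(truth)
        gls = glmodel.gl_from_pileups(block)
        # align calls to the minor-allele labelling
        swap = gls.sites["minor"].to_numpy() == truth.ref
        g_true = truth.genotypes.T.copy()
        g_true[swap] = 2 - g_true[swap]
        calls = gls.values.argmax(axis=2)
        assert (calls != g_true).mean() < 0.01
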