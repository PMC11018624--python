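"""End-to-end orchestration: simulate -> GL -> filters -> per-stratum
SFS/diversity -> pairwise Fst + outliers + genes -> H scans -> PCA /
admixture / kinship -> isolation by distance -> report.

A run is driven by one :class:`RunConfig` (loadable from YAML), writes every
stage's tables under a single output directory, and records a manifest with
parameters, seeds and per-stage row counts so the filter cascade is
auditable.  Strata are species x ecoregion, mirroring per-population GL
calling.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, differentiation as dif, glmodel, selection_scan as sel
from . import sfs_diversity as sfsd, simdata, spatial, structure_kinship as sk


@dataclass
class RunConfig:
    """Full-run parameters; every pipeline constant is a named field."""

    outdir: str = "glpop_run"
    seed: int = 0
    # simulation (None -> use the default study)
    sim: dict | None = None
    # filters
    max_total_depth: int = 6000
    min_base_q: int = 30
    min_ind_fraction: float = 0.25
    snp_pvalue_max: float = 0.05
    maf_min: float = 0.05
    max_ind_missing: float = 0.25
    # windows
    window_bp: int = 10_000
    step_bp: int = 5_000
    h_window_snps: int = 100
    outlier_multiplier: float = 3.0
    # structure / kinship
    admixture_K: int = 2
    admixture_starts: int = 2
    admixture_max_iter: int = 300
    call_posterior_min: float = 0.95
    # spatial
    n_perm: int = 999
    # Ne: mutation rate per bp per generation; no authoritative default —
    # Ne is only reported when a rate is supplied
    mu: float | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def default_study_config(seed: int = 0) -> simdata.SimConfig:
    """The default synthetic study: 2 species-like groups x 3 ecoregions,
    one divergent sweep locus per group, one inversion-like block, 2 sib
    pairs, low Poisson coverage."""
    labels = tuple(
        (sp, eco) for sp in ("speciesA", "speciesB") for eco in ("CS", "DF", "RF")
    )
    return simdata.SimConfig(
        n_pops=6,
        n_dip_per_pop=12,
        target_fst=0.05,
        chrom_lengths={"chr1": 400_000, "chr2": 400_000},
        mut_density=0.004,
        sweep_loci=(
            simdata.SweepLocus("chr1", 100_000, 30_000, 0.8, pops=(0,), name="IR_A"),
            simdata.SweepLocus("chr2", 300_000, 30_000, 0.8, pops=(3,), name="IR_B"),
        ),
        inversion_block=simdata.InversionBlock("chr2", 60_000, 140_000, 0.15),
        n_sib_pairs=2,
        mean_coverage=14.0,
        base_error=20,
        seed=seed,
        pop_labels=labels,
    )


def _sim_config(cfg: RunConfig) -> simdata.SimConfig:
    if cfg.sim is None:
        return default_study_config(cfg.seed)
    d = dict(cfg.sim)
    if "sweep_loci" in d:
        d["sweep_loci"] = tuple(simdata.SweepLocus(**s) for s in d["sweep_loci"])
    if d.get("inversion_block"):
        d["inversion_block"] = simdata.InversionBlock(**d["inversion_block"])
    if "pop_labels" in d and d["pop_labels"] is not None:
        d["pop_labels"] = tuple(tuple(x) for x in d["pop_labels"])
    if "chrom_lengths" in d:
        d["chrom_lengths"] = dict(d["chrom_lengths"])
    d.setdefault("seed", cfg.seed)
    return simdata.SimConfig(**d)


def _filters(cfg: RunConfig, polymorphism: bool) -> glmodel.FilterConfig:
    return glmodel.FilterConfig(
        max_total_depth=cfg.max_total_depth,
        min_base_q=cfg.min_base_q,
        min_ind_fraction=cfg.min_ind_fraction,
        snp_pvalue_max=cfg.snp_pvalue_max,
        maf_min=cfg.maf_min,
        polymorphism_filters_on=polymorphism,
    )


def _subset_block(block: simdata.PileupBlock, idx) -> simdata.PileupBlock:
    return simdata.PileupBlock(
        chroms=block.chroms, positions=block.positions, ref=block.ref, alt=block.alt,
        base_counts=block.base_counts[:, idx], qual=block.qual,
        sample_ids=[block.sample_ids[i] for i in idx],
    )


def _align_sites(a: glmodel.GLMatrix, b: glmodel.GLMatrix):
    """Restrict two GL matrices to their shared (chrom, pos) site list."""
    ka = list(zip(a.sites["chrom"], a.sites["pos"]))
    kb = list(zip(b.sites["chrom"], b.sites["pos"]))
    shared = set(ka) & set(kb)
    ia = np.array([i for i, k in enumerate(ka) if k in shared])
    ib = np.array([i for i, k in enumerate(kb) if k in shared])
    return a.take_sites(ia), b.take_sites(ib)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage; returns the output directory.

    Re-running with an identical config reproduces all outputs (every
    random draw is derived from ``cfg.seed``).
    """
    t_start = time.time()
    out = Path(cfg.outdir)
    for sub in ("data", "diversity", "fst", "selection", "structure", "spatial", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "seed": cfg.seed,
        "stages": {},
    }

    # --- stage: simulate ---------------------------------------------------
    sim_cfg = _sim_config(cfg)
    truth = simdata.simulate(sim_cfg)
    block = simdata.simulate_reads(truth)
    meta = truth.metadata
    simdata.write_metadata(truth, out / "data" / "metadata.tsv")
    simdata.write_truth_tables(truth, str(out / "data" / "truth"))
    simdata.write_annotation(truth, out / "data" / "annotation.gff3")
    simdata.write_genome_fasta(truth, out / "data" / "genome.fa")
    manifest["stages"]["simulate"] = {
        "n_snps": int(truth.n_snps),
        "n_individuals": len(truth.sample_ids),
        "sweep_windows": [list(map(str, w)) for w in truth.sweep_windows],
    }

    # --- stage: genotype likelihoods (global + per stratum) ---------------
    gls_all = glmodel.gl_from_pileups(block, min_base_q=0)
    gls_poly, stats_poly = glmodel.filter_sites(gls_all, block, _filters(cfg, True))
    gls_poly, removed = glmodel.filter_individuals(gls_poly, cfg.max_ind_missing)
    glmodel.write_beagle(gls_poly, out / "data" / "genotype_likelihoods.beagle.gz")
    manifest["stages"]["gl"] = {**stats_poly.as_dict(), "removed_individuals": removed}

    strata = {}
    for (sp, eco), grp in meta.groupby(["species", "ecoregion"], sort=True):
        idx = np.asarray(grp.index)
        sub_block = _subset_block(block, idx)
        sub_gls = glmodel.gl_from_pileups(sub_block)
        poly, _ = glmodel.filter_sites(sub_gls, sub_block, _filters(cfg, True))
        allsites, _ = glmodel.filter_sites(sub_gls, sub_block, _filters(cfg, False))
        strata[(sp, eco)] = {"idx": idx, "poly": poly, "all": allsites}

    # --- stage: diversity per stratum --------------------------------------
    div_rows, window_frames = [], []
    for (sp, eco), st in strata.items():
        saf = sfsd.saf_likelihoods(st["all"])
        sfs = sfsd.estimate_sfs(saf, folded=True)
        th = sfsd.per_site_thetas(saf, sfs)
        wd = sfsd.windowed_diversity(th, cfg.window_bp, cfg.step_bp)
        wd.insert(0, "species", sp)
        wd.insert(1, "ecoregion", eco)
        window_frames.append(wd)
        theta_site = float(th.theta_w.sum() / th.theta_w.size)
        row = {
            "species": sp, "ecoregion": eco, "n": st["all"].n_individuals,
            "pi": float(th.pi.sum() / th.pi.size), "theta_w": theta_site,
            "tajimas_d_windows": float(np.nanmean(wd["tajimas_d"])),
            "tajimas_d_genomewide": sfsd.genomewide_tajimas_d(th),
        }
        if cfg.mu is not None:
            row["Ne"] = sfsd.estimate_ne(theta_site, cfg.mu)
        div_rows.append(row)
    diversity = pd.DataFrame(div_rows)
    diversity.to_csv(out / "diversity" / "per_stratum.tsv", sep="\t", index=False)
    pd.concat(window_frames).to_csv(out / "diversity" / "windows.tsv", sep="\t", index=False)
    manifest["stages"]["diversity"] = {"n_strata": len(div_rows)}

    # --- stage: differentiation (within species, between ecoregions) ------
    fst_rows, outlier_frames, gene_frames = [], [], []
    genes = dif.read_gff_genes(out / "data" / "annotation.gff3")
    keys = sorted(strata)
    for i, k1 in enumerate(keys):
        for k2 in keys[i + 1 :]:
            if k1[0] != k2[0]:
                continue  # ecoregion pairs within each species
            a, b = _align_sites(strata[k1]["poly"], strata[k2]["poly"])
            if a.n_sites < 10:
                warnings.warn(f"too few shared sites for {k1} vs {k2}")
                continue
            saf1, saf2 = sfsd.saf_likelihoods(a), sfsd.saf_likelihoods(b)
            comp = dif.fst_components_from_gls(saf1, saf2, labels=(f"{k1[0]}:{k1[1]}", f"{k2[0]}:{k2[1]}"))
            wfst = dif.windowed_fst(comp, cfg.window_bp, cfg.step_bp)
            label = f"{k1[0]}_{k1[1]}_vs_{k2[1]}"
            fst_rows.append(
                {
                    "species": k1[0], "pop1": k1[1], "pop2": k2[1],
                    "n_sites": comp.alpha.size,
                    "fst_genomewide": dif.genomewide_fst(comp),
                    "fst_window_mean": dif.mean_window_fst(wfst),
                }
            )
            try:
                called = dif.designate_outliers(wfst)
            except ValueError:
                continue
            called.insert(0, "comparison", label)
            outlier_frames.append(called)
            gt = dif.intersect_genes(called, genes)
            if len(gt):
                gt.insert(0, "comparison", label)
                gene_frames.append(gt)
    pd.DataFrame(fst_rows).to_csv(out / "fst" / "genomewide.tsv", sep="\t", index=False)
    if outlier_frames:
        pd.concat(outlier_frames).to_csv(out / "fst" / "windows.tsv", sep="\t", index=False)
    gene_table = (
        pd.concat(gene_frames).sort_values("peak_fst", ascending=False).reset_index(drop=True)
        if gene_frames
        else pd.DataFrame()
    )
    gene_table.to_csv(out / "fst" / "outlier_genes.tsv", sep="\t", index=False)
    manifest["stages"]["differentiation"] = {
        "n_comparisons": len(fst_rows),
        "n_outlier_windows": int(sum(f["is_outlier"].sum() for f in outlier_frames)) if outlier_frames else 0,
        "n_outlier_genes": int(len(gene_table)),
    }

    # --- stage: selection scans (phased haplotypes, per stratum) ----------
    scan_frames = []
    for (sp, eco), st in strata.items():
        for chrom in sim_cfg.chrom_lengths:
            hb = sel.block_from_truth(truth, chrom, individuals=st["idx"])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scan = sel.scan_h(hb, cfg.h_window_snps)
            if len(scan):
                scan.insert(0, "species", sp)
                scan.insert(1, "ecoregion", eco)
                scan_frames.append(scan)
    hscan = pd.concat(scan_frames) if scan_frames else pd.DataFrame()
    hscan.to_csv(out / "selection" / "hscan.tsv", sep="\t", index=False)

    models = sel.gene_models_from_gff(out / "data" / "annotation.gff3", out / "data" / "genome.fa")
    ir_models = {k: m for k, m in models.items() if k.startswith("IR_")}
    focal_variants = []
    for m in ir_models.values():
        lo, hi = m.span
        in_gene = (truth.chroms == m.chrom) & (truth.positions >= lo) & (truth.positions <= hi)
        for s in np.where(in_gene)[0]:
            focal_variants.append((truth.chroms[s], int(truth.positions[s]), truth.ref[s], truth.alt[s]))
    effects = sel.effect_table(focal_variants, ir_models) if focal_variants else pd.DataFrame()
    effects.to_csv(out / "selection" / "focal_gene_effects.tsv", sep="\t", index=False)
    manifest["stages"]["selection"] = {"n_windows": int(len(hscan)), "n_focal_variants": int(len(effects))}

    # --- stage: structure & kinship ----------------------------------------
    meta_kept = meta[meta["sample_id"].isin(gls_poly.sample_ids)].reset_index(drop=True)
    freqs = glmodel.estimate_freq(gls_poly.values)
    dosages = sk.posterior_dosages(gls_poly, freqs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, scores, eigvals = sk.covariance_pca(dosages, freqs)
    pcs = pd.DataFrame(scores[:, :4], columns=[f"PC{i+1}" for i in range(scores[:, :4].shape[1])])
    pcs.insert(0, "sample_id", gls_poly.sample_ids)
    pcs = pcs.merge(meta_kept, on="sample_id")
    pcs.to_csv(out / "structure" / "pca.tsv", sep="\t", index=False)

    fit = sk.admixture_em(
        gls_poly, cfg.admixture_K, seed=cfg.seed, n_starts=cfg.admixture_starts,
        max_iter=cfg.admixture_max_iter,
    )
    qdf = pd.DataFrame(fit.Q, columns=[f"Q{k+1}" for k in range(fit.K)])
    qdf.insert(0, "sample_id", gls_poly.sample_ids)
    qdf.to_csv(out / "structure" / "admixture_Q.tsv", sep="\t", index=False)

    mask = []
    if sim_cfg.inversion_block is not None:
        iv = sim_cfg.inversion_block
        mask = [(iv.chrom, iv.start - 1, iv.end)]
    calls = sk.hard_call(gls_poly, freqs, cfg.call_posterior_min)
    kin = sk.king_kinship(calls, gls_poly.sample_ids, sites=gls_poly.sites, mask_intervals=mask)
    kin = sk.classify_relationships(kin)
    kin.to_csv(out / "structure" / "kinship.tsv", sep="\t", index=False)
    manifest["stages"]["structure"] = {
        "admixture_loglik": fit.loglik,
        "n_kinship_pairs": int(len(kin)),
        "n_full_sib": int((kin["category"] == "full_sib").sum()),
        "pc1_variance": float(eigvals[0]),
    }

    # --- stage: isolation by distance --------------------------------------
    ibd_rows, corr_frames = [], []
    for sp, grp in meta_kept.groupby("species"):
        ids = list(grp["sample_id"])
        pos = {sid: i for i, sid in enumerate(gls_poly.sample_ids)}
        order = [pos[s] for s in ids]
        sub = kin[(kin["id1"].isin(ids)) & (kin["id2"].isin(ids)) & (kin["id1"] != kin["id2"])]
        n = len(ids)
        phi_m = np.zeros((n, n))
        index = {s: i for i, s in enumerate(ids)}
        for _, r in sub.iterrows():
            i, j = index[r["id1"]], index[r["id2"]]
            phi_m[i, j] = phi_m[j, i] = r["phi"]
        geo = spatial.distance_matrix_km(grp["lat"].to_numpy(), grp["lon"].to_numpy())
        try:
            r_obs, p = spatial.mantel(phi_m, geo, n_perm=cfg.n_perm, seed=cfg.seed)
        except ValueError:
            r_obs, p = float("nan"), float("nan")
        ibd_rows.append({"species": sp, "genetic": "kinship", "r": r_obs, "p": p})
        cg = spatial.mantel_correlogram(phi_m, geo, n_perm=cfg.n_perm, seed=cfg.seed)
        cg.insert(0, "species", sp)
        corr_frames.append(cg)
        # between-site Fst IBD
        sub_idx = np.asarray(order)
        fst_m, coords = spatial.site_fst_matrix(calls[sub_idx], grp.reset_index(drop=True), min_n=4)
        vals = fst_m.to_numpy()
        if np.isfinite(vals[np.triu_indices(len(fst_m), 1)]).all() and len(fst_m) >= 4:
            geo_s = spatial.distance_matrix_km(coords["lat"].to_numpy(), coords["lon"].to_numpy())
            r2, p2 = spatial.mantel(-vals, geo_s, n_perm=cfg.n_perm, seed=cfg.seed)
            ibd_rows.append({"species": sp, "genetic": "site_fst", "r": r2, "p": p2})
        fst_m.to_csv(out / "spatial" / f"site_fst_{sp}.tsv", sep="\t")
    pd.DataFrame(ibd_rows).to_csv(out / "spatial" / "mantel.tsv", sep="\t", index=False)
    pd.concat(corr_frames).to_csv(out / "spatial" / "correlogram.tsv", sep="\t", index=False)
    manifest["stages"]["spatial"] = {"n_tests": len(ibd_rows)}

    # --- report -------------------------------------------------------------
    summary_report(out)
    manifest["runtime_s"] = round(time.time() - t_start, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


def summary_report(outdir) -> None:
    """Tables already on disk are re-read and rendered as the run's figures:
    Fst Manhattan scan, H123 scan, PCA scatter by ecoregion, correlogram."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    rep = out / "report"
    rep.mkdir(exist_ok=True)

    wpath = out / "fst" / "windows.tsv"
    if wpath.exists():
        w = pd.read_csv(wpath, sep="\t")
        fig, ax = plt.subplots(figsize=(9, 3))
        for comp, grp in w.groupby("comparison"):
            x = grp["start"] + (grp["chrom"].astype("category").cat.codes * 1e6)
            ax.scatter(x, grp["fst"], s=4, label=comp, alpha=0.6)
        ax.set_xlabel("window start (chrom-offset bp)")
        ax.set_ylabel("Hudson Fst")
        ax.legend(fontsize=5)
        fig.savefig(rep / "fst_scan.png", dpi=120, bbox_inches="tight")
        plt.close(fig)

    hpath = out / "selection" / "hscan.tsv"
    if hpath.exists():
        h = pd.read_csv(hpath, sep="\t")
        if len(h):
            fig, ax = plt.subplots(figsize=(9, 3))
            for (sp, eco), grp in h.groupby(["species", "ecoregion"]):
                x = grp["start_pos"] + (grp["chrom"].astype("category").cat.codes * 1e6)
                ax.plot(x, grp["H123"], lw=0.8, label=f"{sp}:{eco}", alpha=0.7)
            ax.set_ylabel("Garud's H123")
            ax.legend(fontsize=5)
            fig.savefig(rep / "h123_scan.png", dpi=120, bbox_inches="tight")
            plt.close(fig)

    ppath = out / "structure" / "pca.tsv"
    if ppath.exists():
        p = pd.read_csv(ppath, sep="\t")
        fig, ax = plt.subplots(figsize=(5, 4))
        for (sp, eco), grp in p.groupby(["species", "ecoregion"]):
            ax.scatter(grp["PC1"], grp["PC2"], s=12, label=f"{sp}:{eco}")
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend(fontsize=6)
        fig.savefig(rep / "pca.png", dpi=120, bbox_inches="tight")
        plt.close(fig)

    cpath = out / "spatial" / "correlogram.tsv"
    if cpath.exists():
        c = pd.read_csv(cpath, sep="\t")
        fig, ax = plt.subplots(figsize=(5, 3))
        for sp, grp in c.groupby("species"):
            mid = (grp["d_lo_km"] + grp["d_hi_km"]) / 2
            ax.plot(mid, grp["r"], marker="o", label=sp)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("distance class midpoint (km)")
        ax.set_ylabel("Mantel r")
        ax.legend(fontsize=7)
        fig.savefig(rep / "correlogram.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
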