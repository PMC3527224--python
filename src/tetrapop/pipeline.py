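"""End-to-end orchestration: simulate -> genotype -> stats -> inherit -> scan.

Each stage reads the previous stage's plain-text outputs from the run
directory and writes its own, so stages are individually rerunnable.  A
single master seed deterministically derives per-stage seeds
(:class:`numpy.random.SeedSequence` spawning); rerunning with the same
configuration is bit-identical, which the manifest records via sha256
checksums of every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from . import genotyper as gt
from . import inheritance_sim as isim
from . import inheritance_test as itest
from . import popgen_stats as pg
from . import sweep_scan as scan
from . import synthetic_data as syn
from .vcf import write_vcf

log = logging.getLogger("tetrapop")

STAGES = ("simulate", "genotype", "stats", "inherit", "scan")

CLASS_NAMES = {"S": "synonymous", "N": "nonsynonymous", "I": "intron", "O": "other"}


class SimParams(BaseModel):
    """Generator parameters (see :class:`tetrapop.synthetic_data.SimConfig`)."""

    model_config = ConfigDict(extra="forbid")

    n_genes: int = 200
    n_exons: int = 3
    exon_length: int = 402
    intron_length: int = 150
    theta_silent: float = 0.043
    theta_nonsyn: float = 0.017
    d_syn: float = 8.7e-4
    d_nonsyn: float = 2.7e-4
    d_intron: float = 9.6e-4
    outgroup_scale: float = 20.0
    mean_depth: float = 25.0
    error_rate: float = 0.0015
    sweep_fraction: float = 0.0
    sweep_carrier_fraction: float = 0.9
    inheritance: str = "tetrasomic"  # model generating the synthetic sample
    inheritance_td: float | None = None


class RunConfig(BaseModel):
    """Validated configuration of a full pipeline run (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    seed: int
    sim: SimParams = SimParams()
    lod_min: float = 2.0
    min_depth: int = 4  # coverage must be strictly greater than this
    site_class_mode: str = "codon"  # "codon" (context-exact) or "annotation"
    inherit_runs: int = 2000
    td_grid: list[float] = [0.2, 0.4, 0.6, 0.8, 1.0]
    alpha: float = 0.01
    window_snps: int = 100
    clr_tail: float = 0.05
    pi_tail: float = 0.05
    include_partial_windows: bool = True


def _stage_seed(seed: int, stage: str) -> np.random.Generator:
    idx = STAGES.index(stage)
    child = np.random.SeedSequence(seed).spawn(len(STAGES))[idx]
    return np.random.default_rng(child)


def _sim_config(cfg: RunConfig) -> syn.SimConfig:
    d = cfg.sim.model_dump()
    d.pop("inheritance")
    d.pop("inheritance_td")
    return syn.SimConfig(seed=cfg.seed, **d)


# ---------------------------------------------------------------------------
# Stage 1: simulate
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    rng = _stage_seed(cfg.seed, "simulate")
    scfg = _sim_config(cfg)
    model = isim.InheritanceModel(cfg.sim.inheritance, cfg.sim.inheritance_td)

    genes = syn.make_gene_models(scfg, rng)
    triples = [syn.simulate_triple(g, scfg, rng) for g in genes]
    n_swept = int(round(scfg.sweep_fraction * len(genes)))
    swept_ids = set(
        rng.choice([g.gene_id for g in genes], size=n_swept, replace=False)
    ) if n_swept else set()

    pileups = []
    truth_rows = []
    for g, t in zip(genes, triples):
        sample = syn.simulate_population(g, scfg, model, rng, triple=t)
        if g.gene_id in swept_ids:
            sample = syn.inject_sweep(sample, scfg.sweep_carrier_fraction, rng)
        pileups.append(syn.simulate_pileups(sample, scfg, rng))
        k = sample.derived_counts()
        for s in range(sample.n_sites):
            truth_rows.append(
                (g.gene_id, int(sample.positions[s]), sample.ancestral[s],
                 sample.derived[s], int(k[s]), sample.site_class[s])
            )

    syn.write_gene_models_bed(genes, outdir / "gene_models.bed", cfg.seed)
    syn.write_triples_fasta(triples, outdir / "triples.fasta", cfg.seed)
    syn.write_pileups_tsv(pd.concat(pileups, ignore_index=True),
                          outdir / "pileups.tsv", cfg.seed)
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "pos", "ancestral", "derived", "k", "site_class"]
    )
    with open(outdir / "true_frequencies.tsv", "w") as fh:
        fh.write(f"# tetrapop truth; seed={cfg.seed}\n")
        truth.to_csv(fh, sep="\t", index=False)
    (outdir / "swept_genes.txt").write_text(
        "\n".join(sorted(swept_ids)) + ("\n" if swept_ids else "")
    )

    # per-individual error-calibration alignments: each individual's read
    # consensus (focal + error flips) against the sister and outgroup
    # sequences, emulating the reads/reference/outgroup three-way comparison
    focal_cat = "".join(t.focal for t in triples)
    sister_cat = "".join(t.sister for t in triples)
    out_cat = "".join(t.outgroup for t in triples)
    cap = min(len(focal_cat), 200_000)
    with open(outdir / "error_calibration.fasta", "w") as fh:
        fh.write(f"; tetrapop error-calibration alignments; seed={cfg.seed}\n")
        fh.write(f">reference\n{sister_cat[:cap]}\n>outgroup\n{out_cat[:cap]}\n")
        base = np.array(list(focal_cat[:cap]))
        for i in range(syn.N_INDIVIDUALS):
            reads = syn._mutate(base, np.full(cap, scfg.error_rate), rng)
            fh.write(f">reads_ind{i:02d}\n" + "".join(reads) + "\n")
    with open(outdir / "sim_config.json", "w") as fh:
        fh.write(scfg.to_json() + "\n")
    log.info("simulate: %d genes, %d SNPs, %d swept", len(genes), len(truth), n_swept)


# ---------------------------------------------------------------------------
# Stage 2: genotype
# ---------------------------------------------------------------------------

def _read_fasta(path: Path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(";") or not line:
                continue
            if line.startswith(">"):
                name = line[1:]
                seqs[name] = []
            else:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def stage_genotype(cfg: RunConfig, outdir: Path) -> None:
    pileups = syn.read_pileups_tsv(outdir / "pileups.tsv")

    # error rates from the three-way calibration alignments
    calib = _read_fasta(outdir / "error_calibration.fasta")
    err_rows = []
    e_by_ind = np.empty(syn.N_INDIVIDUALS)
    for i in range(syn.N_INDIVIDUALS):
        est = gt.estimate_error_rate(
            calib[f"reads_ind{i:02d}"], calib["reference"], calib["outgroup"],
            individual=i,
        )
        # a zero estimate would make the likelihood degenerate; floor at 1e-5
        e_by_ind[i] = max(est.e, 1e-5)
        err_rows.append((i, est.e, est.n_columns,
                         est.mismatches_reads_outgroup,
                         est.mismatches_reference_outgroup, est.clamped))
    pd.DataFrame(
        err_rows,
        columns=["individual", "e", "n_columns", "mm_reads_outgroup",
                 "mm_reference_outgroup", "clamped"],
    ).to_csv(outdir / "error_rates.tsv", sep="\t", index=False)
    e_pooled = float(e_by_ind.mean())

    count_cols = ["count_A", "count_C", "count_G", "count_T"]
    vcf_rows = []
    call_rows = []
    for (gene_id, pos), grp in pileups.groupby(["gene_id", "pos"], sort=True):
        grp = grp.sort_values("individual")
        counts = grp[count_cols].to_numpy()
        if counts.shape[0] != syn.N_INDIVIDUALS:
            raise ValueError(f"{gene_id}:{pos}: missing individuals in pileup")
        depths = counts.sum(axis=1)
        pooled = counts.sum(axis=0)
        keep, reason = gt.site_filter(depths, pooled, e_pooled,
                                      min_depth=cfg.min_depth)
        variants = gt.detect_variants(pooled, e_pooled)
        if keep and len(variants) < 2:
            continue  # monomorphic under the error model: not a SNP
        a1 = gt.BASES[variants[0]] if variants else "N"
        a2 = gt.BASES[variants[1]] if len(variants) > 1 else "N"
        rec = {"chrom": gene_id, "pos": int(pos), "ref": a1, "alt": a2,
               "filter": "PASS" if keep else reason}
        if not keep or len(variants) < 2:
            for i in range(syn.N_INDIVIDUALS):
                rec[f"dosage_{i}"] = -1
            vcf_rows.append(rec)
            continue
        dosage, lod, called = gt.call_genotypes(
            counts[:, None, :],
            np.array([variants[1]]),  # dosage counts ALT copies
            np.array([variants[0]]),
            e_by_ind,
            lod_min=cfg.lod_min,
        )
        for i in range(syn.N_INDIVIDUALS):
            d = int(dosage[i, 0])
            ok = bool(called[i, 0])
            rec[f"dosage_{i}"] = d if ok else -1
            call_rows.append((gene_id, int(pos), a1, a2, i, d,
                              float(lod[i, 0]), "called" if ok else "no_call"))
        vcf_rows.append(rec)

    calls = pd.DataFrame(
        call_rows,
        columns=["gene_id", "pos", "a1", "a2", "individual", "alt_dosage",
                 "log_odds", "status"],
    )
    with open(outdir / "calls.tsv", "w") as fh:
        fh.write(f"# tetrapop genotype calls; seed={cfg.seed}\n")
        calls.to_csv(fh, sep="\t", index=False)
    write_vcf(outdir / "calls.vcf", pd.DataFrame(vcf_rows))
    log.info("genotype: %d sites written, mean e=%.5f", len(vcf_rows), e_pooled)


# ---------------------------------------------------------------------------
# Stage 3: stats
# ---------------------------------------------------------------------------

def _load_calls_matrix(outdir: Path) -> pd.DataFrame:
    calls = pd.read_csv(outdir / "calls.tsv", sep="\t", comment="#")
    wide = calls.pivot(
        index=["gene_id", "pos", "a1", "a2"], columns="individual", values="alt_dosage"
    )
    status = calls.pivot(
        index=["gene_id", "pos", "a1", "a2"], columns="individual", values="status"
    )
    complete = (status == "called").all(axis=1)
    wide = wide[complete].astype(int).reset_index()
    return wide


def stage_stats(cfg: RunConfig, outdir: Path) -> None:
    genes = syn.read_gene_models_bed(outdir / "gene_models.bed")
    triples = {t.gene_id: t for t in
               syn.read_triples_fasta(outdir / "triples.fasta", genes)}
    gene_map = {g.gene_id: g for g in genes}
    wide = _load_calls_matrix(outdir)
    ind_cols = list(range(syn.N_INDIVIDUALS))
    n = syn.N_CHROM

    kept_ids = [g.gene_id for g in genes if pg.identity_filter(triples[g.gene_id])]
    kept = set(kept_ids)

    site_rows = []
    for row in wide.itertuples(index=False):
        if row.gene_id not in kept:
            continue
        triple = triples[row.gene_id]
        gene = gene_map[row.gene_id]
        alt_count = int(sum(getattr(row, f"_{4 + i}") for i in range(12)))
        if not 0 < alt_count < n:
            continue  # monomorphic after calling
        alleles = (row.a1, row.a2)
        anc = pg.polarize(alleles, triple.sister[row.pos], triple.outgroup[row.pos])
        if anc is None:
            derived_count = -1
            anc_label = "unpolarized"
        else:
            derived_count = alt_count if anc == row.a1 else n - alt_count
            anc_label = anc
        if cfg.site_class_mode == "codon":
            cls = pg.classify_site(gene, triple.focal, row.pos, alleles)
        else:
            cls = CLASS_NAMES[gene.site_classes()[row.pos]]
        site_rows.append(
            (row.gene_id, row.pos, row.a1, row.a2, anc_label, derived_count,
             min(alt_count, n - alt_count), alt_count, cls)
        )
    sites = pd.DataFrame(
        site_rows,
        columns=["gene_id", "pos", "a1", "a2", "ancestral", "k",
                 "minor_count", "alt_count", "site_class"],
    )
    with open(outdir / "site_records.tsv", "w") as fh:
        fh.write(f"# tetrapop site records; seed={cfg.seed}\n")
        sites.to_csv(fh, sep="\t", index=False)

    # SFS (folded over all SNPs; unfolded over polarized SNPs)
    folded = pg.build_sfs(sites["minor_count"].to_numpy(), "folded", n)
    pol = sites[sites["ancestral"] != "unpolarized"]
    unfolded = pg.build_sfs(pol["k"].to_numpy(), "unfolded", n)
    for sfs, name in ((folded, "sfs_folded.tsv"), (unfolded, "sfs_unfolded.tsv")):
        pd.DataFrame({"class": np.arange(len(sfs.counts)), "count": sfs.counts}) \
            .to_csv(outdir / name, sep="\t", index=False)

    # per-gene summaries stratified by nominal class composition
    summaries = []
    for gene_id in kept_ids:
        gene = gene_map[gene_id]
        nominal = gene.site_classes()
        lengths = {"all": gene.length}
        for code, cname in CLASS_NAMES.items():
            lengths[cname] = int((nominal == code).sum())
        gsites = sites[sites["gene_id"] == gene_id]
        row = {"gene_id": gene_id, "length": gene.length}
        for cname in ["all", "synonymous", "nonsynonymous", "intron"]:
            L = lengths[cname]
            sel = gsites if cname == "all" else gsites[gsites["site_class"] == cname]
            S = len(sel)
            row[f"L_{cname}"] = L
            row[f"S_{cname}"] = S
            row[f"theta_w_{cname}"] = pg.watterson_theta(S, n, L) if L > 0 else np.nan
            row[f"pi_{cname}"] = (
                pg.pi(sel["alt_count"].to_numpy(), n, L) if L > 0 else np.nan
            )
        summaries.append(row)
    gsum = pd.DataFrame(summaries)
    with open(outdir / "gene_summaries.tsv", "w") as fh:
        fh.write(f"# tetrapop gene summaries; seed={cfg.seed}\n")
        gsum.to_csv(fh, sep="\t", index=False)

    # pairwise FST between the four 3-individual populations (12 gametes each)
    pops = {p: ind_cols[3 * p : 3 * p + 3] for p in range(4)}
    dosages = wide[[c for c in wide.columns if isinstance(c, int)]].to_numpy()
    fst_rows = []
    for p1 in range(4):
        for p2 in range(p1 + 1, 4):
            c1 = dosages[:, pops[p1]].sum(axis=1)
            c2 = dosages[:, pops[p2]].sum(axis=1)
            seg = (c1 + c2 > 0) & (c1 + c2 < 24)
            _, avg = pg.pairwise_fst(c1[seg], c2[seg], 12, 12)
            fst_rows.append((f"pop{p1}", f"pop{p2}", int(seg.sum()), avg))
    pd.DataFrame(fst_rows, columns=["pop_a", "pop_b", "n_sites", "fst"]) \
        .to_csv(outdir / "fst.tsv", sep="\t", index=False)
    log.info("stats: %d SNPs (%d polarized), %d genes kept",
             len(sites), len(pol), len(kept_ids))


# ---------------------------------------------------------------------------
# Stage 4: inheritance test
# ---------------------------------------------------------------------------

def _ascertained_pool(
    model: isim.InheritanceModel,
    theta_source: np.ndarray,
    runs: int,
    cfg: RunConfig,
    e: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a model pool subjected to the same genotyping ascertainment
    as the observed data.

    Each run's 48 chromosomes are assembled into 12 individuals, read pileups
    are simulated at the run's segregating sites (Poisson depth, error-prone
    reads), tetraploid genotypes are called with the same log-odds and
    coverage rules as the genotype stage, and only sites where all 12
    individuals are confidently called survive.  One random surviving SNP
    per run enters the pool, keeping pool entries independent.  Returns
    (folded minor classes, pooled inferred dosage-class counts).
    """
    e = max(e, 1e-5)
    demes = 1 if model.kind == "tetrasomic" else 2
    t_merge = None if model.kind == "tetrasomic" else model.t_d
    classes: list[int] = []
    geno_classes = np.zeros(5, dtype=np.int64)
    for _ in range(runs):
        theta = theta_source[rng.integers(theta_source.size)]
        haps = isim.coalescent_sample(48, theta, demes=demes, t_merge=t_merge, rng=rng)
        S = haps.shape[1]
        if S == 0:
            continue
        dosages, _ = isim.assemble_individuals(haps, model, rng=rng)
        frac = dosages / 4.0
        p = np.empty((12, S, 4))
        p[:, :, 0] = (1 - frac) * (1 - e) + frac * (e / 3)  # ancestral base
        p[:, :, 1] = frac * (1 - e) + (1 - frac) * (e / 3)  # derived base
        p[:, :, 2] = e / 3
        p[:, :, 3] = e / 3
        depth = rng.poisson(cfg.sim.mean_depth, size=(12, S))
        counts = rng.multinomial(depth, p)
        depth_ok = (counts.sum(axis=2) > cfg.min_depth).all(axis=0)
        called_dosage, _, called = gt.call_genotypes(
            counts, np.ones(S, dtype=int), np.zeros(S, dtype=int), e,
            lod_min=cfg.lod_min,
        )
        complete = called.all(axis=0) & depth_ok
        k = called_dosage.astype(int).sum(axis=0)
        seg = complete & (k > 0) & (k < 48)
        if not seg.any():
            continue
        ks = np.minimum(k[seg], 48 - k[seg])
        classes.append(int(ks[rng.integers(ks.size)]))
        geno_classes += np.bincount(called_dosage[:, seg].ravel(), minlength=5)
    return np.array(classes, dtype=int), geno_classes


def stage_inherit(cfg: RunConfig, outdir: Path) -> None:
    rng = _stage_seed(cfg.seed, "inherit")
    sites = pd.read_csv(outdir / "site_records.tsv", sep="\t", comment="#")
    gsum = pd.read_csv(outdir / "gene_summaries.tsv", sep="\t", comment="#")
    err = pd.read_csv(outdir / "error_rates.tsv", sep="\t")
    e_mean = float(err["e"].mean())

    # empirical per-gene silent locus thetas (theta/site * silent length)
    silent_L = gsum["L_synonymous"] + gsum["L_intron"]
    silent_S = gsum["S_synonymous"] + gsum["S_intron"]
    theta_site = silent_S / (pg.harmonic(47) * silent_L)
    theta_source = (theta_site * silent_L).to_numpy()
    theta_source = theta_source[theta_source > 0]

    observed = sites["minor_count"].to_numpy()
    calls = pd.read_csv(outdir / "calls.tsv", sep="\t", comment="#")
    pol = sites[sites["ancestral"] != "unpolarized"][["gene_id", "pos", "a1", "ancestral"]]
    merged = calls.merge(pol, on=["gene_id", "pos"], suffixes=("", "_site"))
    derived_dosage = np.where(
        merged["a1"] == merged["ancestral"], merged["alt_dosage"], 4 - merged["alt_dosage"]
    )
    obs_classes = np.bincount(derived_dosage[merged["status"] == "called"], minlength=5)

    # observed SNPs survived genotyping, so the simulated pools are pushed
    # through the same pileup -> call -> filter chain before comparison
    models = [isim.InheritanceModel("tetrasomic")] + [
        isim.InheritanceModel("disomic", td) for td in cfg.td_grid
    ]
    pools = []
    pool_geno = {}
    for m in models:
        classes, gcounts = _ascertained_pool(
            m, theta_source, cfg.inherit_runs, cfg, e_mean, rng
        )
        pools.append((m.label, classes))
        pool_geno[m.label] = gcounts
    report = itest.classify_inheritance(observed, pools, alpha=cfg.alpha)
    for comp in report["comparisons"]:
        gcounts = pool_geno[comp.model_label]
        if obs_classes.sum() > 0 and gcounts.sum() > 0:
            comp.genotype_divergence = itest.compare_genotype_classes(
                obs_classes, gcounts, cfg.alpha
            )
    out = {
        "alpha": report["alpha"],
        "n_observed_snps": int(observed.size),
        "runs_per_model": cfg.inherit_runs,
        "consistent_models": report["consistent_models"],
        "comparisons": [
            {
                "model": c.model_label,
                "U": c.u_statistic,
                "p": c.p_value,
                "verdict": c.verdict,
                "genotype_divergence": c.genotype_divergence,
            }
            for c in report["comparisons"]
        ],
    }
    with open(outdir / "inheritance_report.json", "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
        fh.write("\n")
    pool_rows = []
    for label, classes in pools:
        hist = np.bincount(classes, minlength=25)
        for cls in range(1, 25):
            pool_rows.append((label, cls, int(hist[cls])))
    pd.DataFrame(pool_rows, columns=["model", "folded_class", "count"]) \
        .to_csv(outdir / "simulated_pools.tsv", sep="\t", index=False)
    log.info("inherit: consistent models %s", out["consistent_models"])


# ---------------------------------------------------------------------------
# Stage 5: sweep scan
# ---------------------------------------------------------------------------

def stage_scan(cfg: RunConfig, outdir: Path) -> None:
    sites = pd.read_csv(outdir / "site_records.tsv", sep="\t", comment="#")
    gsum = pd.read_csv(outdir / "gene_summaries.tsv", sep="\t", comment="#")
    pol = sites[sites["ancestral"] != "unpolarized"]

    bg_sfs = pg.build_sfs(pol["k"].to_numpy(), "unfolded", syn.N_CHROM)
    q = scan.background_proportions(bg_sfs)

    win_rows = []
    for gene_id, grp in pol.groupby("gene_id"):
        windows = scan.make_windows(
            gene_id, grp["k"].to_numpy(), grp["pos"].to_numpy(), cfg.window_snps
        )
        for w in windows:
            if w.partial and not cfg.include_partial_windows and w.index > 0:
                continue
            win_rows.append((gene_id, w.index, w.n_snps, w.partial, scan.clr_score(w, q)))
    windows_df = pd.DataFrame(
        win_rows, columns=["gene_id", "window", "n_snps", "partial", "clr"]
    )
    with open(outdir / "window_clr.tsv", "w") as fh:
        fh.write(f"# tetrapop window CLR scores; seed={cfg.seed}\n")
        windows_df.to_csv(fh, sep="\t", index=False)

    genes_df = gsum[["gene_id", "pi_all"]].rename(columns={"pi_all": "pi_bp"})
    cand = scan.select_candidates(
        genes_df, windows_df, clr_tail=cfg.clr_tail, pi_tail=cfg.pi_tail
    )
    with open(outdir / "candidates.tsv", "w") as fh:
        fh.write(
            f"# tetrapop sweep candidates; seed={cfg.seed}; "
            f"clr_threshold={cand.clr_threshold:.6g}; "
            f"pi_threshold={cand.pi_threshold:.6g}\n"
        )
        cand.table.to_csv(fh, sep="\t", index=False)

    r2 = scan.check_independence(
        cand.table["max_clr"].fillna(0.0).to_numpy(), cand.table["pi_bp"].to_numpy()
    )
    swept_path = outdir / "swept_genes.txt"
    swept = set(swept_path.read_text().split()) if swept_path.exists() else set()
    universe = set(genes_df["gene_id"])
    result = {
        "n_genes": len(genes_df),
        "n_windows": len(windows_df),
        "n_candidates": len(cand.candidates),
        "clr_pi_r2": None if np.isnan(r2) else r2,
        "degenerate": cand.degenerate,
    }
    if swept & universe:
        enr = scan.enrichment_test(cand.candidates, swept & universe, universe)

        def _finite(x):
            return x if np.isfinite(x) else None

        result["swept_set_enrichment"] = {
            "table": [enr.in_set_candidate, enr.in_set_other,
                      enr.out_set_candidate, enr.out_set_other],
            "fold_enrichment": _finite(enr.fold_enrichment),
            "odds_ratio": _finite(enr.odds_ratio),
            "p_value": enr.p_value,
            "recovered_fraction": enr.in_set_candidate_fraction,
        }
    with open(outdir / "scan_report.json", "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("scan: %d candidates of %d genes", len(cand.candidates), len(genes_df))


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig, outdir: Path | str,
                 stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in order and write a checksum manifest.

    A stage failure aborts with the failing stage named; outputs of completed
    stages are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    funcs = {
        "simulate": stage_simulate,
        "genotype": stage_genotype,
        "stats": stage_stats,
        "inherit": stage_inherit,
        "scan": stage_scan,
    }
    for stage in stages:
        log.info("stage %s ...", stage)
        try:
            funcs[stage](cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    checksums = {}
    for path in sorted(outdir.iterdir()):
        if path.name == "manifest.json" or path.is_dir():
            continue
        checksums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "tetrapop_version": __version__,
        "seed": cfg.seed,
        "config": json.loads(cfg.model_dump_json()),
        "stages": list(stages),
        "checksums": checksums,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
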