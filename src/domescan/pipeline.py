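"""End-to-end orchestration of the two-genus selection-scan pipeline.

Stage order per genus: MAF filter -> kinship (Reynolds + NJ) -> LD model
(EM) -> wild-vs-domestic hapFLK contrasts -> Stouffer combination ->
q-values -> candidate regions -> haplotype-consistency filter.  Across
genera: stratum assignment through the homology map, stratified FDR for
final detection, and the convergence curve.  Finally, per-region delta-pi
classification and (when conservation scores are provided) genetic-load
analysis.

Everything is driven by a single config and a single seed; a re-run with
the same config produces bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import combine as cmb
from . import convergence as conv
from . import load as loadmod
from .io import (
    GenotypePanel, GeneTrack, HomologyMap,
    read_conservation, read_genes_bed, read_homology, read_vcf, filter_sites,
)
from .ldmodel import cluster_frequencies, fit_cluster_model
from .popgen import build_kinship, inbreeding_coefficient
from .scan import run_contrast

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    K: int = 25
    n_em_runs: int = 5
    em_max_iter: int = 100
    em_tol: float = 1e-6
    maf_min: float = 0.10
    q_max: float = 1e-2
    merge_gap: int = 50_000
    flk_p_max: float = 1e-4
    grid_max: float = 0.2
    grid_min: float = 0.002
    grid_n: int = 10
    constraint_min: float = 1.5
    load_alpha: float = 0.05
    kinship_subsample: float = 0.01
    trim_upper: float = 0.01
    consistency_min_fraction: float = 0.5
    drop_inconsistent: bool = True
    train_unphased: bool = True
    seed: int = 0

    def validate(self) -> None:
        assert 0 <= self.maf_min < 0.5 and 0 < self.q_max <= 1
        assert self.K >= 1 and self.n_em_runs >= 1 and self.merge_gap > 0
        assert 0 < self.grid_min < self.grid_max <= 1


@dataclass
class GenusScan:
    panel: GenotypePanel                 # filtered, all groups
    scan_table: pd.DataFrame             # per-SNP scores, p_comb, q
    kinship: object
    regions: list = field(default_factory=list)          # pre-stratification
    final_regions: list = field(default_factory=list)    # stratified detection
    stratified_table: pd.DataFrame | None = None
    curve: object = None
    delta_pi: list = field(default_factory=list)
    load_table: object = None
    gene_load: pd.DataFrame | None = None
    f_load_r: float = float("nan")
    inbreeding: pd.Series | None = None


def scan_genus(panel: GenotypePanel, params: PipelineParams, seed: int) -> GenusScan:
    """Filter, fit the drift null and LD model, and run both contrasts."""
    filtered = filter_sites(panel, maf_min=params.maf_min)
    scan_groups = filtered.scan_groups()
    kin = build_kinship(
        filtered, scan_groups,
        subsample_fraction=params.kinship_subsample, seed=seed,
    )
    scan_cols = np.concatenate([filtered.group_columns(g) for g in scan_groups])
    scan_inds = [filtered.individuals[c] for c in np.sort(scan_cols)]
    sub = dataclasses.replace(
        filtered,
        genotypes=filtered.genotypes[:, np.sort(scan_cols), :],
        individuals=scan_inds,
    )
    phased = False if params.train_unphased else None
    models = fit_cluster_model(
        sub, K=params.K, n_em_runs=params.n_em_runs,
        max_iter=params.em_max_iter, tol=params.em_tol, seed=seed, phased=phased,
    )
    cfreqs = cluster_frequencies(models, sub, scan_groups, phased=phased)

    wild = filtered.group_for_role("wild")
    tabs = {}
    for role in ("domestic_A", "domestic_B"):
        dom = filtered.group_for_role(role)
        tabs[role] = run_contrast(
            sub, wild, dom, kin, cfreqs=cfreqs, trim_upper=params.trim_upper
        )
    table = tabs["domestic_A"][["chrom", "pos"]].copy()
    for role, t in tabs.items():
        suffix = "A" if role == "domestic_A" else "B"
        table[f"hapflk_{suffix}"] = t["hapflk"]
        table[f"hapflk_p_{suffix}"] = t["hapflk_p"]
        table[f"flk_{suffix}"] = t["flk"]
        table[f"flk_p_{suffix}"] = t["flk_p"]
    table["p_comb"] = cmb.stouffer_combine(table["hapflk_p_A"], table["hapflk_p_B"])
    table["flk_comb_p"] = cmb.stouffer_combine(table["flk_p_A"], table["flk_p_B"])
    table["q"] = cmb.qvalues(table["p_comb"].to_numpy())
    return GenusScan(panel=filtered, scan_table=table, kinship=kin)


def call_and_filter_regions(
    gs: GenusScan, params: PipelineParams, q_col: str = "q",
    table: pd.DataFrame | None = None,
) -> list[cmb.RegionRecord]:
    """Candidate regions with top-FLK SNPs and the consistency filter applied."""
    tbl = gs.scan_table if table is None else table
    regions = cmb.call_regions(tbl, q_col=q_col, q_max=params.q_max,
                               merge_gap=params.merge_gap)
    kept = []
    for reg in regions:
        reg.top_flk_pos = cmb.top_flk_snps(reg, tbl, p_max=params.flk_p_max)
        status, _ = cmb.haplotype_consistency(
            reg, gs.panel, min_fraction=params.consistency_min_fraction
        )
        reg.consistency = status
        if params.drop_inconsistent and status == "fail":
            logger.info("region %s dropped by consistency filter", reg.region_id)
            continue
        kept.append(reg)
    return kept


def run_pipeline(
    panel1: GenotypePanel,
    panel2: GenotypePanel,
    hmap12: HomologyMap,
    params: PipelineParams | None = None,
    genes: dict[int, GeneTrack] | None = None,
    conservation: dict[int, pd.DataFrame] | None = None,
) -> dict[int, GenusScan]:
    """Run the full two-genus analysis in memory."""
    params = params or PipelineParams()
    params.validate()
    genes = genes or {}
    conservation = conservation or {}
    hmaps = {1: hmap12, 2: hmap12.inverse()}

    scans = {}
    for genus, panel in ((1, panel1), (2, panel2)):
        logger.info("=== scanning genus %d ===", genus)
        scans[genus] = scan_genus(panel, params, seed=params.seed + genus)
        scans[genus].regions = call_and_filter_regions(scans[genus], params)

    grid = conv.default_grid(params.grid_max, params.grid_min, params.grid_n)
    for genus in (1, 2):
        other = 2 if genus == 1 else 1
        gs = scans[genus]
        # strata for this genus come from the other genus's candidate regions
        strata = conv.assign_strata(
            gs.scan_table, scans[other].regions, hmaps[other]
        )
        gs.stratified_table, strat_regions = conv.stratified_qvalues(
            gs.scan_table, strata, p_col="p_comb",
            q_max=params.q_max, merge_gap=params.merge_gap,
        )
        gs.final_regions = call_and_filter_regions(
            gs, params, q_col="q_strat", table=gs.stratified_table
        )
        # Curve region pool is called at the loosest grid threshold so that
        # regions of varying stringency enter and leave along the grid; the
        # candidate regions themselves stay at q_max.
        loose = cmb.call_regions(
            scans[other].scan_table, q_col="q",
            q_max=params.grid_max, merge_gap=params.merge_gap,
        )
        gs.curve = conv.convergence_curve(
            loose, gs.scan_table, hmaps[other], p_col="p_comb", grid=grid,
        )
        if genes.get(genus) is not None:
            cmb.annotate_regions(gs.final_regions, genes[genus])
        gs.delta_pi = loadmod.classify_regions(gs.final_regions, gs.panel)
        if conservation.get(genus) is not None:
            gs.load_table = loadmod.individual_load(
                gs.panel, conservation[genus], genes.get(genus),
                constraint_min=params.constraint_min,
            )
            gs.inbreeding = inbreeding_coefficient(gs.panel)
            gs.gene_load = loadmod.gene_load_test(
                gs.load_table, gs.panel, alpha=params.load_alpha
            )
            gs.f_load_r, _ = loadmod.load_inbreeding_correlation(
                gs.load_table, gs.inbreeding
            )
    return scans


# ---------------------------------------------------------------------------
# file-level driver
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg


def run_full(config: dict, outdir, seed: int | None = None) -> Path:
    """Execute the pipeline from a config mapping and write a results bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = dict(config.get("params", {}))
    if seed is not None:
        p["seed"] = int(seed)
    params = PipelineParams(**p)

    panels, genes, cons = {}, {}, {}
    for genus in (1, 2):
        g = config[f"genus{genus}"]
        panels[genus] = read_vcf(g["vcf"], g["groups"])
        if g.get("genes"):
            genes[genus] = read_genes_bed(g["genes"])
        if g.get("conservation"):
            cons[genus] = read_conservation(g["conservation"])
    hmap12 = read_homology(config["homology"])

    scans = run_pipeline(panels[1], panels[2], hmap12, params,
                         genes=genes, conservation=cons)
    write_results(scans, params, outdir)
    return outdir


def write_results(scans: dict[int, GenusScan], params: PipelineParams, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(params), fh, sort_keys=True)
    for genus, gs in scans.items():
        pre = outdir / f"genus{genus}"
        pre.mkdir(exist_ok=True)
        tbl = gs.stratified_table if gs.stratified_table is not None else gs.scan_table
        tbl.to_csv(pre / "scan.tsv", sep="\t", index=False, float_format="%.6g")
        cmb.regions_to_json(gs.final_regions, pre / "regions.json")
        cmb.regions_to_bed(gs.final_regions, pre / "regions.bed")
        if getattr(gs, "curve", None) is not None:
            gs.curve.to_frame().to_csv(pre / "convergence.tsv", sep="\t",
                                       index=False, float_format="%.6g")
        pd.DataFrame([dataclasses.asdict(d) for d in gs.delta_pi]).to_csv(
            pre / "delta_pi.tsv", sep="\t", index=False, float_format="%.6g"
        )
        with open(pre / "kinship.nwk", "w") as fh:
            fh.write(gs.kinship.newick() + "\n")
        gs.kinship.covariance.to_csv(pre / "kinship.tsv", sep="\t",
                                     float_format="%.6g")
        if gs.load_table is not None:
            gs.load_table.per_individual.to_csv(pre / "load.tsv", sep="\t",
                                                float_format="%.6g")
            gs.gene_load.to_csv(pre / "gene_load.tsv", sep="\t", index=False,
                                float_format="%.6g")
    manifest = {}
    for f in sorted(outdir.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest[str(f.relative_to(outdir))] = hashlib.sha256(
                f.read_bytes()
            ).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
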