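"""End-to-end orchestration and report tables.

The pipeline runs preprocess -> multiplicity -> contrasts -> overlap
panel -> paired change -> panel evaluation -> network chain -> report
tables, writing every stage's output as a TSV under the run directory
plus a ``manifest.json`` with the seed, threshold and per-file row
counts.  Stages communicate through those files, so the CLI subcommands
compose; a rerun with the same config is identical up to floating-point
determinism.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import dcmmet.io as dio
from dcmmet import __version__, association, netenrich, panel as panelmod, preprocess, synthdata
from dcmmet.multiplicity import MultiplicityResult, effective_tests, from_meff, metabolite_correlation
from dcmmet.types import DCM_BY_DIET_CONTRAST, DIET_CONTRAST, DISEASE_CONTRAST, MetaboMatrix

log = logging.getLogger("dcmmet")


@dataclass
class RunConfig:
    """Declarative configuration for a full pipeline run."""

    outdir: str = "results/run"
    seed: int = 0
    alpha: float = 0.05
    meff_override: float | None = None
    shrinkage: float | str | None = "auto"
    eligibility_alpha: float = 0.05
    min_metabolites: int = 2
    min_genes: int = 2
    covariates: tuple[str, ...] = ("age", "sex")
    post_change_band: str = "fdr"
    network_mode: str = "one_hop"
    rf_trees: int = 500
    rf_method: str = "oob"
    k_clusters: int = 3
    #: overrides for the synthetic generator (SimConfig fields); the
    #: pipeline seed is always injected
    sim: dict = field(default_factory=dict)
    #: optional paths to externally supplied input tables; when set, the
    #: simulate stage is skipped and these files are used instead
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "covariates" in payload:
            payload["covariates"] = tuple(payload["covariates"])
        return cls(**payload)

    def sim_config(self) -> synthdata.SimConfig:
        kwargs = dict(self.sim)
        for key in ("group_sizes", "block_sizes"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        kwargs["seed"] = self.seed
        return synthdata.SimConfig(**kwargs)

    def path(self, name: str) -> Path:
        return Path(self.outdir) / name


def setup_logging(outdir: str | Path, quiet: bool = False) -> None:
    Path(outdir).mkdir(parents=True, exist_ok=True)
    log.setLevel(logging.DEBUG)
    log.handlers.clear()
    stream = logging.StreamHandler()
    stream.setLevel(logging.WARNING if quiet else logging.INFO)
    filehandler = logging.FileHandler(Path(outdir) / "run.log", mode="a")
    filehandler.setLevel(logging.DEBUG)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (stream, filehandler):
        h.setFormatter(fmt)
        log.addHandler(h)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig) -> None:
    """Generate the synthetic cohort, follow-up and annotation inputs."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = cfg.sim_config()
    log.info("simulate: seed=%d groups=%s metabolites=%d", sim.seed, sim.group_sizes, sim.n_metabolites)
    samples, matrix, truth = synthdata.simulate_cohort(sim)
    samples_fu, matrix_fu = synthdata.simulate_followup(samples, matrix, truth, sim)
    bundle = synthdata.simulate_annotations(sim, truth)

    dio.write_samples(pd.concat([samples, samples_fu], ignore_index=True), cfg.path("samples.tsv"))
    combined = MetaboMatrix(pd.concat([matrix.values, matrix_fu.values]), matrix.annotation)
    dio.write_matrix(combined, cfg.path("metabolites_raw.tsv"), cfg.path("metabolite_annotation.tsv"))
    dio.write_bundle(bundle, out)
    dio.write_truth(truth, cfg.path("truth.json"))


def _read_inputs(cfg: RunConfig, log_scale: bool = False) -> tuple[pd.DataFrame, MetaboMatrix]:
    samples = dio.read_samples(cfg.inputs.get("samples", cfg.path("samples.tsv")))
    name = "metabolites_log.tsv" if log_scale else "metabolites_raw.tsv"
    matrix = dio.read_matrix(
        cfg.inputs.get("metabolites", cfg.path(name)) if not log_scale else cfg.path(name),
        cfg.inputs.get("annotation", cfg.path("metabolite_annotation.tsv")),
        log_scale=log_scale,
    )
    return samples, matrix


def stage_preprocess(cfg: RunConfig) -> None:
    """Normalise, impute and log-transform; estimate Meff and the bands."""
    samples, matrix = _read_inputs(cfg, log_scale=False)
    matrix_log, report = preprocess.preprocess_pipeline(matrix, samples)
    dio.write_matrix(matrix_log, cfg.path("metabolites_log.tsv"))
    report.to_frame().to_csv(cfg.path("preprocess_report.tsv"), sep="\t")

    baseline_ids = samples.sample_id[samples.timepoint == "baseline"]
    if cfg.meff_override is not None:
        bands = from_meff(cfg.meff_override, alpha=cfg.alpha)
        shrink_lambda = None
        log.info("multiplicity: external meff=%g", cfg.meff_override)
    else:
        corr, shrink_lambda = metabolite_correlation(matrix_log.values.loc[baseline_ids], shrinkage=cfg.shrinkage)
        bands = effective_tests(corr, alpha=cfg.alpha)
        log.info("multiplicity: meff=%.1f (shrinkage %.3f)", bands.meff, shrink_lambda)
    payload = bands.summary()
    payload["shrinkage_lambda"] = shrink_lambda
    payload["n_baseline_samples"] = int(len(baseline_ids))
    dio.write_json(payload, cfg.path("multiplicity.json"))


def _load_bands(cfg: RunConfig) -> MultiplicityResult:
    import json

    with open(cfg.path("multiplicity.json")) as fh:
        payload = json.load(fh)
    return from_meff(payload["meff"], alpha=payload["alpha"])


def stage_associate(cfg: RunConfig) -> None:
    """All per-metabolite screens: three contrasts, paired, biomarker, demographics."""
    samples, matrix_log = _read_inputs(cfg, log_scale=True)
    bands = _load_bands(cfg)
    for contrast in (DISEASE_CONTRAST, DIET_CONTRAST, DCM_BY_DIET_CONTRAST):
        table = association.fit_contrast(matrix_log, samples, contrast, covariates=cfg.covariates, bands=bands)
        table.to_csv(cfg.path(f"assoc_{contrast.id}.tsv"), sep="\t", index=False)
        n_fdr = int((table.tier == "fdr").sum())
        log.info("contrast %s: %d fdr-tier, %d nominal", contrast.id, n_fdr, int((table.tier == "nominal").sum()))

    fu = samples[samples.timepoint == "month9"]
    if len(fu) >= 3:
        pairs = {dog: sid for dog, sid in zip(fu.dog_id, fu.sample_id)}
        base = MetaboMatrix(matrix_log.values.loc[sorted(pairs)], matrix_log.annotation, log_scale=True)
        follow = MetaboMatrix(matrix_log.values.loc[[pairs[d] for d in sorted(pairs)]], matrix_log.annotation, log_scale=True)
        paired = association.paired_change(base, follow, pairs, bands=bands)
        paired.to_csv(cfg.path("paired_dcm_nt.tsv"), sep="\t", index=False)
    else:
        log.warning("fewer than 3 follow-up pairs; paired analysis skipped")

    corr = association.biomarker_correlation(matrix_log, samples, biomarker="ctni", bands=bands)
    corr.to_csv(cfg.path("corr_ctni.tsv"), sep="\t", index=False)
    association.cohort_summary(samples).to_csv(cfg.path("demographics.tsv"), sep="\t", index=False)


def stage_panel(cfg: RunConfig) -> None:
    """Overlap panel, post-change calls, RF evaluation, correlation clusters."""
    samples, matrix_log = _read_inputs(cfg, log_scale=True)
    assoc_d = pd.read_csv(cfg.path("assoc_disease.tsv"), sep="\t")
    assoc_t = pd.read_csv(cfg.path("assoc_diet.tsv"), sep="\t")
    panel = panelmod.overlap_panel(assoc_d, assoc_t, annotation=matrix_log.annotation)
    paired_path = cfg.path("paired_dcm_nt.tsv")
    if paired_path.exists() and len(panel):
        paired = pd.read_csv(paired_path, sep="\t")
        panel = panelmod.annotate_post_change(panel, paired, band=cfg.post_change_band, alpha=cfg.alpha)
    panel.to_csv(cfg.path("panel.tsv"), sep="\t", index=False)
    log.info("overlap panel: %d metabolites", len(panel))

    ids = list(panel.metabolite_id)
    if ids:
        for task in ("disease", "diet"):
            ev = panelmod.panel_predictive_accuracy(
                matrix_log, samples, ids, task, seed=cfg.seed, n_trees=cfg.rf_trees, method=cfg.rf_method
            )
            table = ev.importance.copy()
            table.insert(0, "task", task)
            table["accuracy"] = ev.accuracy
            table.to_csv(cfg.path(f"panel_eval_{task}.tsv"), sep="\t", index=False)
            log.info("panel RF %s: accuracy %.3f", task, ev.accuracy)
        baseline_ids = samples.sample_id[samples.timepoint == "baseline"]
        base = MetaboMatrix(matrix_log.values.loc[baseline_ids], matrix_log.annotation, log_scale=True)
        k = min(cfg.k_clusters, len(ids))
        corr, clusters, top = panelmod.panel_correlation_clusters(base, ids, k=k)
        corr.to_csv(cfg.path("panel_corr.tsv"), sep="\t")
        cl = clusters.rename_axis("metabolite_id").reset_index()
        cl["top_pair"] = f"{top[0]}|{top[1]}|r={top[2]:.3f}"
        cl.to_csv(cfg.path("panel_clusters.tsv"), sep="\t", index=False)
    else:
        log.warning("empty overlap panel; RF evaluation and clustering skipped")

    prior_path = cfg.inputs.get("prior")
    if prior_path:
        prior = pd.read_csv(prior_path, sep="\t")
        assoc_p2 = pd.read_csv(cfg.path("assoc_dcm_by_diet.tsv"), sep="\t")
        joined, counts = panelmod.prior_study_lookup(assoc_p2, prior)
        joined.to_csv(cfg.path("prior_lookup.tsv"), sep="\t", index=False)
        counts.to_csv(cfg.path("prior_lookup_counts.tsv"), sep="\t")


def stage_network(cfg: RunConfig) -> None:
    """Protein over-representation, per-contrast networks, intersection, gene sets."""
    bundle = dio.read_bundle(
        Path(cfg.inputs["met2prot"]).parent if "met2prot" in cfg.inputs else cfg.outdir
    )
    hits = {}
    nets = {}
    for cid in ("disease", "diet"):
        assoc = pd.read_csv(cfg.path(f"assoc_{cid}.tsv"), sep="\t")
        sig = set(assoc.metabolite_id[assoc.tier == "fdr"])
        table = netenrich.metabolite_protein_enrichment(
            sig, bundle.met2prot, alpha=cfg.eligibility_alpha, min_metabolites=cfg.min_metabolites
        )
        table.to_csv(cfg.path(f"protein_hits_{cid}.tsv"), sep="\t", index=False)
        eligible = set(table.protein_id[table.eligible]) if len(table) else set()
        net = netenrich.build_ppi_network(eligible, bundle.interactome, mode=cfg.network_mode)
        nets[cid] = net
        hits[cid] = table
        edges = pd.DataFrame(sorted(tuple(sorted(e)) for e in net.edges), columns=["protein_a", "protein_b"])
        edges.to_csv(cfg.path(f"network_{cid}.tsv"), sep="\t", index=False)
        log.info("network %s: %d eligible proteins, %d edges", cid, len(eligible), len(edges))

    shared_edges, proteins = netenrich.shared_ppi(nets["disease"], nets["diet"], hits["disease"], hits["diet"])
    pd.DataFrame(shared_edges, columns=["protein_a", "protein_b"]).to_csv(
        cfg.path("shared_ppi.tsv"), sep="\t", index=False
    )
    pd.DataFrame({"protein_id": proteins}).to_csv(cfg.path("shared_proteins.tsv"), sep="\t", index=False)
    log.info("shared PPI: %d pairs, %d unique proteins", len(shared_edges), len(proteins))

    members_union = set().union(*bundle.gene_set_members().values()) if bundle.gene_sets else set()
    interactome_nodes = set(bundle.interactome.protein_a) | set(bundle.interactome.protein_b)
    background = members_union & interactome_nodes
    if not background:
        background = members_union | set(proteins)
    enr = netenrich.gene_set_enrichment(
        set(proteins) & background, bundle.gene_sets, background=background, alpha=cfg.alpha, min_genes=cfg.min_genes
    )
    enr.to_csv(cfg.path("geneset_enrichment.tsv"), sep="\t", index=False)

    # per-contrast enrichment over each network's own node set, for the tile
    for cid in ("disease", "diet"):
        nodes = nets[cid].nodes & background
        enr_c = netenrich.gene_set_enrichment(
            nodes, bundle.gene_sets, background=background, alpha=cfg.alpha, min_genes=cfg.min_genes
        )
        enr_c.to_csv(cfg.path(f"geneset_enrichment_{cid}.tsv"), sep="\t", index=False)


def volcano_table(assoc: pd.DataFrame, sign_convention: str = "as_is", threshold: float | None = None) -> tuple[pd.DataFrame, float | None]:
    """Plot-ready volcano columns: beta, -log10 p, tier class.

    ``sign_convention="flip"`` negates every beta (for conventions where a
    negative value denotes the group of interest).  Returns the table and
    the -log10 threshold line value.
    """
    if sign_convention not in {"as_is", "flip"}:
        raise ValueError("sign_convention must be 'as_is' or 'flip'")
    sign = -1.0 if sign_convention == "flip" else 1.0
    with np.errstate(divide="ignore"):
        mlp = -np.log10(np.clip(assoc.p.to_numpy(dtype=float), 1e-300, None))
    mlp = np.where(assoc.p.to_numpy(dtype=float) >= 1.0, 0.0, mlp)
    out = pd.DataFrame(
        {
            "metabolite_id": assoc.metabolite_id,
            "beta": sign * assoc.beta.to_numpy(dtype=float),
            "minus_log10_p": mlp,
            "tier": assoc.tier,
        }
    )
    line = None if threshold is None else float(-np.log10(threshold))
    return out, line


def tile_table(enrichments: list[tuple[str, pd.DataFrame]]) -> tuple[pd.DataFrame, int]:
    """Pathway x contrast grid of corrected p values.

    Cells carry the BH q per contrast with an explicit ``NS`` marker
    column per contrast; the returned count is the number of pathways
    significant in every contrast.
    """
    if not enrichments:
        raise ValueError("need at least one contrast's enrichment table")
    all_sets: list[str] = []
    for _, df in enrichments:
        for s in df.set_id:
            if s not in all_sets:
                all_sets.append(s)
    grid = pd.DataFrame({"set_id": all_sets})
    sig_masks = []
    for cid, df in enrichments:
        ix = df.set_index("set_id")
        grid[f"q_{cid}"] = [float(ix.q.get(s, np.nan)) for s in all_sets]
        sig = pd.Series([bool(ix.significant.get(s, False)) for s in all_sets], index=all_sets)
        grid[f"marker_{cid}"] = np.where(sig.to_numpy(), "sig", "NS")
        sig_masks.append(sig)
    shared = int(np.logical_and.reduce([m.to_numpy() for m in sig_masks]).sum()) if sig_masks else 0
    return grid, shared


def stage_report(cfg: RunConfig) -> dict:
    """Volcano and tile tables plus the run manifest."""
    bands = _load_bands(cfg)
    assoc_p2 = pd.read_csv(cfg.path("assoc_dcm_by_diet.tsv"), sep="\t")
    volcano, line = volcano_table(assoc_p2, sign_convention="as_is", threshold=bands.threshold)
    volcano.to_csv(cfg.path("volcano_dcm_by_diet.tsv"), sep="\t", index=False)

    enrichments = []
    for cid in ("disease", "diet"):
        path = cfg.path(f"geneset_enrichment_{cid}.tsv")
        if path.exists():
            enrichments.append((cid, pd.read_csv(path, sep="\t")))
    if enrichments:
        grid, shared = tile_table(enrichments)
        grid.to_csv(cfg.path("tile_pathways.tsv"), sep="\t", index=False)
    else:
        shared = 0

    files = {}
    for f in sorted(Path(cfg.outdir).glob("*.tsv")):
        files[f.name] = int(len(pd.read_csv(f, sep="\t")))
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "meff": bands.meff,
        "threshold": bands.threshold,
        "volcano_threshold_line": line,
        "shared_significant_pathways": shared,
        "files": files,
    }
    dio.write_json(manifest, cfg.path("manifest.json"))
    log.info("manifest written: %d files", len(files))
    return manifest


STAGES = ("simulate", "preprocess", "associate", "panel", "network", "report")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in order; returns the manifest."""
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    run_stage = {
        "simulate": stage_simulate,
        "preprocess": stage_preprocess,
        "associate": stage_associate,
        "panel": stage_panel,
        "network": stage_network,
        "report": stage_report,
    }
    manifest: dict = {}
    for name in STAGES:
        if name == "simulate" and cfg.inputs:
            log.info("external inputs supplied; simulate stage skipped")
            continue
        log.info("stage %s", name)
        try:
            result = run_stage[name](cfg)
        except Exception as exc:
            log.error("stage %s failed: %s", name, exc)
            raise RuntimeError(f"pipeline aborted at stage {name!r}: {exc}") from exc
        if name == "report":
            manifest = result
    return manifest
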