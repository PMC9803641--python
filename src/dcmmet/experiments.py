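"""Calibration and recovery experiments over the synthetic generator.

These are the study-condition experiments the package uses to validate
itself: a null calibration of the per-metabolite screens, an end-to-end
recovery run (overlap panel and network chain against the planted
truth), and classifier sanity checks for the panel random forest.  They
are used both by the test suite and by the results-reproduction script,
so the conditions are defined here once.

Seeds passed in are offsets into independent `SeedSequence` streams, so
experiments are reproducible and mutually independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dcmmet import netenrich
from dcmmet.association import fit_contrast
from dcmmet.multiplicity import effective_tests, metabolite_correlation
from dcmmet.panel import overlap_panel, panel_predictive_accuracy
from dcmmet.preprocess import preprocess_pipeline
from dcmmet.synthdata import SimConfig, simulate_annotations, simulate_cohort
from dcmmet.types import DIET_CONTRAST, DISEASE_CONTRAST, MetaboMatrix


def null_config(seed: int, n_metabolites: int = 500) -> SimConfig:
    """Zero-effect cohort with independent metabolites.

    Blocks, the shared per-dog component, missingness and batch shifts
    are switched off so that the per-metabolite p values are iid under
    the null and the pooled uniformity test below is exact; the
    correlated / censored regime is exercised by the recovery
    experiments instead.
    """
    return SimConfig(
        n_metabolites=n_metabolites,
        block_sizes=(),
        within_block_rho=0.0,
        n_disease_effects=0,
        n_diet_effects=0,
        n_overlap_effects=0,
        missing_rate=0.0,
        n_batches=1,
        dog_var_share=0.0,
        ctni_linked_metabolites=0,
        seed=seed,
    )


@dataclass
class NullCalibration:
    """Pooled null p values and per-replicate fdr-tier discovery counts."""

    pvalues: dict[str, np.ndarray]
    fdr_counts: dict[str, np.ndarray]
    meffs: np.ndarray

    def mean_fdr_count(self, contrast: str) -> float:
        return float(self.fdr_counts[contrast].mean())

    def fraction_below(self, contrast: str, cut: float = 0.05) -> float:
        return float((self.pvalues[contrast] < cut).mean())


def null_calibration(
    n_replicates: int = 200,
    n_metabolites: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> NullCalibration:
    """Replicate the full inference chain on zero-effect cohorts.

    Each replicate simulates a 75-sample cohort, preprocesses it,
    estimates Meff from the data, and runs both baseline contrasts;
    pooled p values and the per-family count of alpha/Meff-tier
    discoveries are collected.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    pvals: dict[str, list] = {"disease": [], "diet": []}
    counts: dict[str, list] = {"disease": [], "diet": []}
    meffs = []
    for s in seeds:
        cfg = null_config(int(s), n_metabolites=n_metabolites)
        samples, matrix, _ = simulate_cohort(cfg)
        mlog, _ = preprocess_pipeline(matrix, samples)
        corr, _ = metabolite_correlation(mlog.values)
        bands = effective_tests(corr, alpha=alpha)
        meffs.append(bands.meff)
        for cid, contrast in (("disease", DISEASE_CONTRAST), ("diet", DIET_CONTRAST)):
            table = fit_contrast(mlog, samples, contrast, bands=bands)
            pvals[cid].append(table.p.to_numpy())
            counts[cid].append(int((table.tier == "fdr").sum()))
    return NullCalibration(
        pvalues={k: np.concatenate(v) for k, v in pvals.items()},
        fdr_counts={k: np.array(v) for k, v in counts.items()},
        meffs=np.array(meffs),
    )


@dataclass
class RecoveryResult:
    """One seeded end-to-end run against the planted truth."""

    overlap_recovery: float
    panel_size: int
    planted_sets_recovered: bool
    decoy_sig_fraction: float
    n_shared_pairs: int
    n_unique_proteins: int
    meff: float
    n_fdr_disease: int
    n_fdr_diet: int
    panel_ids: list[str] = field(default_factory=list)


def recovery_run(seed: int, config: SimConfig | None = None) -> RecoveryResult:
    """Simulate under the default study conditions and measure recovery.

    Runs cohort simulation, preprocessing, Meff estimation, both
    contrasts, the overlap panel, and the full network chain
    (protein over-representation -> per-contrast PPI networks ->
    shared-edge intersection -> Z-score gene-set enrichment), comparing
    each against the planted ground truth.
    """
    cfg = config if config is not None else SimConfig(seed=seed)
    if config is not None and config.seed != seed:
        cfg = SimConfig(**{**cfg.__dict__, "seed": seed})
    samples, matrix, truth = simulate_cohort(cfg)
    mlog, _ = preprocess_pipeline(matrix, samples)
    corr, _ = metabolite_correlation(mlog.values)
    bands = effective_tests(corr)
    assoc = {
        "disease": fit_contrast(mlog, samples, DISEASE_CONTRAST, bands=bands),
        "diet": fit_contrast(mlog, samples, DIET_CONTRAST, bands=bands),
    }
    pan = overlap_panel(assoc["disease"], assoc["diet"])
    n_overlap = max(len(truth.overlap_metabolites), 1)
    recovery = len(set(pan.metabolite_id) & truth.overlap_metabolites) / n_overlap

    bundle = simulate_annotations(cfg, truth)
    hits, nets = {}, {}
    for cid in ("disease", "diet"):
        sig = set(assoc[cid].metabolite_id[assoc[cid].tier == "fdr"])
        table = netenrich.metabolite_protein_enrichment(sig, bundle.met2prot)
        hits[cid] = table
        nets[cid] = netenrich.build_ppi_network(set(table.protein_id[table.eligible]), bundle.interactome)
    edges, proteins = netenrich.shared_ppi(nets["disease"], nets["diet"], hits["disease"], hits["diet"])
    members = set().union(*bundle.gene_set_members().values())
    nodes = set(bundle.interactome.protein_a) | set(bundle.interactome.protein_b)
    background = members & nodes
    enr = netenrich.gene_set_enrichment(set(proteins) & background, bundle.gene_sets, background=background)
    sig_sets = set(enr.set_id[enr.significant])
    n_decoys = max(cfg.n_decoy_sets, 1)
    return RecoveryResult(
        overlap_recovery=recovery,
        panel_size=len(pan),
        planted_sets_recovered=truth.enriched_gene_sets <= sig_sets,
        decoy_sig_fraction=len(sig_sets - truth.enriched_gene_sets) / n_decoys,
        n_shared_pairs=len(edges),
        n_unique_proteins=len(proteins),
        meff=bands.meff,
        n_fdr_disease=int((assoc["disease"].tier == "fdr").sum()),
        n_fdr_diet=int((assoc["diet"].tier == "fdr").sum()),
        panel_ids=list(pan.metabolite_id),
    )


def separated_panel_dataset(
    seed: int, n_samples: int = 60, n_features: int = 12, separation: float = 3.0
) -> tuple[MetaboMatrix, pd.DataFrame, list[str]]:
    """Balanced two-class toy cohort whose panel features differ by ``separation`` SDs."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n_samples // 2)
    X = rng.standard_normal((n_samples, n_features)) + separation * y[:, None]
    ids = [f"M{j + 1:04d}" for j in range(n_features)]
    sample_ids = [f"dog{i:03d}" for i in range(n_samples)]
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "dog_id": sample_ids,
            "disease": np.where(y == 1, "DCM", "control"),
            "diet": np.where(y == 1, "NT", "T"),
            "age": 7.0,
            "sex": "male",
            "body_weight": 30.0,
            "batch": "B1",
            "timepoint": "baseline",
            "ctni": 1.0,
        }
    )
    annotation = pd.DataFrame(
        {"super_pathway": "Amino acid", "sub_pathway": "toy"}, index=pd.Index(ids, name="metabolite_id")
    )
    matrix = MetaboMatrix(
        pd.DataFrame(X, index=pd.Index(sample_ids, name="sample_id"), columns=ids),
        annotation,
        log_scale=True,
    )
    return matrix, samples, ids


def classifier_sanity(seed: int = 0, n_seeds: int = 20) -> dict[str, float]:
    """OOB accuracy on separated classes and on permuted balanced labels.

    Returns the separated-class accuracy for one seeded dataset and the
    mean chance-level accuracy over ``n_seeds`` label permutations.
    """
    matrix, samples, ids = separated_panel_dataset(seed)
    ev = panel_predictive_accuracy(matrix, samples, ids, task="disease", seed=seed)
    chance = []
    rng = np.random.default_rng(seed + 1)
    for k in range(n_seeds):
        perm = samples.copy()
        labels = perm.disease.to_numpy().copy()
        rng.shuffle(labels)
        perm["disease"] = labels
        ev_k = panel_predictive_accuracy(
            matrix, perm, ids, task="disease", seed=seed + 100 + k, compute_importance=False
        )
        chance.append(ev_k.accuracy)
    return {"separated_accuracy": ev.accuracy, "chance_accuracy_mean": float(np.mean(chance))}
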