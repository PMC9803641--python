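"""Synthetic cohort, follow-up, and annotation generator.

Generates data with the statistical structure the analysis chain assumes:
a four-group cohort (disease x diet) with block-correlated log-normal
metabolite abundances, planted disease/diet/overlap effects, left-censored
missingness, batch shifts, a troponin-like biomarker tied to chosen
metabolites, paired 9-month follow-up samples for a survivor subset of the
DCM-NT group, and a local annotation bundle (metabolite->protein table,
PPI interactome, gene-set collection) in which planted signal is
recoverable by the downstream network chain.  A :class:`GroundTruth`
record makes recovery testable.

Everything is driven by a single integer seed; one RNG stream per logical
component (covariates, abundances, missingness, biomarker, annotations,
follow-up) is spawned from it so that, e.g., enlarging the metabolome does
not perturb the sample draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from dcmmet import studydesign
from dcmmet.types import SAMPLE_COLUMNS, AnnotationBundle, MetaboMatrix

SUPER_PATHWAYS = [
    "Amino acid",
    "Lipid",
    "Carbohydrate",
    "Nucleotide",
    "Xenobiotics",
    "Peptide",
    "Cofactors and vitamins",
    "Energy",
]
SUPER_WEIGHTS = np.array([0.25, 0.32, 0.06, 0.05, 0.18, 0.06, 0.05, 0.03])

# group medians used to centre the simulated covariates (age in years,
# female fraction, body weight in kg), one entry per design group
GROUP_AGE = {"DCM-NT": 7.4, "DCM-T": 9.2, "C-NT": 5.7, "C-T": 7.7}
GROUP_FEMALE = {"DCM-NT": 16 / 38, "DCM-T": 1 / 8, "C-NT": 6 / 12, "C-T": 7 / 17}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Counts and sizes default to the reference design: group sizes
    38/8/12/17, ~1027 assayed metabolites, 153 disease-associated,
    63 diet-associated and 12 overlap metabolites, and a 20-of-38
    follow-up survivor fraction.  ``effect_size`` is the planted shift in
    within-group SD units on the natural-log scale.
    """

    group_sizes: tuple[int, int, int, int] = studydesign.GROUP_SIZES
    n_metabolites: int = 1027
    block_sizes: tuple[int, ...] = tuple([10] * 50)
    within_block_rho: float = 0.5
    n_disease_effects: int = 153
    n_diet_effects: int = 63
    n_overlap_effects: int = 12
    effect_size: float = 1.5
    missing_rate: float = 0.15
    n_batches: int = 2
    batch_sd: float = 0.25
    survivor_fraction: float = 20 / 38
    intervention_reversal: float = 0.8
    ctni_linked_metabolites: int = 10
    seed: int = 0
    # variance-structure extensions
    dog_var_share: float = 0.10
    ctni_noise_sd: float = 0.35
    # annotation-bundle design
    n_seed_proteins: int = 8
    n_decoy_proteins: int = 60
    metabolites_per_seed_protein: int = 4
    annotation_coverage: int = 300
    n_decoy_edges: int = 50
    n_enriched_sets: int = 5
    n_decoy_sets: int = 25
    gene_set_size: int = 8

    def __post_init__(self) -> None:
        counts = (
            self.n_metabolites,
            self.n_disease_effects,
            self.n_diet_effects,
            self.n_overlap_effects,
            self.n_batches,
            self.ctni_linked_metabolites,
        )
        if any(c < 0 for c in counts) or any(g < 0 for g in self.group_sizes):
            raise ValueError("all counts must be non-negative")
        if self.n_batches < 1:
            raise ValueError("need at least one batch")
        if self.n_overlap_effects > min(self.n_disease_effects, self.n_diet_effects):
            raise ValueError("overlap effects cannot exceed either margin's effect count")
        if self.n_disease_effects + self.n_diet_effects - self.n_overlap_effects > self.n_metabolites:
            raise ValueError("planted effects exceed the metabolome size")
        if any(b < 1 for b in self.block_sizes) or sum(self.block_sizes) > self.n_metabolites:
            raise ValueError("inconsistent block specification")
        if not 0 <= self.within_block_rho < 1:
            raise ValueError("within_block_rho must be in [0, 1)")
        for name in ("missing_rate", "survivor_fraction", "intervention_reversal", "dog_var_share"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(g == 0 for g in self.group_sizes):
            warnings.warn("a design group is empty; downstream contrasts over it will fail", stacklevel=2)

    def rngs(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(6)
        names = ("covariates", "abundance", "missing", "ctni", "annotations", "followup")
        return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


@dataclass
class GroundTruth:
    """Planted-signal record for recovery tests."""

    disease_metabolites: set[str]
    diet_metabolites: set[str]
    overlap_metabolites: set[str]
    effect_signs: dict[str, int]
    enriched_gene_sets: set[str]
    seed_proteins: set[str]
    ctni_metabolites: set[str] = field(default_factory=set)
    latent: dict[str, Any] = field(default_factory=dict, repr=False)

    def validate(self, metabolite_ids: set[str]) -> None:
        if self.overlap_metabolites != (self.disease_metabolites & self.diet_metabolites):
            raise ValueError("overlap set must equal the intersection of disease and diet sets")
        planted = self.disease_metabolites | self.diet_metabolites | self.ctni_metabolites
        if not planted <= metabolite_ids:
            raise ValueError("truth sets reference unknown metabolite ids")


def _correlated_noise(rng: np.random.Generator, n: int, m: int, block_of: np.ndarray, rho: float) -> np.ndarray:
    """Unit-variance noise with compound-symmetric correlation inside blocks."""
    eps = rng.standard_normal((n, m))
    if rho == 0 or (block_of < 0).all():
        return eps
    n_blocks = int(block_of.max()) + 1
    shared = rng.standard_normal((n, n_blocks))
    out = eps.copy()
    in_block = block_of >= 0
    out[:, in_block] = np.sqrt(rho) * shared[:, block_of[in_block]] + np.sqrt(1 - rho) * eps[:, in_block]
    return out


def _left_censor(rng: np.random.Generator, raw: np.ndarray, rate: float) -> np.ndarray:
    """Mask ~``rate`` of entries, preferentially the low values of each column."""
    if rate == 0:
        return np.zeros(raw.shape, dtype=bool)
    n = raw.shape[0]
    order = raw.argsort(axis=0).argsort(axis=0)  # within-column ranks, 0-based
    rank_pct = (order + 0.5) / n
    p_miss = np.clip(2.0 * rate * (1.0 - rank_pct), 0.0, 1.0)
    return rng.random(raw.shape) < p_miss


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, MetaboMatrix, GroundTruth]:
    """Draw the baseline cohort: sample table, abundance matrix, ground truth.

    Log abundances follow ``mu_j + sd_j * (shared-dog + block-correlated
    noise)`` with planted metabolites shifted by ``effect_size * sd_j`` in
    the DCM and/or NT margins, batch offsets added on the log scale, values
    exponentiated to the raw scale, and left-censored missingness applied.
    Identical config (incl. seed) gives bit-identical output.
    """
    rngs = config.rngs()
    rng_cov, rng_ab, rng_miss, rng_ctni = (rngs[k] for k in ("covariates", "abundance", "missing", "ctni"))

    # ---- samples -------------------------------------------------------
    groups = [lab for lab, g in zip(studydesign.GROUP_LABELS, config.group_sizes) for _ in range(g)]
    n = len(groups)
    sample_ids = [f"dog{i:03d}" for i in range(n)]
    disease = np.array(["DCM" if g.startswith("DCM") else "control" for g in groups])
    diet = np.array(["NT" if g.endswith("NT") else "T" for g in groups])
    age = np.clip(
        np.array([GROUP_AGE[g] for g in groups]) + 2.2 * rng_cov.standard_normal(n), 0.6, 13.5
    )
    sex = np.where(rng_cov.random(n) < np.array([GROUP_FEMALE[g] for g in groups]), "female", "male")
    weight = np.clip(np.exp(np.log(33.0) + 0.35 * rng_cov.standard_normal(n)), 3.5, 80.0)
    batch = rng_cov.permutation(np.array([f"B{i % config.n_batches + 1}" for i in range(n)]))

    # ---- metabolome ----------------------------------------------------
    m = config.n_metabolites
    met_ids = [f"M{j + 1:04d}" for j in range(m)]
    sup = rng_cov.choice(SUPER_PATHWAYS, size=m, p=SUPER_WEIGHTS / SUPER_WEIGHTS.sum())
    sub = np.array([f"{s} sub-pathway {rng_cov.integers(1, 9)}" for s in sup])
    annotation = pd.DataFrame({"super_pathway": sup, "sub_pathway": sub}, index=pd.Index(met_ids, name="metabolite_id"))

    mu = rng_ab.uniform(2.0, 8.0, size=m)
    sd = rng_ab.uniform(0.4, 1.2, size=m)
    block_of = np.full(m, -1, dtype=int)
    start = 0
    for b, size in enumerate(config.block_sizes):
        block_of[start : start + size] = b
        start += size

    # planted sets: overlap carries BOTH effects
    perm = rng_ab.permutation(m)
    overlap_idx = perm[: config.n_overlap_effects]
    disease_idx = perm[: config.n_disease_effects]
    diet_idx = np.concatenate(
        [overlap_idx, perm[config.n_disease_effects : config.n_disease_effects + config.n_diet_effects - config.n_overlap_effects]]
    )
    signs = np.where(rng_ab.random(m) < 0.8, 1, -1)
    in_disease = np.zeros(m, dtype=bool)
    in_disease[disease_idx] = True
    in_diet = np.zeros(m, dtype=bool)
    in_diet[diet_idx] = True

    dog_effects = rng_ab.standard_normal(n)
    g_noise = _correlated_noise(rng_ab, n, m, block_of, config.within_block_rho)
    s_d = config.dog_var_share
    noise = np.sqrt(s_d) * dog_effects[:, None] + np.sqrt(1 - s_d) * g_noise

    is_dcm = (disease == "DCM").astype(float)[:, None]
    is_nt = (diet == "NT").astype(float)[:, None]
    shift = config.effect_size * sd * signs
    effects = shift * (in_disease * is_dcm + in_diet * is_nt)

    batch_levels = [f"B{i + 1}" for i in range(config.n_batches)]
    batch_offsets = config.batch_sd * rng_ab.standard_normal((config.n_batches, m))
    batch_idx = np.array([batch_levels.index(b) for b in batch])

    log_values = mu + sd * noise + effects + batch_offsets[batch_idx]

    # ---- biomarker -----------------------------------------------------
    k = min(config.ctni_linked_metabolites, m)
    if k > 0:
        pool = disease_idx if len(disease_idx) >= k else np.arange(m)
        linked_idx = rng_ctni.choice(pool, size=k, replace=False)
        z = (log_values[:, linked_idx] - log_values[:, linked_idx].mean(0)) / log_values[:, linked_idx].std(0)
        log_ctni = 0.3 + 0.8 * z.mean(axis=1) + config.ctni_noise_sd * rng_ctni.standard_normal(n)
    else:
        linked_idx = np.array([], dtype=int)
        log_ctni = 0.3 + config.ctni_noise_sd * rng_ctni.standard_normal(n)
    ctni = np.exp(log_ctni)

    # ---- raw scale + missingness --------------------------------------
    raw = np.exp(log_values)
    mask = _left_censor(rng_miss, raw, config.missing_rate)
    raw = np.where(mask, np.nan, raw)

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "dog_id": sample_ids,
            "disease": disease,
            "diet": diet,
            "age": age,
            "sex": sex,
            "body_weight": weight,
            "batch": batch,
            "timepoint": "baseline",
            "ctni": ctni,
        },
        columns=SAMPLE_COLUMNS,
    )
    matrix = MetaboMatrix(
        pd.DataFrame(raw, index=pd.Index(sample_ids, name="sample_id"), columns=met_ids),
        annotation,
    )
    ids = np.array(met_ids)
    truth = GroundTruth(
        disease_metabolites=set(ids[disease_idx]),
        diet_metabolites=set(ids[diet_idx]),
        overlap_metabolites=set(ids[overlap_idx]),
        effect_signs={ids[j]: int(signs[j]) for j in np.union1d(disease_idx, diet_idx)},
        enriched_gene_sets={f"GS{i + 1:02d}" for i in range(config.n_enriched_sets)},
        seed_proteins={f"P{i + 1:03d}" for i in range(config.n_seed_proteins)},
        ctni_metabolites=set(ids[linked_idx]),
        latent={
            "mu": mu,
            "sd": sd,
            "block_of": block_of,
            "dog_effects": pd.Series(dog_effects, index=sample_ids),
            "batch_offsets": batch_offsets,
            "batch_levels": batch_levels,
            "in_disease": in_disease,
            "in_diet": in_diet,
            "signs": signs,
        },
    )
    truth.validate(set(met_ids))
    return samples, matrix, truth


def simulate_followup(
    samples: pd.DataFrame,
    matrix: MetaboMatrix,
    truth: GroundTruth,
    config: SimConfig,
) -> tuple[pd.DataFrame, MetaboMatrix]:
    """Nine-month follow-up samples for a survivor subset of the DCM-NT group.

    Diet-driven planted effects are attenuated by ``intervention_reversal``
    (disease-driven components persist); the per-dog intercept from
    baseline is preserved so pairing is informative.  Returns the
    month-9-only sample table and abundance matrix, with row ids
    ``<dog_id>_m9``.
    """
    if not 0 <= config.survivor_fraction <= 1:
        raise ValueError("survivor_fraction must be in [0, 1]")
    rng = config.rngs()["followup"]
    lat = truth.latent
    if not lat:
        raise ValueError("ground truth lacks latent state; pass the truth from simulate_cohort")

    base = samples[(samples.timepoint == "baseline") & (samples.disease == "DCM") & (samples.diet == "NT")]
    n_surv = int(round(config.survivor_fraction * len(base)))
    survivors = sorted(rng.choice(base.dog_id.to_numpy(), size=n_surv, replace=False))
    if n_surv == 0:
        warnings.warn("no survivors drawn; follow-up tables are empty", stacklevel=2)

    m = len(matrix.metabolites)
    mu, sd, block_of = lat["mu"], lat["sd"], lat["block_of"]
    dog_u = lat["dog_effects"].loc[survivors].to_numpy()
    g_noise = _correlated_noise(rng, n_surv, m, block_of, config.within_block_rho)
    s_d = config.dog_var_share
    noise = np.sqrt(s_d) * dog_u[:, None] + np.sqrt(1 - s_d) * g_noise

    shift = config.effect_size * sd * lat["signs"]
    # survivors are DCM dogs that ate NT at baseline: disease component
    # persists, diet component is attenuated by the intervention
    effects = shift * lat["in_disease"] + shift * lat["in_diet"] * (1 - config.intervention_reversal)

    base_rows = base.set_index("dog_id").loc[survivors]
    batch_idx = np.array([lat["batch_levels"].index(b) for b in base_rows.batch])
    log_values = mu + sd * noise + effects + lat["batch_offsets"][batch_idx]

    raw = np.exp(log_values)
    mask = _left_censor(rng, raw, config.missing_rate)
    raw = np.where(mask, np.nan, raw)

    row_ids = [f"{d}_m9" for d in survivors]
    samples_fu = pd.DataFrame(
        {
            "sample_id": row_ids,
            "dog_id": survivors,
            "disease": "DCM",
            "diet": "T",
            "age": base_rows.age.to_numpy() + 0.75,
            "sex": base_rows.sex.to_numpy(),
            "body_weight": base_rows.body_weight.to_numpy(),
            "batch": base_rows.batch.to_numpy(),
            "timepoint": "month9",
            "ctni": np.full(len(survivors), np.nan),
        },
        columns=SAMPLE_COLUMNS,
    )
    matrix_fu = MetaboMatrix(
        pd.DataFrame(raw, index=pd.Index(row_ids, name="sample_id"), columns=matrix.metabolites),
        matrix.annotation,
    )
    return samples_fu, matrix_fu


def followup_pairs(samples_fu: pd.DataFrame) -> dict[str, str]:
    """Map baseline row id -> month-9 row id for the survivor dogs."""
    return {dog: sid for dog, sid in zip(samples_fu.dog_id, samples_fu.sample_id)}


def simulate_annotations(config: SimConfig, truth: GroundTruth) -> AnnotationBundle:
    """Local annotation bundle with recoverable planted structure.

    Each seed protein is annotated to >=2 overlap-planted metabolites
    (hence >=2 members of both the disease and the diet significant sets)
    plus one random covered metabolite; decoy proteins are annotated to
    random non-planted metabolites.  The interactome links seed proteins
    to each other and sparsely to decoys, plus decoy-decoy edges.  The
    gene-set collection loads each planted set with seed proteins and adds
    random decoy sets.  Coverage of the metabolite->protein table is
    deliberately partial, as real annotation resources are.
    """
    rng = config.rngs()["annotations"]
    seeds = sorted(truth.seed_proteins)
    decoys = [f"Q{i + 1:03d}" for i in range(config.n_decoy_proteins)]
    all_proteins = seeds + decoys

    overlap = sorted(truth.overlap_metabolites)
    planted = truth.disease_metabolites | truth.diet_metabolites
    all_mets = sorted({f"M{j + 1:04d}" for j in range(config.n_metabolites)})
    nonplanted = [x for x in all_mets if x not in planted]
    n_cov = min(max(config.annotation_coverage - len(overlap), 0), len(nonplanted))
    covered = list(rng.choice(nonplanted, size=n_cov, replace=False)) if n_cov else []

    degenerate = len(overlap) < 2 or not seeds
    if degenerate:
        warnings.warn("empty or undersized truth sets; emitting a decoy-only bundle", stacklevel=2)

    rows: list[tuple[str, str]] = []
    if not degenerate:
        for p in seeds:
            k = min(config.metabolites_per_seed_protein, len(overlap))
            for met in rng.choice(overlap, size=k, replace=False):
                rows.append((met, p))
            if covered:
                rows.append((rng.choice(covered), p))
    for q in decoys:
        if covered:
            for met in rng.choice(covered, size=min(4, len(covered)), replace=False):
                rows.append((met, q))
    met2prot = pd.DataFrame(sorted(set(rows)), columns=["metabolite_id", "protein_id"])

    edges: set[tuple[str, str]] = set()

    def add_edge(a: str, b: str) -> None:
        if a != b:
            edges.add((min(a, b), max(a, b)))

    if not degenerate:
        for i, p in enumerate(seeds):
            add_edge(p, seeds[(i + 1) % len(seeds)])
            if decoys:
                add_edge(p, rng.choice(decoys))
    for _ in range(config.n_decoy_edges):
        if len(decoys) >= 2:
            a, b = rng.choice(decoys, size=2, replace=False)
            add_edge(a, b)
    interactome = pd.DataFrame(sorted(edges), columns=["protein_a", "protein_b"])

    gene_sets: dict[str, tuple[str, list[str]]] = {}
    size = config.gene_set_size
    if not degenerate:
        for name in sorted(truth.enriched_gene_sets):
            n_seed = min(size - 1, len(seeds))
            members = list(rng.choice(seeds, size=n_seed, replace=False))
            fill = [p for p in decoys if p not in members]
            members += list(rng.choice(fill, size=min(size - n_seed, len(fill)), replace=False))
            gene_sets[name] = ("synthetic planted set", sorted(members))
    for i in range(config.n_decoy_sets):
        members = list(rng.choice(all_proteins, size=min(size, len(all_proteins)), replace=False))
        gene_sets[f"DS{i + 1:02d}"] = ("synthetic decoy set", sorted(members))

    return AnnotationBundle(met2prot=met2prot, interactome=interactome, gene_sets=gene_sets)
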