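"""The disease x diet overlap panel and its follow-up characterisation.

Metabolites that pass the alpha/Meff ("fdr") tier in *both* the disease
and the diet contrast form the overlap panel.  The panel is then
annotated with the direction of its post-intervention change, evaluated
as a classifier feature set with a random forest (out-of-bag accuracy and
permutation importance), clustered on pairwise Pearson correlations with
Ward linkage (the ward.D2 convention: squared dissimilarities in the
update rule), and cross-referenced against a prior study's results table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from dcmmet.multiplicity import bh_adjust
from dcmmet.types import MetaboMatrix


@dataclass
class PanelEvaluation:
    """Random-forest evaluation of a panel for one prediction task."""

    task: str
    accuracy: float
    importance: pd.DataFrame  # metabolite_id, importance, rank
    method: str = "oob"


def overlap_panel(assoc_disease: pd.DataFrame, assoc_diet: pd.DataFrame, annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Intersection of the fdr-tier metabolite sets of both contrasts.

    Carries both contrasts' statistics; rows are ordered by descending
    min(|beta/se|) over the two contrasts, ties broken by metabolite id.
    An empty intersection is a valid (empty) panel.
    """
    d = assoc_disease.set_index("metabolite_id")
    t = assoc_diet.set_index("metabolite_id")
    members = sorted(set(d.index[d.tier == "fdr"]) & set(t.index[t.tier == "fdr"]))
    out = pd.DataFrame(
        {
            "metabolite_id": members,
            "disease_beta": d.beta.loc[members].to_numpy(),
            "disease_se": d.se.loc[members].to_numpy(),
            "disease_p": d.p.loc[members].to_numpy(),
            "diet_beta": t.beta.loc[members].to_numpy(),
            "diet_se": t.se.loc[members].to_numpy(),
            "diet_p": t.p.loc[members].to_numpy(),
        }
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        min_abs_t = np.minimum(
            np.abs(out.disease_beta / out.disease_se), np.abs(out.diet_beta / out.diet_se)
        )
    out["min_abs_t"] = min_abs_t
    out["post_change"] = "ns"
    if annotation is not None:
        out["super_pathway"] = annotation.reindex(members).super_pathway.to_numpy()
        out["sub_pathway"] = annotation.reindex(members).sub_pathway.to_numpy()
    out = out.sort_values(["min_abs_t", "metabolite_id"], ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)


def annotate_post_change(panel: pd.DataFrame, paired: pd.DataFrame, band: str = "fdr", alpha: float = 0.05) -> pd.DataFrame:
    """Call the post-intervention direction (down / up / ns) per panel row.

    Significance of the paired change is judged within the panel: the
    paired p values of the panel metabolites are BH-adjusted across the
    panel and called at ``alpha`` (``band="fdr"``, the default) or taken
    nominally at p < 0.05 (``band="nominal"``).
    """
    if band not in {"fdr", "nominal"}:
        raise ValueError("band must be 'fdr' or 'nominal'")
    out = panel.copy()
    paired_ix = paired.set_index("metabolite_id")
    present = [m for m in out.metabolite_id if m in paired_ix.index]
    absent = [m for m in out.metabolite_id if m not in paired_ix.index]
    if absent:
        warnings.warn(f"panel metabolites missing from paired table treated as ns: {absent[:5]}", stacklevel=2)
    calls = {m: "ns" for m in out.metabolite_id}
    if present:
        sub = paired_ix.loc[present]
        p = sub.p.to_numpy(dtype=float)
        ok = ~np.isnan(p)
        sig = np.zeros(len(sub), dtype=bool)
        if band == "fdr":
            q = np.full(len(sub), np.nan)
            if ok.any():
                q[ok] = bh_adjust(p[ok])
            sig[ok] = q[ok] < alpha
        else:
            sig[ok] = p[ok] < 0.05
        for m, s, diff in zip(present, sig, sub.mean_diff):
            if s:
                calls[m] = "down" if diff < 0 else "up"
    out["post_change"] = [calls[m] for m in out.metabolite_id]
    return out


def panel_predictive_accuracy(
    matrix: MetaboMatrix,
    samples: pd.DataFrame,
    panel: list[str],
    task: str,
    seed: int = 0,
    n_trees: int = 500,
    method: str = "oob",
    compute_importance: bool = True,
) -> PanelEvaluation:
    """Random-forest accuracy of the panel for predicting disease or diet.

    ``method="oob"`` (default) reports the out-of-bag proportion correct
    of a 500-tree forest; ``method="cv"`` reports stratified 5-fold
    cross-validated accuracy.  Importance is permutation importance (mean
    decrease in accuracy), ranked descending with ties broken by
    metabolite id, matching a biochemical-importance ordering.
    """
    if not panel:
        raise ValueError("panel is empty")
    if task not in {"disease", "diet"}:
        raise ValueError("task must be 'disease' or 'diet'")
    base = samples[samples.timepoint == "baseline"].set_index("sample_id")
    positive = {"disease": "DCM", "diet": "NT"}[task]
    y = (base[task] == positive).to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are single-class")
    X = matrix.values.loc[base.index, panel].to_numpy(dtype=float)

    rf = RandomForestClassifier(
        n_estimators=n_trees,
        oob_score=method == "oob",
        random_state=seed,
        n_jobs=1,
    )
    if method == "oob":
        rf.fit(X, y)
        accuracy = float(rf.oob_score_)
    elif method == "cv":
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        pred = cross_val_predict(rf, X, y, cv=cv)
        accuracy = float((pred == y).mean())
        rf.fit(X, y)
    else:
        raise ValueError("method must be 'oob' or 'cv'")

    if compute_importance:
        imp = permutation_importance(rf, X, y, scoring="accuracy", n_repeats=10, random_state=seed)
        table = pd.DataFrame({"metabolite_id": panel, "importance": imp.importances_mean})
        table = table.sort_values(["importance", "metabolite_id"], ascending=[False, True], kind="mergesort")
        table["rank"] = np.arange(1, len(table) + 1)
        table = table.reset_index(drop=True)
    else:
        table = pd.DataFrame(columns=["metabolite_id", "importance", "rank"])
    return PanelEvaluation(task=task, accuracy=accuracy, importance=table, method=method)


def panel_correlation_clusters(
    matrix: MetaboMatrix, panel: list[str], k: int = 3
) -> tuple[pd.DataFrame, pd.Series, tuple[str, str, float]]:
    """Pairwise panel correlations, Ward clusters, and the top pair.

    Hierarchical clustering uses Ward linkage on the dissimilarity
    1 - r (the hclust ward.D2 convention) cut into ``k`` clusters; the
    result is invariant to the panel's column order (ids are sorted
    internally).  Returns (correlation matrix, cluster labels, (id_a,
    id_b, r) of the maximally correlated pair).
    """
    ids = sorted(panel)
    if not 1 <= k <= len(ids):
        raise ValueError("need panel size >= k >= 1")
    sub = matrix.values[ids]
    const = sub.columns[sub.std(axis=0, ddof=1) == 0]
    if len(const):
        raise ValueError(f"constant panel columns: {list(const)}")
    corr = sub.corr(method="pearson")
    if len(ids) == 1:
        return corr, pd.Series([1], index=ids), (ids[0], ids[0], 1.0)
    dist = squareform(np.clip(1.0 - corr.to_numpy(), 0.0, None), checks=False)
    labels = fcluster(linkage(dist, method="ward"), t=k, criterion="maxclust")
    tri = corr.where(np.triu(np.ones(corr.shape, dtype=bool), k=1))
    j = np.unravel_index(np.nanargmax(tri.to_numpy()), tri.shape)
    top_pair = (ids[j[0]], ids[j[1]], float(corr.iloc[j]))
    return corr, pd.Series(labels, index=ids, name="cluster"), top_pair


def prior_study_lookup(
    assoc: pd.DataFrame,
    prior: pd.DataFrame,
    prior_name_col: str = "name",
    prior_tier_col: str = "tier",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-reference contrast results against a prior study's table.

    Names are matched after canonical lower-casing/stripping.  Returns
    the left-joined table (contrast rows, prior columns suffixed
    ``prior_``) and a tier x prior-tier match-count crosstab.
    """
    left = assoc.copy()
    left["_key"] = left.metabolite_id.astype(str).str.strip().str.lower()
    right = prior.copy()
    right["_key"] = right[prior_name_col].astype(str).str.strip().str.lower()
    right = right.drop_duplicates("_key").set_index("_key").add_prefix("prior_")
    joined = left.join(right, on="_key").drop(columns="_key")
    matched = joined[f"prior_{prior_name_col}"].notna()
    if not matched.any():
        warnings.warn("no shared metabolite names between contrast and prior table", stacklevel=2)
    counts = (
        pd.crosstab(joined.tier[matched], joined[f"prior_{prior_tier_col}"][matched])
        if matched.any()
        else pd.DataFrame()
    )
    return joined, counts
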