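"""Abundance preprocessing: batch normalisation, imputation, log transform.

The sequence is the conventional one for referenced-laboratory
metabolomics panels: scale each metabolite per batch so batch medians
agree, replace missing values by the metabolite's minimum observed value
(missingness in such data is predominantly left-censoring at the
detection limit), then take natural logs.  Zero raw abundances are
treated as missing before imputation since the log step requires strict
positivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dcmmet.types import MetaboMatrix


@dataclass
class PreprocessReport:
    """Bookkeeping for the preprocessing stages.

    ``scaling_factors`` is metabolites x batches (multiplicative, grand
    median / batch median); ``imputation_value`` and ``imputed_cells`` are
    per metabolite.
    """

    scaling_factors: pd.DataFrame = field(default_factory=pd.DataFrame)
    imputation_value: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    imputed_cells: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = self.scaling_factors.add_prefix("factor_")
        out["imputation_value"] = self.imputation_value
        out["imputed_cells"] = self.imputed_cells
        return out


def mask_zeros(matrix: MetaboMatrix) -> MetaboMatrix:
    """Treat zero raw abundances as missing (below detection)."""
    values = matrix.values.where(matrix.values != 0)
    return MetaboMatrix(values, matrix.annotation, matrix.log_scale)


def batch_normalize(matrix: MetaboMatrix, samples: pd.DataFrame) -> tuple[MetaboMatrix, PreprocessReport]:
    """Scale each metabolite per batch to the metabolite's grand median.

    After scaling, the median of the observed values of a metabolite
    within every batch equals its grand median over all observed values.
    The missing mask is unchanged.  A batch in which a metabolite is
    entirely missing keeps factor 1 (with a warning).
    """
    if "batch" not in samples.columns:
        raise ValueError("sample table lacks a batch column")
    batches = samples.set_index("sample_id").loc[matrix.values.index, "batch"]
    values = matrix.values.copy()

    grand = values.median(axis=0, skipna=True)
    factors = pd.DataFrame(1.0, index=values.columns, columns=sorted(batches.unique()))
    all_missing = 0
    for b in factors.columns:
        rows = batches[batches == b].index
        med = values.loc[rows].median(axis=0, skipna=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = grand / med
        bad = ~np.isfinite(f)
        all_missing += int(bad.sum())
        f[bad] = 1.0
        factors[b] = f
        values.loc[rows] = values.loc[rows] * f

    report = PreprocessReport(scaling_factors=factors)
    report.notes.append("per-batch median scaled to each metabolite's grand median")
    if all_missing:
        warnings.warn(f"{all_missing} metabolite/batch cells had no observed values; factor 1 kept", stacklevel=2)
        report.notes.append(f"{all_missing} all-missing metabolite/batch combinations (factor 1)")
    return MetaboMatrix(values, matrix.annotation, matrix.log_scale), report


def impute_min(matrix: MetaboMatrix) -> tuple[MetaboMatrix, PreprocessReport]:
    """Replace every missing cell by that metabolite's minimum observed value."""
    values = matrix.values
    n_obs = values.notna().sum(axis=0)
    empty = n_obs[n_obs == 0]
    if len(empty):
        raise ValueError(f"cannot impute metabolites with no observed values: {list(empty.index)[:5]}")
    mins = values.min(axis=0, skipna=True)
    imputed_cells = values.isna().sum(axis=0)
    out = values.fillna(mins)
    report = PreprocessReport(imputation_value=mins, imputed_cells=imputed_cells)
    return MetaboMatrix(out, matrix.annotation, matrix.log_scale), report


def log_transform(matrix: MetaboMatrix) -> MetaboMatrix:
    """Natural log, elementwise; requires strictly positive values."""
    values = matrix.values
    nonpos = values.columns[(values <= 0).any(axis=0)]
    if len(nonpos):
        raise ValueError(f"non-positive values in metabolites: {list(nonpos)[:5]}")
    return MetaboMatrix(np.log(values), matrix.annotation, log_scale=True)


def preprocess_pipeline(matrix: MetaboMatrix, samples: pd.DataFrame) -> tuple[MetaboMatrix, PreprocessReport]:
    """Full chain: zeros->missing, batch normalise, impute minima, log."""
    matrix = mask_zeros(matrix)
    matrix, rep_batch = batch_normalize(matrix, samples)
    matrix, rep_imp = impute_min(matrix)
    matrix = log_transform(matrix)
    report = PreprocessReport(
        scaling_factors=rep_batch.scaling_factors,
        imputation_value=rep_imp.imputation_value,
        imputed_cells=rep_imp.imputed_cells,
        notes=rep_batch.notes + rep_imp.notes + ["natural log transform applied"],
    )
    return matrix, report
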