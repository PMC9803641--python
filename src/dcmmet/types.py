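"""Shared containers used across the analysis chain."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns expected in a sample (design) table
SAMPLE_COLUMNS = [
    "sample_id",
    "dog_id",
    "disease",
    "diet",
    "age",
    "sex",
    "body_weight",
    "batch",
    "timepoint",
    "ctni",
]


@dataclass
class MetaboMatrix:
    """Samples x metabolites abundance grid plus metabolite annotations.

    ``values`` holds one row per sample and one column per metabolite;
    missing measurements are NaN.  On the raw scale all present values must
    be non-negative; after :func:`dcmmet.preprocess.log_transform` the
    matrix is flagged with ``log_scale=True`` and values are real numbers.
    ``annotation`` is indexed by metabolite id and carries the two-level
    biochemical classification (``super_pathway``, ``sub_pathway``).
    """

    values: pd.DataFrame
    annotation: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate sample ids in abundance matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate metabolite ids in abundance matrix")
        missing_ann = self.values.columns.difference(self.annotation.index)
        if len(missing_ann):
            raise ValueError(f"annotation missing for metabolites: {list(missing_ann)[:5]} ...")
        if not self.log_scale:
            vals = self.values.to_numpy(dtype=float)
            if np.nanmin(vals, initial=np.inf) < 0:
                raise ValueError("raw abundances must be non-negative where present")

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    def copy(self) -> "MetaboMatrix":
        return MetaboMatrix(self.values.copy(), self.annotation.copy(), self.log_scale)


@dataclass
class AnnotationBundle:
    """Local annotation resources for the network-enrichment chain.

    ``met2prot``   metabolite->protein interaction table
                   (columns ``metabolite_id``, ``protein_id``).
    ``interactome`` undirected protein-protein edge list
                   (columns ``protein_a``, ``protein_b``).
    ``gene_sets``  mapping set id -> (description, member list), the
                   in-memory form of a GMT collection.
    """

    met2prot: pd.DataFrame
    interactome: pd.DataFrame
    gene_sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def gene_set_members(self) -> dict[str, set[str]]:
        return {name: set(members) for name, (_, members) in self.gene_sets.items()}


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison over the baseline samples.

    ``variable`` names the sample-table column, ``level_one`` the level
    coded 1 (so a positive beta means higher abundance in that level) and
    ``subset`` optionally restricts the samples first, e.g. the
    within-DCM diet comparison.  Default codings follow the study's sign
    conventions: positive beta = higher in DCM (disease contrast) or in
    the non-traditional diet (diet contrast), while the within-DCM
    contrast codes the traditional diet as 1 so a *negative* beta denotes
    higher levels in the DCM-NT group.
    """

    id: str
    variable: str
    level_one: str
    subset: tuple[tuple[str, str], ...] = ()

    def select(self, samples: pd.DataFrame) -> pd.DataFrame:
        out = samples
        for col, level in self.subset:
            out = out[out[col] == level]
        return out


#: disease contrast: all DCM vs. all healthy controls
DISEASE_CONTRAST = Contrast("disease", "disease", "DCM")
#: diet contrast: all non-traditional vs. all traditional diets
DIET_CONTRAST = Contrast("diet", "diet", "NT")
#: within-DCM diet contrast; traditional diet coded 1, so negative beta
#: means higher in the DCM-NT group
DCM_BY_DIET_CONTRAST = Contrast("dcm_by_diet", "diet", "T", subset=(("disease", "DCM"),))
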