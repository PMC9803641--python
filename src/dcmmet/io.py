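"""Readers and writers for the pipeline's plain-text formats.

All tables are tab-separated with header rows.  The abundance matrix is
written wide (first column ``sample_id``, one column per metabolite,
missing values as empty fields).  Gene sets use the standard GMT dialect:
``name <TAB> description <TAB> member...``, one set per line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from dcmmet.synthdata import GroundTruth
from dcmmet.types import AnnotationBundle, MetaboMatrix


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_samples(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "dog_id": str, "batch": str})


def write_matrix(matrix: MetaboMatrix, values_path: str | Path, annotation_path: str | Path | None = None) -> None:
    matrix.values.to_csv(values_path, sep="\t", index=True, na_rep="")
    if annotation_path is not None:
        matrix.annotation.to_csv(annotation_path, sep="\t", index=True)


def read_matrix(values_path: str | Path, annotation_path: str | Path, log_scale: bool = False) -> MetaboMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    annotation = pd.read_csv(annotation_path, sep="\t", index_col=0)
    return MetaboMatrix(values, annotation, log_scale=log_scale)


def write_met2prot(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_met2prot(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_interactome(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_interactome(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_gmt(gene_sets: dict[str, tuple[str, list[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (description, members) in gene_sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    out: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            out[parts[0]] = (parts[1], parts[2:])
    return out


def write_bundle(bundle: AnnotationBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    write_met2prot(bundle.met2prot, outdir / "met2prot.tsv")
    write_interactome(bundle.interactome, outdir / "interactome.tsv")
    write_gmt(bundle.gene_sets, outdir / "genesets.gmt")


def read_bundle(indir: str | Path) -> AnnotationBundle:
    indir = Path(indir)
    return AnnotationBundle(
        met2prot=read_met2prot(indir / "met2prot.tsv"),
        interactome=read_interactome(indir / "interactome.tsv"),
        gene_sets=read_gmt(indir / "genesets.gmt"),
    )


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "disease_metabolites": sorted(truth.disease_metabolites),
        "diet_metabolites": sorted(truth.diet_metabolites),
        "overlap_metabolites": sorted(truth.overlap_metabolites),
        "effect_signs": {k: int(v) for k, v in sorted(truth.effect_signs.items())},
        "enriched_gene_sets": sorted(truth.enriched_gene_sets),
        "seed_proteins": sorted(truth.seed_proteins),
        "ctni_metabolites": sorted(truth.ctni_metabolites),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return GroundTruth(
        disease_metabolites=set(payload["disease_metabolites"]),
        diet_metabolites=set(payload["diet_metabolites"]),
        overlap_metabolites=set(payload["overlap_metabolites"]),
        effect_signs={k: int(v) for k, v in payload["effect_signs"].items()},
        enriched_gene_sets=set(payload["enriched_gene_sets"]),
        seed_proteins=set(payload["seed_proteins"]),
        ctni_metabolites=set(payload.get("ctni_metabolites", [])),
    )


def write_json(payload: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=default)
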