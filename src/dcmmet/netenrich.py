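"""Metabolite->protein over-representation, PPI networks, Z-score gene sets.

The chain mirrors a protein-centric reading of a metabolite hit list:

1. per protein, an exact hypergeometric test of the overlap between its
   annotated metabolites and the significant metabolite set, with BH
   adjustment across proteins and an eligibility rule (>= 2 metabolites
   AND FDR-significant);
2. a PPI network per contrast: interactome edges with at least one
   endpoint among that contrast's eligible proteins (first-neighbour
   expansion; an induced-subgraph mode is available);
3. the shared-edge intersection of the disease and diet networks,
   retaining edges having an endpoint eligible in BOTH analyses, and the
   deduplicated endpoint set;
4. gene-set enrichment of those proteins by the standardised
   hypergeometric Z-score with finite-population correction,

       z = (r - nR/N) / sqrt(n (R/N)(1 - R/N)(1 - (n-1)/(N-1))),

   converted to a two-sided normal p = 2 Phi(-|z|), BH-adjusted, with
   sets represented by fewer than 2 genes excluded from the significant
   list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from dcmmet.multiplicity import bh_adjust


def metabolite_protein_enrichment(
    sig_metabolites: set[str],
    interactions: pd.DataFrame,
    background: set[str] | None = None,
    alpha: float = 0.05,
    min_metabolites: int = 2,
) -> pd.DataFrame:
    """Per-protein hypergeometric over-representation of a metabolite set.

    ``background`` defaults to all metabolites present in the interaction
    table.  ``eligible`` requires both an overlap of at least
    ``min_metabolites`` and BH q below ``alpha`` — the count rule takes
    precedence regardless of p.
    """
    if background is None:
        background = set(interactions.metabolite_id)
    # metabolites without annotation cannot inform the protein test; the
    # significant set is restricted to the annotated background
    sig = set(sig_metabolites) & background
    inter = interactions[interactions.metabolite_id.isin(background)]
    N = len(background)
    n = len(sig)
    rows = []
    for protein, grp in inter.groupby("protein_id"):
        annotated = set(grp.metabolite_id)
        K = len(annotated)
        if K == 0:
            continue
        x = len(annotated & sig)
        p = float(stats.hypergeom.sf(x - 1, N, K, n))
        rows.append({"protein_id": protein, "n_annotated": K, "overlap": x, "p": p})
    out = pd.DataFrame(rows, columns=["protein_id", "n_annotated", "overlap", "p"])
    if len(out):
        out = out.sort_values("protein_id", kind="mergesort").reset_index(drop=True)
        out["q"] = bh_adjust(out.p.to_numpy())
        out["eligible"] = (out.overlap >= min_metabolites) & (out.q < alpha)
    else:
        out["q"] = []
        out["eligible"] = []
    return out


@dataclass
class PPINetwork:
    """Undirected protein network seeded by eligible proteins."""

    graph: nx.Graph
    seeds: set[str] = field(default_factory=set)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)


def build_ppi_network(
    seed_proteins: set[str],
    interactome: pd.DataFrame,
    mode: str = "one_hop",
) -> PPINetwork:
    """Network of interactome edges touching the seed proteins.

    ``one_hop`` (default) keeps every edge with at least one seed
    endpoint — the input proteins plus their identified interactions;
    ``induced`` requires both endpoints to be seeds.  Self-loops and
    duplicate/reversed edges are dropped; isolated seeds stay in the node
    set.
    """
    if mode not in {"one_hop", "induced"}:
        raise ValueError("mode must be 'one_hop' or 'induced'")
    seeds = {str(s).strip() for s in seed_proteins}
    g = nx.Graph()
    g.add_nodes_from(seeds)
    if len(interactome) == 0:
        warnings.warn("empty interactome; network has no edges", stacklevel=2)
        return PPINetwork(graph=g, seeds=seeds)
    for a, b in zip(interactome.protein_a, interactome.protein_b):
        a, b = str(a).strip(), str(b).strip()
        if a == b:
            continue
        keep = (a in seeds or b in seeds) if mode == "one_hop" else (a in seeds and b in seeds)
        if keep:
            g.add_edge(a, b)
    return PPINetwork(graph=g, seeds=seeds)


def shared_ppi(
    net_disease: PPINetwork,
    net_diet: PPINetwork,
    hits_disease: pd.DataFrame,
    hits_diet: pd.DataFrame,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Edges common to both networks whose endpoint is eligible in both.

    An edge is retained when at least one of its endpoints is an eligible
    protein (>= 2 metabolites, FDR-significant) in BOTH hit tables.
    Returns the sorted retained edge list and the deduplicated endpoint
    proteins.
    """
    elig_d = set(hits_disease.protein_id[hits_disease.eligible]) if len(hits_disease) else set()
    elig_t = set(hits_diet.protein_id[hits_diet.eligible]) if len(hits_diet) else set()
    elig_both = elig_d & elig_t
    shared = net_disease.edges & net_diet.edges
    retained = sorted(tuple(sorted(e)) for e in shared if e & elig_both)
    proteins = sorted({p for e in retained for p in e})
    return retained, proteins


def gene_set_enrichment(
    genes: set[str],
    collections: dict[str, tuple[str, list[str]]],
    background: set[str] | None = None,
    alpha: float = 0.05,
    min_genes: int = 2,
    adjust_scope: str = "all",
) -> pd.DataFrame:
    """Z-score over-representation of a gene set collection.

    ``background`` defaults to the union of collection members and the
    query.  Sets whose background-restricted size is 0 or N are skipped
    (zero variance).  BH adjustment spans all tested sets by default
    (``adjust_scope="all"``); ``"filtered"`` adjusts only across sets
    with overlap >= ``min_genes``.  The ``significant`` flag always
    requires both q < alpha and overlap >= ``min_genes``.
    """
    if adjust_scope not in {"all", "filtered"}:
        raise ValueError("adjust_scope must be 'all' or 'filtered'")
    members_by_set = {name: set(members) for name, (_, members) in collections.items()}
    if background is None:
        background = set().union(*members_by_set.values(), genes) if members_by_set else set(genes)
    query = set(genes) & background
    if not set(genes) <= background:
        warnings.warn("query genes outside the background were dropped", stacklevel=2)
    N = len(background)
    n = len(query)
    rows = []
    for name in sorted(members_by_set):
        members = members_by_set[name] & background
        R = len(members)
        if R == 0 or R == N:
            continue
        r = len(members & query)
        expected = n * R / N
        var = n * (R / N) * (1 - R / N) * (1 - (n - 1) / (N - 1)) if N > 1 else 0.0
        if var <= 0:
            z = 0.0
        else:
            z = (r - expected) / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
        rows.append(
            {"set_id": name, "overlap": r, "set_size": R, "query_size": n, "background_size": N, "z": z, "p": p}
        )
    out = pd.DataFrame(rows, columns=["set_id", "overlap", "set_size", "query_size", "background_size", "z", "p"])
    if not len(out):
        out["q"] = []
        out["significant"] = []
        return out
    if adjust_scope == "all":
        out["q"] = bh_adjust(out.p.to_numpy())
    else:
        out["q"] = np.nan
        mask = (out.overlap >= min_genes).to_numpy()
        if mask.any():
            out.loc[mask, "q"] = bh_adjust(out.p.to_numpy()[mask])
    out["significant"] = (out.q < alpha) & (out.overlap >= min_genes)
    out = out.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)
    return out
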