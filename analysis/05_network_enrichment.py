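"""Protein-metabolite over-representation -> shared PPI -> gene sets.

For each contrast's significant metabolites: hypergeometric protein
over-representation with the >=2-metabolite + FDR eligibility rule,
first-neighbour PPI network construction, the shared-edge intersection
of the disease and diet networks, and Z-score gene-set enrichment of the
resulting unique proteins.
"""

import importlib

import pandas as pd

common = importlib.import_module("00_config")
from dcmmet.pipeline import stage_network

cfg = common.config()
stage_network(cfg)

for cid in ("disease", "diet"):
    hits = pd.read_csv(cfg.path(f"protein_hits_{cid}.tsv"), sep="\t")
    net = pd.read_csv(cfg.path(f"network_{cid}.tsv"), sep="\t")
    print(f"{cid}: {hits.eligible.sum()} eligible proteins of {len(hits)} tested; network {len(net)} edges")
shared = pd.read_csv(cfg.path("shared_ppi.tsv"), sep="\t")
prot = pd.read_csv(cfg.path("shared_proteins.tsv"), sep="\t")
enr = pd.read_csv(cfg.path("geneset_enrichment.tsv"), sep="\t")
print(f"shared PPI pairs: {len(shared)}; unique proteins: {len(prot)}")
print(f"gene sets: {enr.significant.sum()} significant (q < 0.05, >= 2 genes) of {len(enr)} tested")
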