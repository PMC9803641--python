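"""Generate the synthetic study cohort.

Draws the four-group baseline cohort (38 DCM-NT, 8 DCM-T, 12 C-NT,
17 C-T dogs; ~1027 metabolites with block-correlated log-normal
abundances, planted disease/diet/overlap effects, left-censored
missingness and batch shifts), the 9-month follow-up samples for the
DCM-NT survivor subset, and the annotation bundle
(metabolite->protein table, PPI interactome, gene-set collection),
writing everything plus the ground-truth record under results/run/.
"""

import importlib

import pandas as pd

common = importlib.import_module("00_config")
from dcmmet.pipeline import stage_simulate

cfg = common.config()
stage_simulate(cfg)

samples = pd.read_csv(cfg.path("samples.tsv"), sep="\t")
base = samples[samples.timepoint == "baseline"]
fu = samples[samples.timepoint == "month9"]
print(f"baseline cohort: {len(base)} dogs "
      f"({(base.disease == 'DCM').sum()} DCM / {(base.disease == 'control').sum()} controls; "
      f"{(base.diet == 'NT').sum()} NT / {(base.diet == 'T').sum()} T diets)")
print(f"follow-up: {len(fu)} month-9 samples from DCM-NT survivors")
ann = pd.read_csv(cfg.path("metabolite_annotation.tsv"), sep="\t")
print(f"metabolome: {len(ann)} metabolites in {ann.super_pathway.nunique()} super pathways")
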