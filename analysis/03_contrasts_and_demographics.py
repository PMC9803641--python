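"""Per-metabolite screens: the three contrasts, paired changes, cTnI.

Fits the disease contrast (all DCM vs. all controls), the diet contrast
(all NT vs. all T) and the within-DCM diet contrast (DCM-NT vs. DCM-T;
negative beta = higher in DCM-NT), each adjusted for age and sex; runs
the paired baseline/month-9 test in the DCM-NT survivors, the Pearson
screen against cTnI, and the four-group demographics table.
"""

import importlib

import pandas as pd

common = importlib.import_module("00_config")
from dcmmet.pipeline import stage_associate

cfg = common.config()
stage_associate(cfg)

for cid in ("disease", "diet", "dcm_by_diet"):
    t = pd.read_csv(cfg.path(f"assoc_{cid}.tsv"), sep="\t")
    print(f"{cid:12s}: {(t.tier == 'fdr').sum():4d} significant, "
          f"{(t.tier == 'nominal').sum():4d} nominally significant of {len(t)}")
paired = pd.read_csv(cfg.path("paired_dcm_nt.tsv"), sep="\t")
print(f"paired 9-month change: {(paired.tier == 'fdr').sum()} significant, "
      f"{(paired.tier == 'nominal').sum()} nominal")
corr = pd.read_csv(cfg.path("corr_ctni.tsv"), sep="\t")
print(f"cTnI screen: {(corr.tier == 'fdr').sum()} significant, {(corr.tier == 'nominal').sum()} nominal")
demo = pd.read_csv(cfg.path("demographics.tsv"), sep="\t")
print(demo[["variable", "test", "p"]].to_string(index=False))
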