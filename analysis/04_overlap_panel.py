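"""The disease x diet overlap panel and its characterisation.

Intersects the significant sets of the disease and diet contrasts,
annotates each panel metabolite with its post-intervention direction
(within-panel BH on the paired p values), evaluates the panel as a
random-forest feature set for both prediction tasks (out-of-bag
accuracy, permutation importance), and clusters the panel on pairwise
correlations with Ward linkage.
"""

import importlib

import pandas as pd

common = importlib.import_module("00_config")
from dcmmet.pipeline import stage_panel

cfg = common.config()
stage_panel(cfg)

panel = pd.read_csv(cfg.path("panel.tsv"), sep="\t")
print(f"overlap panel: {len(panel)} metabolites significant in BOTH contrasts")
if len(panel):
    changed = panel.post_change.value_counts().to_dict()
    print(f"post-intervention direction: {changed}")
    for task in ("disease", "diet"):
        ev = pd.read_csv(cfg.path(f"panel_eval_{task}.tsv"), sep="\t")
        top = ev.sort_values("rank").metabolite_id.iloc[0]
        print(f"random forest ({task}): OOB accuracy {ev.accuracy.iloc[0]:.2f}, most predictive {top}")
    clusters = pd.read_csv(cfg.path("panel_clusters.tsv"), sep="\t")
    print(f"correlation clustering: {clusters.cluster.nunique()} clusters, top pair {clusters.top_pair.iloc[0]}")
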