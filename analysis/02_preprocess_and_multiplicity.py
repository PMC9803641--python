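"""Preprocess the abundance matrix and set the significance threshold.

Batch-normalises each metabolite to its grand median, imputes missing
values at the per-metabolite minimum, log-transforms, then estimates the
effective number of independent tests (Meff) from the shrinkage-
regularised correlation matrix of the baseline samples and derives the
two significance bands (alpha/Meff and the nominal 0.05 band).
"""

import importlib
import json

common = importlib.import_module("00_config")
from dcmmet.pipeline import stage_preprocess

cfg = common.config()
stage_preprocess(cfg)

mult = json.load(open(cfg.path("multiplicity.json")))
print(f"Meff = {mult['meff']:.1f} of {mult['n_eigenvalues']} metabolites "
      f"(shrinkage intensity {mult['shrinkage_lambda']:.3f})")
print(f"significance threshold alpha/Meff = {mult['threshold']:.3g}; "
      f"nominal band [{mult['threshold']:.3g}, {mult['nominal_cut']})")
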