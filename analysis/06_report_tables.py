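"""Plot-ready report tables and the run manifest.

Writes the volcano table for the within-DCM diet contrast (with the
alpha/Meff threshold line), the pathway x contrast tile table with its
shared-pathway count, and the manifest with per-file row counts.
"""

import importlib

common = importlib.import_module("00_config")
from dcmmet.pipeline import stage_report

cfg = common.config()
manifest = stage_report(cfg)

print(f"threshold line at -log10(p) = {manifest['volcano_threshold_line']:.3f}")
print(f"pathways significant in both contrasts: {manifest['shared_significant_pathways']}")
print(f"run manifest: {len(manifest['files'])} output tables, seed {manifest['seed']}, "
      f"Meff {manifest['meff']:.1f}, threshold {manifest['threshold']:.3g}")
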