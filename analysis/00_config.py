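"""Shared run configuration for the numbered analysis drivers.

Every driver operates on the same run directory (``results/run``) with
the same seed, so the scripts can be executed in order to reproduce the
full analysis, or individually to rerun one stage.
"""

from dcmmet.pipeline import RunConfig, setup_logging

SEED = 1
OUTDIR = "results/run"


def config() -> RunConfig:
    cfg = RunConfig(outdir=OUTDIR, seed=SEED)
    setup_logging(cfg.outdir, quiet=True)
    return cfg
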