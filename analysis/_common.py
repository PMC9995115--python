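"""Shared setup for the numbered analysis drivers: one default configuration,
one output root (results/analysis), cohort loading with on-demand simulation."""

import logging
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from tcrshare.io import load_cohort  # noqa: E402
from tcrshare.pipeline import RunConfig, run_simulate  # noqa: E402

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")

OUTDIR = os.path.join(os.path.dirname(__file__), "..", "results", "analysis")
SEED = 1


def config() -> RunConfig:
    return RunConfig(seed=SEED, outdir=OUTDIR)


def cohort(cfg: RunConfig):
    sheet = os.path.join(cfg.outdir, "cohort", "samples.tsv")
    if os.path.exists(sheet):
        return load_cohort(sheet)
    reps, _ = run_simulate(cfg)
    return reps
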