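"""Shared configuration for the numbered analysis drivers.

One study-like simulation (19 bears, one active season at 50.6N 122.5W,
UTC-8) drives the whole analysis chain.  Small summary tables land in
``results/``; bulky intermediate state series are cached in ``scratch/`` so
later steps do not re-simulate.
"""

from pathlib import Path

from ursactive.synthetic_data import SimConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

STUDY_LAT, STUDY_LON, STUDY_TZ = 50.6, -122.5, -8.0
SEED = 42

CONFIG = SimConfig(seed=SEED)


def results_dir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS


def scratch_dir() -> Path:
    SCRATCH.mkdir(exist_ok=True)
    return SCRATCH
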