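import sys
from datetime import date
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from ursactive.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Five bears over ten weeks: enough data for histogram and smoothing
    checks without the full-study cost."""
    return SimConfig(
        n_bears=5,
        sex_ratio=0.6,
        start_date=date(2006, 6, 1),
        end_date=date(2006, 8, 10),
        capture_gap_days=0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def fixture_files(tmp_path_factory, small_config):
    from ursactive.synthetic_data import make_fixture_dataset

    outdir = tmp_path_factory.mktemp("fixture")
    return make_fixture_dataset(small_config, outdir)
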