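import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from iscn.network import build_cohort_networks
from iscn.simulate import null_spec, simulate_cohort

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA


@pytest.fixture(scope="session")
def small_cohort():
    """Null 6+6-subject, 20-region cohort with its similarity networks."""
    spec = null_spec(n_patients=6, n_controls=6, n_regions=20, voxels_per_region=120, seed=11)
    cohort, phenotype, truth = simulate_cohort(spec)
    networks = build_cohort_networks(cohort)
    return {"spec": spec, "cohort": cohort, "phenotype": phenotype, "truth": truth, "networks": networks}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
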