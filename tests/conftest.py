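import time

import pytest

from ocdsim.config import (RunConfig, build_defect_lattice,
                           build_scaffold_layout, load_tissue_table, preset)
from ocdsim.driver import run_simulation


@pytest.fixture(scope="session")
def default_config():
    return RunConfig()


@pytest.fixture(scope="session")
def lattice(default_config):
    return build_defect_lattice(default_config)


@pytest.fixture(scope="session")
def layout(lattice):
    return build_scaffold_layout(lattice)


@pytest.fixture(scope="session")
def tissue_table():
    return load_tissue_table()


class _RunCache:
    """Lazily run (and memoise) full-lattice simulations shared by the
    scenario-level tests; also records wall time per run."""

    def __init__(self):
        self._cache = {}
        self.wall_times = {}

    def get(self, modality, speed):
        key = (modality, speed)
        if key not in self._cache:
            t0 = time.perf_counter()
            self._cache[key] = run_simulation(RunConfig(),
                                              preset(modality, speed))
            self.wall_times[key] = time.perf_counter() - t0
        return self._cache[key]


@pytest.fixture(scope="session")
def scenario_runs():
    return _RunCache()
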