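import numpy as np
import pytest

from ictalnet import SyntheticConfig, generate_record, write_fixture


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """Fixture-scale stated world: short records, seizures >= 2x the 60 s buffer apart."""
    return SyntheticConfig(n_patients=2, record_duration_s=600.0,
                           seizures_per_patient=2, seizure_duration_s=(40.0, 60.0),
                           min_separation_s=120.0, seed=5)


@pytest.fixture(scope="session")
def record_and_annotation(small_cfg):
    return generate_record(small_cfg, 0)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_cfg):
    """EDF + summary pairs for every synthetic patient."""
    directory = tmp_path_factory.mktemp("edf_fixtures")
    for i in range(small_cfg.n_patients):
        record, annotation = generate_record(small_cfg, i)
        write_fixture(record, annotation, directory)
    return directory


def random_intervals(rng: np.random.Generator, n_max: int = 6,
                     span: float = 20000.0, max_len: float = 400.0):
    """Sorted, non-overlapping random intervals for labeling-rule oracles."""
    n = int(rng.integers(0, n_max + 1))
    starts = np.sort(rng.uniform(0, span, size=n))
    intervals = []
    prev_end = 0.0
    for s in starts:
        a = max(s, prev_end + 1e-6)
        b = a + rng.uniform(1.0, max_len)
        if b > span:
            break
        intervals.append((a, b))
        prev_end = b
    return intervals
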